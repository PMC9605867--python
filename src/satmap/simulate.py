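"""Seeded synthetic-data generators for the whole pipeline.

Every generator is deterministic under a fixed seed and emits the same
in-memory containers (and, through the writers in
:mod:`satmap.sumstats`, the same TSV dialects) that the analysis modules
consume.  Three data-generating processes are covered:

* **Signal maps** (:func:`gen_signal_map`): clustered independent GWS
  signals along a genome of 22 equal-length chromosomes totalling
  3,039 Mb, with genes drawn to populate all 22 gene-length classes and
  candidate genes placed near signal hotspots with configurable odds
  (``gamma``), emulating the clustering of height signals near known
  skeletal-growth genes.
* **Two-cohort summary statistics** (:func:`gen_two_cohort_sumstats`):
  per-SNP true effects bivariate normal across cohorts with correlation
  ``rho_true`` and per-allele variance sigma_b^2 / (2p(1-p)) (so the
  per-SNP variance explained averages sigma_b^2), observed with
  independent sampling noise of standard error 1/sqrt(2p(1-p)N).
* **Family cohorts** (:func:`gen_family_cohort`): an additive polygenic
  model with phenotypic assortative mating.  Couple phenotypes are drawn
  jointly from a bivariate normal with correlation ``rho_spouse``
  (equivalent in law to Gaussian-copula rank pairing of a mating pool);
  parental genetic values follow their conditional law given phenotype;
  children receive the mid-parental genetic value plus segregation
  variance h2/2; the PGS is a noisy proxy of the child's genetic value
  with accuracy ``r2_pgs``.  Assortative-mating equilibrium inflation of
  the *parental* genetic variance is deliberately not modelled; the
  analytic module matches the covariances this process realises.
* **Annotation pools** (:func:`gen_annotation_pool`): binary functional
  annotations with configurable prevalence and a logistic selection
  model, for testing the annotation-matched SNP sampling.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .loci import GENOME_LENGTH_BP
from .sumstats import SatmapError

__all__ = [
    "SignalMapParams",
    "TwoCohortParams",
    "FamilySimParams",
    "gen_signal_map",
    "gen_two_cohort_sumstats",
    "gen_family_cohort",
    "gen_annotation_pool",
]

_Z_GWS = 5.4513  # |z| at p = 5e-8, two-sided

# Gene-length class weights over the 22 classes: dominated by the
# 10-100 kb range as in human gene annotations, with a thin tail of
# Mb-scale genes so every class stays populated.
_GENE_CLASS_WEIGHTS = np.array(
    [0.22]
    + [0.085, 0.075, 0.06, 0.05, 0.04, 0.035, 0.03, 0.025, 0.02]  # 10-100 kb
    + [0.09, 0.06, 0.04, 0.028, 0.02, 0.015, 0.012, 0.010, 0.008]  # 100 kb - 1 Mb
    + [0.014, 0.008, 0.005]  # 1-1.5 Mb, 1.5-2 Mb, >= 2 Mb
)
_GENE_CLASS_EDGES = (
    [(0, 10_000)]
    + [(10_000 * i, 10_000 * (i + 1)) for i in range(1, 10)]
    + [(100_000 * i, 100_000 * (i + 1)) for i in range(1, 10)]
    + [(1_000_000, 1_500_000), (1_500_000, 2_000_000), (2_000_000, 3_000_000)]
)


@dataclasses.dataclass(frozen=True)
class SignalMapParams:
    """Conditions for the clustered signal-map generator.

    Defaults emulate the saturated height GWAS: 12,111 independent GWS
    signals on 22 autosomes totalling 3,039 Mb, with a majority of
    signals concentrated in kilobase-scale hotspots (reproducing a mean
    signal density near 2), ~19,000 genes of which ~2.5% are candidates
    (the scale of the 462-gene Mendelian growth-disorder list), and a
    candidate placement odds ``gamma`` of 3 near hotspots (the scale of
    the observed 2.5-fold enrichment).
    """

    n_chromosomes: int = 22
    genome_length_bp: int = GENOME_LENGTH_BP
    n_signals: int = 12_111
    hotspot_fraction: float = 0.6
    n_hotspots: int = 2_000
    hotspot_width_bp: int = 200_000
    n_genes: int = 19_000
    candidate_fraction: float = 0.025
    gamma: float = 3.0
    candidate_window_bp: int = 100_000
    gwas_n: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hotspot_fraction <= 1 or not 0 <= self.candidate_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def _chrom_lengths(params: SignalMapParams) -> np.ndarray:
    base = params.genome_length_bp // params.n_chromosomes
    lengths = np.full(params.n_chromosomes, base, dtype=np.int64)
    lengths[0] += params.genome_length_bp - lengths.sum()
    return lengths


def gen_signal_map(params: SignalMapParams = SignalMapParams()):
    """Generate clustered GWS signals and genes with candidate flags.

    Returns ``(signals, genes)``: a COJO-compatible signal table (snp,
    chrom, pos, alleles, eaf, beta, se, pval, n and joint-effect columns,
    all genome-wide significant) and a gene table (name, chrom, start,
    end, is_candidate).
    """
    rng = np.random.default_rng(params.seed)
    lengths = _chrom_lengths(params)
    if params.n_signals > params.genome_length_bp // 1000:
        raise SatmapError("infeasible signal density for the genome length")

    # hotspot centers: chromosomes proportional to length, centers uniform
    hot_chrom = rng.choice(
        params.n_chromosomes, size=params.n_hotspots, p=lengths / lengths.sum()
    )
    hot_center = (rng.random(params.n_hotspots) * lengths[hot_chrom]).astype(np.int64)

    n_hot = int(round(params.n_signals * params.hotspot_fraction))
    n_bg = params.n_signals - n_hot
    which = rng.integers(0, params.n_hotspots, size=n_hot)
    hot_pos = hot_center[which] + rng.integers(
        -params.hotspot_width_bp // 2, params.hotspot_width_bp // 2 + 1, size=n_hot
    )
    hot_pos = np.clip(hot_pos, 1, lengths[hot_chrom[which]])
    sig_chrom = np.concatenate(
        [
            hot_chrom[which],
            rng.choice(params.n_chromosomes, size=n_bg, p=lengths / lengths.sum()),
        ]
    )
    bg_pos = (rng.random(n_bg) * lengths[sig_chrom[n_hot:]]).astype(np.int64) + 1
    sig_pos = np.concatenate([hot_pos, bg_pos])
    order = rng.permutation(params.n_signals)
    sig_chrom, sig_pos = sig_chrom[order], sig_pos[order]

    maf = rng.uniform(0.01, 0.5, size=params.n_signals)
    flip = rng.random(params.n_signals) < 0.5
    eaf = np.where(flip, 1 - maf, maf)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * params.gwas_n)
    z = rng.choice([-1, 1], size=params.n_signals) * (
        _Z_GWS + np.abs(rng.normal(0, 3, size=params.n_signals))
    )
    from scipy import stats as st

    pval = np.maximum(2 * st.norm.sf(np.abs(z)), 1e-300)
    signals = pd.DataFrame(
        {
            "snp": [f"rs{i+1}" for i in range(params.n_signals)],
            "chrom": sig_chrom + 1,
            "pos": sig_pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": z * se,
            "se": se,
            "pval": pval,
            "n": params.gwas_n,
            "beta_joint": z * se,
            "se_joint": se,
            "pval_joint": pval,
        }
    )

    # genes: lengths stratified over the 22 classes, uniform placement
    cls = rng.choice(
        len(_GENE_CLASS_WEIGHTS),
        size=params.n_genes,
        p=_GENE_CLASS_WEIGHTS / _GENE_CLASS_WEIGHTS.sum(),
    )
    lo = np.array([_GENE_CLASS_EDGES[c][0] for c in cls])
    hi = np.array([_GENE_CLASS_EDGES[c][1] for c in cls])
    glen = (lo + rng.random(params.n_genes) * (hi - lo)).astype(np.int64)
    glen = np.maximum(glen, 200)  # no zero-length genes in the <10 kb class
    gchrom = rng.choice(params.n_chromosomes, size=params.n_genes, p=lengths / lengths.sum())
    gstart = (
        rng.random(params.n_genes) * np.maximum(lengths[gchrom] - glen, 1)
    ).astype(np.int64) + 1
    genes = pd.DataFrame(
        {
            "name": [f"GENE{i+1}" for i in range(params.n_genes)],
            "chrom": gchrom + 1,
            "start": gstart,
            "end": gstart + glen - 1,
        }
    )

    # candidate genes placed near hotspots with odds gamma
    near = np.zeros(params.n_genes, dtype=bool)
    for c in range(params.n_chromosomes):
        gm = genes["chrom"].to_numpy() == c + 1
        centers = np.sort(hot_center[hot_chrom == c])
        if not gm.any() or centers.size == 0:
            continue
        s = genes.loc[gm, "start"].to_numpy() - params.candidate_window_bp
        e = genes.loc[gm, "end"].to_numpy() + params.candidate_window_bp
        lo_i = np.searchsorted(centers, s, side="left")
        hi_i = np.searchsorted(centers, e, side="right")
        near[gm] = hi_i > lo_i
    weights = np.where(near, params.gamma, 1.0)
    n_cand = int(round(params.candidate_fraction * params.n_genes))
    cand_idx = rng.choice(
        params.n_genes, size=n_cand, replace=False, p=weights / weights.sum()
    )
    genes["is_candidate"] = False
    genes.loc[cand_idx, "is_candidate"] = True
    return signals, genes


@dataclasses.dataclass(frozen=True)
class TwoCohortParams:
    """Conditions for the paired discovery/replication generator.

    Defaults mirror the replication design of the height study: a
    ~5-million discovery sample, a ~50,000 replication sample, mean
    per-SNP variance explained sigma_b^2 = 1e-3, and MAF uniform on
    [0.01, 0.5].  ``maf`` may be a (low, high) range or a single fixed
    value.
    """

    m_snps: int = 5_000
    sigma2_b: float = 1e-3
    rho_true: float = 1.0
    n_d: float = 5_000_000
    n_r: float = 50_000
    maf: tuple[float, float] | float = (0.01, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.rho_true <= 1:
            raise ValueError("rho_true must lie in [-1, 1]")
        if self.sigma2_b < 0 or self.n_d <= 0 or self.n_r <= 0:
            raise ValueError("invalid cohort parameters")


def gen_two_cohort_sumstats(params: TwoCohortParams = TwoCohortParams()) -> pd.DataFrame:
    """Paired effect estimates from two cohorts sharing correlated true effects.

    Per SNP with MAF p, the true per-allele effects (b_d, b_r) are
    bivariate normal with variance sigma_b^2 / (2p(1-p)) each and
    correlation ``rho_true``; observed effects add independent noise with
    se = 1/sqrt(2p(1-p)N).  Columns: snp, chrom, eaf_d, eaf_r, true_d,
    true_r, beta_d, se_d, beta_r, se_r.
    """
    rng = np.random.default_rng(params.seed)
    m = params.m_snps
    if isinstance(params.maf, tuple):
        maf = rng.uniform(params.maf[0], params.maf[1], size=m)
    else:
        maf = np.full(m, float(params.maf))
    het = 2 * maf * (1 - maf)
    sd_true = np.sqrt(params.sigma2_b / het)
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    rho = params.rho_true
    true_d = sd_true * z1
    true_r = sd_true * (rho * z1 + np.sqrt(1 - rho**2) * z2)
    se_d = 1.0 / np.sqrt(het * params.n_d)
    se_r = 1.0 / np.sqrt(het * params.n_r)
    return pd.DataFrame(
        {
            "snp": [f"rs{i+1}" for i in range(m)],
            "chrom": (np.arange(m) % 22) + 1,
            "eaf_d": maf,
            "eaf_r": maf,
            "true_d": true_d,
            "true_r": true_r,
            "beta_d": true_d + se_d * rng.standard_normal(m),
            "se_d": se_d,
            "beta_r": true_r + se_r * rng.standard_normal(m),
            "se_r": se_r,
        }
    )


@dataclasses.dataclass(frozen=True)
class FamilySimParams:
    """Conditions for the family simulator.

    Defaults are height-like: heritability 0.8, spousal phenotypic
    correlation 0.25, and a GWS-SNP PGS accuracy of 0.4.
    """

    n_families: int = 10_000
    h2: float = 0.8
    rho_spouse: float = 0.25
    r2_pgs: float = 0.4
    sibling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r2_pgs <= self.h2 <= 1:
            raise ValueError("need 0 <= r2_pgs <= h2 <= 1")
        if not -1 <= self.rho_spouse <= 1:
            raise ValueError("rho_spouse must lie in [-1, 1]")


def gen_family_cohort(params: FamilySimParams = FamilySimParams()) -> pd.DataFrame:
    """Simulate families under the additive model with assortative mating.

    Returns one row per family with columns ``y, s, y_f, y_m`` (child
    phenotype and PGS, parental phenotypes) and, when ``params.sibling``
    is set, ``y_sib, s_sib`` for a second child with independent
    segregation, environment and PGS noise.
    """
    rng = np.random.default_rng(params.seed)
    n, h2, rho, r2 = params.n_families, params.h2, params.rho_spouse, params.r2_pgs
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    y_f = z1
    y_m = rho * z1 + np.sqrt(1 - rho**2) * z2
    # parental genetic values from their conditional law given phenotype
    g_f = h2 * y_f + np.sqrt(h2 * (1 - h2)) * rng.standard_normal(n)
    g_m = h2 * y_m + np.sqrt(h2 * (1 - h2)) * rng.standard_normal(n)
    midparent = 0.5 * (g_f + g_m)

    def child():
        g = midparent + np.sqrt(h2 / 2) * rng.standard_normal(n)
        y = g + np.sqrt(1 - h2) * rng.standard_normal(n)
        if h2 > 0:
            s = (r2 / h2) * g + np.sqrt(r2 * (1 - r2 / h2)) * rng.standard_normal(n)
        else:
            s = np.zeros(n)
        return y, s

    y, s = child()
    out = pd.DataFrame({"y": y, "s": s, "y_f": y_f, "y_m": y_m})
    if params.sibling:
        y2, s2 = child()
        out["y_sib"] = y2
        out["s_sib"] = s2
    return out


def gen_annotation_pool(
    n_snps: int,
    n_annotations: int = 24,
    coefficients: Sequence[float] | None = None,
    intercept: float = -3.0,
    prevalence: Sequence[float] | float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Pool of SNPs with binary annotations and a logistic selection flag.

    Columns: ``snp, chrom, pos, maf, ld_score, annot_1..annot_K,
    selected``.  The selection flag is Bernoulli with logit
    ``intercept + annotations @ coefficients`` (zero coefficients by
    default, i.e. selection independent of annotation).
    """
    rng = np.random.default_rng(seed)
    coef = np.zeros(n_annotations) if coefficients is None else np.asarray(coefficients, float)
    if coef.size != n_annotations or not np.all(np.isfinite(coef)):
        raise ValueError("need one finite coefficient per annotation")
    prev = np.broadcast_to(np.asarray(prevalence, float), (n_annotations,))
    ann = (rng.random((n_snps, n_annotations)) < prev[None, :]).astype(int)
    logit = intercept + ann @ coef
    selected = (rng.random(n_snps) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    pool = pd.DataFrame(ann, columns=[f"annot_{j+1}" for j in range(n_annotations)])
    pool.insert(0, "snp", [f"rs{i+1}" for i in range(n_snps)])
    pool.insert(1, "chrom", rng.integers(1, 23, size=n_snps))
    pool.insert(2, "pos", rng.integers(1, 130_000_000, size=n_snps))
    pool.insert(3, "maf", rng.uniform(0.01, 0.5, size=n_snps))
    pool.insert(4, "ld_score", rng.gamma(2.0, 50.0, size=n_snps))
    pool["selected"] = selected
    return pool
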