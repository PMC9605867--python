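"""Colocalization and gene-enrichment statistics with resampling nulls.

Four pieces of machinery live here:

* **Proximity between SNP sets** — the fraction of query signals lying
  within a window (default 100 kb, inclusive) of any same-chromosome
  reference signal, used to quantify cross-ancestry colocalization.
* **Gene enrichment near dense signals** — a 2x2 contingency table of
  "candidate gene within the window of the signal" against "signal
  density above / at-or-below a threshold", summarised by an odds ratio,
  with a null distribution built by resampling length-matched random gene
  sets (candidate genes in each of 22 gene-length classes replaced by an
  equal number of non-candidates from the same class).
* **Matched SNP sampling** — either via a logistic selection model on
  binary functional annotations (fit, predict, sample with replacement
  proportional to the predicted selection probability), or via exact
  per-class sampling over 28 MAF x LD-score classes.
* **Cross-ancestry LD independence filter** — keep a SNP only when its
  maximum squared LD correlation with the reference set stays below a
  cutoff (default 0.8) in *both* LD panels.

Gene-signal distance is measured to the nearest interval edge (0 inside
the gene).  Permutation p-values use the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_samples).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .sumstats import EmptyInputError, SatmapError

__all__ = [
    "ContingencyTable2x2",
    "LengthClassScheme",
    "EnrichmentResult",
    "AnnotationMatchResult",
    "proximity_fraction",
    "gene_proximity_table",
    "odds_ratio",
    "enrichment_null",
    "enrichment_by_density_threshold",
    "match_snps_by_annotation_model",
    "match_snps_by_bins",
    "ld_independence_filter",
    "DEFAULT_MAF_BREAKS",
]

#: MAF class breakpoints: <1%, 1-5%, 5-10%, 10-20%, 20-30%, 30-40%, 40-50%.
DEFAULT_MAF_BREAKS = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40)


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for the gene-proximity x density-stratum table.

    Layout: ``a`` = gene-proximal & high-density, ``b`` = non-proximal &
    high-density, ``c`` = gene-proximal & low-density, ``d`` =
    non-proximal & low-density.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def odds_ratio(table: ContingencyTable2x2, return_flag: bool = False):
    """Odds ratio (a*d)/(b*c) of a 2x2 table.

    If any cell is zero the Haldane-Anscombe correction (+0.5 to every
    cell) is applied; pass ``return_flag=True`` to also receive whether
    the correction was used.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = (a * d) / (b * c)
    return (value, corrected) if return_flag else value


@dataclasses.dataclass(frozen=True)
class LengthClassScheme:
    """Ordered, disjoint, exhaustive gene-length classes.

    The default resolves to 22 classes: <10 kb; nine 10-kb classes
    covering [10, 100) kb; nine 100-kb classes covering [100 kb, 1 Mb);
    [1, 1.5) Mb; [1.5, 2) Mb; and >= 2 Mb.
    """

    edges_bp: tuple[float, ...] = tuple(
        [10_000 * i for i in range(1, 10)]
        + [100_000 * i for i in range(1, 11)]
        + [1_500_000, 2_000_000]
    )

    @property
    def n_classes(self) -> int:
        return len(self.edges_bp) + 1

    def classify(self, lengths_bp) -> np.ndarray:
        """Map positive gene lengths to 0-based class indices."""
        lengths_bp = np.asarray(lengths_bp)
        if (lengths_bp <= 0).any():
            raise ValueError("gene lengths must be positive")
        return np.digitize(lengths_bp, self.edges_bp)


def _split_positions(df: pd.DataFrame):
    for chrom, grp in df.groupby("chrom"):
        yield int(chrom), grp


def proximity_fraction(
    query: pd.DataFrame, reference: pd.DataFrame, window_bp: int = 100_000
) -> tuple[float, np.ndarray]:
    """Fraction of query signals within ``window_bp`` of a reference signal.

    Both tables need ``chrom`` and ``pos`` columns.  The comparison is
    same-chromosome and inclusive; with ``window_bp=0`` the fraction is
    the exact-position overlap.  Returns ``(fraction, indicator)`` with a
    per-query-row boolean indicator.
    """
    if query.shape[0] == 0 or reference.shape[0] == 0:
        raise EmptyInputError("proximity_fraction requires non-empty SNP sets")
    hit = np.zeros(query.shape[0], dtype=bool)
    ref_by_chrom = {
        c: np.sort(g["pos"].to_numpy()) for c, g in _split_positions(reference)
    }
    qpos_all = query["pos"].to_numpy()
    qchrom = query["chrom"].to_numpy()
    for chrom, ref in ref_by_chrom.items():
        mask = qchrom == chrom
        if not mask.any():
            continue
        qpos = qpos_all[mask]
        lo = np.searchsorted(ref, qpos - window_bp, side="left")
        hi = np.searchsorted(ref, qpos + window_bp, side="right")
        hit[mask] = hi > lo
    return float(hit.mean()), hit


def gene_signal_proximity(
    signals: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 100_000
) -> np.ndarray:
    """Boolean matrix (signals x genes): gene edge within ``window_bp``.

    Distance is to the nearest gene-interval edge and 0 when the signal
    lies inside the gene; genes on other chromosomes never match.
    """
    P = np.zeros((signals.shape[0], genes.shape[0]), dtype=bool)
    spos = signals["pos"].to_numpy()
    schrom = signals["chrom"].to_numpy()
    gchrom = genes["chrom"].to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    for chrom in np.unique(schrom):
        srows = np.flatnonzero(schrom == chrom)
        gcols = np.flatnonzero(gchrom == chrom)
        if gcols.size == 0:
            continue
        pos = spos[srows][:, None]
        dist = np.maximum(gstart[gcols][None, :] - pos, 0) + np.maximum(
            pos - gend[gcols][None, :], 0
        )
        P[np.ix_(srows, gcols)] = dist <= window_bp
    return P


def _table_from_masks(proximal: np.ndarray, high: np.ndarray) -> ContingencyTable2x2:
    return ContingencyTable2x2(
        a=int(np.sum(proximal & high)),
        b=int(np.sum(~proximal & high)),
        c=int(np.sum(proximal & ~high)),
        d=int(np.sum(~proximal & ~high)),
    )


def gene_proximity_table(
    signals: pd.DataFrame,
    densities: np.ndarray,
    genes: pd.DataFrame,
    window_bp: int = 100_000,
    density_threshold: int = 0,
) -> ContingencyTable2x2:
    """Cross-classify signals by candidate-gene proximity and density.

    A signal is *gene-proximal* when any candidate gene interval comes
    within ``window_bp`` of its position (edge distance, 0 inside); the
    *high-density* stratum holds signals with density strictly above
    ``density_threshold`` (default: density >= 1 versus density 0).
    """
    candidates = genes.loc[genes["is_candidate"]]
    if candidates.shape[0] == 0:
        raise SatmapError("gene_proximity_table requires at least one candidate gene")
    P = gene_signal_proximity(signals, candidates, window_bp)
    proximal = P.any(axis=1)
    high = np.asarray(densities) > density_threshold
    return _table_from_masks(proximal, high)


@dataclasses.dataclass
class EnrichmentResult:
    observed_or: float
    null_or: np.ndarray
    p_value: float
    n_samples: int


def enrichment_null(
    genes: pd.DataFrame,
    signals: pd.DataFrame,
    densities: np.ndarray,
    n_samples: int = 1000,
    scheme: LengthClassScheme | None = None,
    seed: int | np.random.Generator = 0,
    window_bp: int = 100_000,
    density_threshold: int = 0,
) -> EnrichmentResult:
    """Length-matched resampling null for the gene-enrichment odds ratio.

    For each replicate, the candidate genes falling in each gene-length
    class are replaced by an equal number of non-candidate genes sampled
    (without replacement) from the same class, and the odds ratio of
    :func:`gene_proximity_table` is recomputed.  The permutation p-value
    is (1 + #{null OR >= observed OR}) / (1 + n_samples).

    Raises
    ------
    SatmapError
        When a length class contains candidates but not enough
        non-candidate genes to resample from (the class is named).
    """
    rng = np.random.default_rng(seed)
    scheme = scheme or LengthClassScheme()
    lengths = genes["end"].to_numpy() - genes["start"].to_numpy() + 1
    classes = scheme.classify(lengths)
    cand = genes["is_candidate"].to_numpy().astype(bool)
    if not cand.any():
        raise SatmapError("enrichment_null requires candidate genes")

    high = np.asarray(densities) > density_threshold
    P = gene_signal_proximity(signals, genes, window_bp)

    def or_for(cols: np.ndarray) -> float:
        proximal = P[:, cols].any(axis=1)
        return odds_ratio(_table_from_masks(proximal, high))

    observed = or_for(np.flatnonzero(cand))

    pool_by_class: dict[int, np.ndarray] = {}
    need_by_class: dict[int, int] = {}
    for cls in np.unique(classes[cand]):
        need = int(np.sum(cand & (classes == cls)))
        pool = np.flatnonzero(~cand & (classes == cls))
        if pool.size < need:
            raise SatmapError(
                f"gene-length class {cls} has {need} candidate(s) but only "
                f"{pool.size} non-candidate gene(s) to sample from"
            )
        pool_by_class[cls] = pool
        need_by_class[cls] = need

    null = np.empty(n_samples)
    for r in range(n_samples):
        cols = np.concatenate(
            [
                rng.choice(pool, size=need_by_class[cls], replace=False)
                for cls, pool in pool_by_class.items()
            ]
        )
        null[r] = or_for(cols)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_samples)
    return EnrichmentResult(observed, null, p, n_samples)


def enrichment_by_density_threshold(
    signals: pd.DataFrame,
    densities: np.ndarray,
    genes: pd.DataFrame,
    thresholds: Sequence[int] = tuple(range(1, 11)),
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Odds ratio as a function of the density cut (strata d >= k vs d < k)."""
    rows = []
    for k in thresholds:
        table = gene_proximity_table(
            signals, densities, genes, window_bp, density_threshold=k - 1
        )
        value, flagged = odds_ratio(table, return_flag=True)
        rows.append({"threshold": k, "odds_ratio": value, "haldane": flagged})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class AnnotationMatchResult:
    sets: list[np.ndarray]
    probabilities: np.ndarray
    coefficients: pd.Series
    fisher_pvals: pd.DataFrame  # n_sets x annotations
    summary: pd.DataFrame  # per-annotation mean / median Fisher p


def match_snps_by_annotation_model(
    pool: pd.DataFrame,
    n_sets: int,
    set_size: int,
    seed: int | np.random.Generator = 0,
    annotation_cols: Sequence[str] | None = None,
    selected_col: str = "selected",
) -> AnnotationMatchResult:
    """Sample SNP sets matched to a selected set via a logistic model.

    Three steps: (1) fit a logistic regression of the selection flag on
    the binary annotations; (2) predict each pool SNP's selection
    probability; (3) draw ``n_sets`` sets of ``set_size`` SNPs with
    replacement, with probability proportional to the prediction.
    Annotation balance is diagnosed per sampled set with a two-sided
    Fisher's exact test on the 2x2 counts of each annotation (selected
    vs sampled).
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    if annotation_cols is None:
        annotation_cols = [c for c in pool.columns if c.startswith("annot")]
    if not annotation_cols:
        raise SatmapError("no annotation columns found")
    y = pool[selected_col].to_numpy().astype(float)
    if y.min() == y.max():
        raise SatmapError("pool must contain both selected and unselected SNPs")
    ann_mat = pool[list(annotation_cols)].to_numpy().astype(float)
    informative = ann_mat.std(axis=0) > 0
    full_params = np.zeros(1 + len(annotation_cols))
    if not informative.any():
        # constant annotations carry no information: sampling is uniform
        prob = np.full(pool.shape[0], y.mean())
        full_params[0] = np.log(y.mean() / (1 - y.mean()))
    else:
        X = sm.add_constant(ann_mat[:, informative])
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params)
            if not np.all(np.isfinite(fit.bse)):
                raise SatmapError(
                    "quasi-separation in the annotation model; prune collinear "
                    "or perfectly predictive annotations"
                )
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise SatmapError(
                "perfect separation in the annotation model; prune annotations"
            ) from exc
        full_params[0] = params[0]
        full_params[1:][informative] = params[1:]
        prob = 1.0 / (1.0 + np.exp(-(params @ np.vstack([np.ones(len(y)), ann_mat[:, informative].T]))))
    weights = prob / prob.sum()
    sets = [
        rng.choice(pool.shape[0], size=set_size, replace=True, p=weights)
        for _ in range(n_sets)
    ]

    ann = pool[list(annotation_cols)].to_numpy().astype(int)
    sel_mask = y.astype(bool)
    n_sel = int(sel_mask.sum())
    sel_with = ann[sel_mask].sum(axis=0)
    pvals = np.empty((n_sets, len(annotation_cols)))
    for i, idx in enumerate(sets):
        samp_with = ann[idx].sum(axis=0)
        for j in range(len(annotation_cols)):
            table = [
                [int(sel_with[j]), n_sel - int(sel_with[j])],
                [int(samp_with[j]), set_size - int(samp_with[j])],
            ]
            pvals[i, j] = st.fisher_exact(table, alternative="two-sided")[1]
    fisher = pd.DataFrame(pvals, columns=list(annotation_cols))
    summary = pd.DataFrame(
        {"mean_p": fisher.mean(axis=0), "median_p": fisher.median(axis=0)}
    )
    coef = pd.Series(full_params, index=["const"] + list(annotation_cols))
    return AnnotationMatchResult(sets, prob, coef, fisher, summary)


def _joint_classes(
    maf: np.ndarray, ld: np.ndarray, maf_breaks: Sequence[float], ld_edges: np.ndarray
) -> np.ndarray:
    maf_cls = np.digitize(maf, maf_breaks)
    ld_cls = np.digitize(ld, ld_edges)
    return maf_cls * (len(ld_edges) + 1) + ld_cls


def match_snps_by_bins(
    pool: pd.DataFrame,
    targets: np.ndarray,
    maf_breaks: Sequence[float] = DEFAULT_MAF_BREAKS,
    seed: int | np.random.Generator = 0,
    maf_col: str = "maf",
    ld_col: str = "ld_score",
) -> np.ndarray:
    """Draw a random SNP set matching targets on joint MAF x LD classes.

    MAF classes use fixed breakpoints (default 1/5/10/20/30/40/50 %); LD
    score classes are the quartiles of the *pool* LD-score distribution,
    giving 28 joint classes.  For every joint class the same number of
    pool SNPs as targets in that class is sampled without replacement.

    Parameters
    ----------
    targets
        Integer row indices into ``pool`` (a boolean mask also works).

    Returns
    -------
    numpy.ndarray
        Row indices of the matched set (same per-class counts as the
        targets, exactly).
    """
    rng = np.random.default_rng(seed)
    targets = np.asarray(targets)
    if targets.dtype == bool:
        targets = np.flatnonzero(targets)
    maf = pool[maf_col].to_numpy()
    ld = pool[ld_col].to_numpy()
    ld_edges = np.quantile(ld, [0.25, 0.5, 0.75])
    classes = _joint_classes(maf, ld, maf_breaks, ld_edges)
    matched = []
    for cls, need in zip(*np.unique(classes[targets], return_counts=True)):
        members = np.flatnonzero(classes == cls)
        if members.size < need:
            raise SatmapError(
                f"MAF-LD class {cls} has {need} target(s) but only "
                f"{members.size} pool SNP(s)"
            )
        matched.append(rng.choice(members, size=need, replace=False))
    return np.concatenate(matched)


def _max_r2(snps_a: Sequence[str], snps_b: Sequence[str], ld: pd.DataFrame):
    """Per-a-SNP max r2 against snps_b from a long-format LD table."""
    b_set = set(snps_b)
    sub = ld.loc[ld["snp_a"].isin(snps_a) & ld["snp_b"].isin(b_set)]
    # symmetric storage: also accept (b, a) rows
    sub_rev = ld.loc[ld["snp_b"].isin(snps_a) & ld["snp_a"].isin(b_set)]
    frames = [
        sub[["snp_a", "r2"]],
        sub_rev[["snp_b", "r2"]].rename(columns={"snp_b": "snp_a"}),
    ]
    both = pd.concat(frames, ignore_index=True)
    best = both.groupby("snp_a")["r2"].max()
    n_pairs_present = both.shape[0]
    return best, n_pairs_present


def ld_independence_filter(
    snps_a: Sequence[str],
    snps_b: Sequence[str],
    ld_a: pd.DataFrame,
    ld_b: pd.DataFrame,
    r2_max: float = 0.8,
) -> tuple[list[str], dict]:
    """Keep each query SNP only if independent of the reference set in both panels.

    A SNP from ``snps_a`` is removed when its maximum squared LD
    correlation with any SNP in ``snps_b`` reaches ``r2_max`` in *either*
    LD panel (long-format tables with columns ``snp_a, snp_b, r2``).
    Pairs absent from a panel are treated as r2 = 0 and counted in the
    returned info dict.
    """
    n_possible = len(snps_a) * len(snps_b)
    best_a, seen_a = _max_r2(snps_a, snps_b, ld_a)
    best_b, seen_b = _max_r2(snps_a, snps_b, ld_b)
    kept = [
        s
        for s in snps_a
        if best_a.get(s, 0.0) < r2_max and best_b.get(s, 0.0) < r2_max
    ]
    info = {
        "missing_pairs_panel_a": n_possible - seen_a,
        "missing_pairs_panel_b": n_possible - seen_b,
        "removed": len(snps_a) - len(kept),
    }
    return kept, info
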