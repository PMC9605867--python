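"""Replication-concordance statistics for paired GWAS summary data.

Machinery for comparing effect estimates between a discovery and a
replication GWAS:

* fixed-effect inverse-variance-weighted meta-analysis with Cochran's Q;
* Hudson's F_ST estimator, averaged as a ratio of averages;
* winner's-curse correction of effects selected at a significance
  threshold, via the conditional expectation of a two-sided truncated
  normal (solved by monotone root finding);
* the noise-corrected effect correlation rho_b between two GWASs,

      rho_b = cov(b_d, b_r) / sqrt[(var(b_d) - median(se_d^2))
                                    * (var(b_r) - median(se_r^2))],

  with a leave-one-SNP-out jackknife standard error;
* closed-form expectations under shared true effects:
  the expected correlation of *estimated* effects

      E[rho_b] = sigma_b^2 / sqrt[(sigma_b^2 + (1 - sigma_b^2 h_d)/(N_d h_d))
                                  * (sigma_b^2 + (1 - sigma_b^2 h_r)/(N_r h_r))],

  where h is the mean SNP heterozygosity 2*MAF*(1-MAF) and sigma_b^2 the
  mean per-SNP variance explained, and the expected proportion of
  sign-consistent effects E[P] = 1/2 + arcsin(rho)/pi (the orthant
  probability of a standard bivariate Gaussian);
* an exact binomial test of observed sign consistency against 1/2.

Paired tables are pandas DataFrames with columns ``beta_d, se_d, beta_r,
se_r`` (plus optionally ``eaf_d, eaf_r, chrom``), aligned to the same
effect allele upstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as st

from .sumstats import SatmapError

__all__ = [
    "MetaResult",
    "ReplicationDesign",
    "RhoBResult",
    "ivw_meta",
    "hudson_fst",
    "winners_curse_correct",
    "estimate_rho_b",
    "expected_rho_b",
    "expected_sign_consistency",
    "sign_consistency_test",
    "align_effect_pairs",
]


@dataclasses.dataclass(frozen=True)
class MetaResult:
    """Fixed-effect meta-analysis of one SNP across studies."""

    beta: float
    se: float
    pval: float
    cochran_q: float
    df: int
    i2: float  #: heterogeneity fraction max(0, (Q - df) / Q)


def ivw_meta(betas, ses) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Weights are 1/se^2; Cochran's Q is the weighted sum of squared
    deviations from the pooled effect, with k-1 degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise SatmapError("ivw_meta requires at least one study")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (betas - beta) ** 2))
    df = betas.size - 1
    pval = float(2 * st.norm.sf(abs(beta) / se))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(beta, se, pval, q, df, i2)


def hudson_fst(p1, n1, p2, n2) -> tuple[np.ndarray, float, int]:
    """Hudson's F_ST between two populations, per SNP and ratio-of-averages.

    Parameters are allele-frequency vectors and *allele* counts (2N for
    diploids).  Per SNP the numerator is
    (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and the denominator is
    p1(1-p2) + p2(1-p1); the mean is sum(num)/sum(den) over SNPs with a
    nonzero denominator (SNPs monomorphic in both samples are excluded
    and counted).

    Returns
    -------
    (per_snp, mean_fst, n_excluded)
        ``per_snp`` contains NaN at excluded SNPs.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("allele counts must be at least 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    per_snp = np.full(p1.shape, np.nan)
    per_snp[ok] = num[ok] / den[ok]
    mean = float(num[ok].sum() / den[ok].sum())
    return per_snp, mean, int(np.sum(~ok))


def _expected_observed(b: np.ndarray, se: np.ndarray, z_alpha: float) -> np.ndarray:
    """E[beta_hat | true effect b, selected at |beta_hat/se| >= z_alpha]."""
    u = b / se
    num = st.norm.pdf(z_alpha - u) - st.norm.pdf(-z_alpha - u)
    den = st.norm.sf(z_alpha - u) + st.norm.cdf(-z_alpha - u)
    return b + se * num / den


def winners_curse_correct(
    beta, se, alpha: float = 5e-8, tol: float = 1e-10, max_iter: int = 200
):
    """Correct selected effect estimates for winner's curse.

    Inverts the conditional-expectation map of a normal estimate under
    two-sided selection at the threshold z_alpha = Phi^-1(1 - alpha/2):
    solves E[beta_hat | b, |beta_hat| >= z_alpha * se] = beta_hat for the
    underlying effect b by bisection (the map is monotone in b).  The
    corrected effect preserves the sign and never exceeds the observed
    magnitude.  Vectorised over SNPs.

    Raises
    ------
    SatmapError
        If bisection fails to bracket or converge (with diagnostics).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    se = np.broadcast_to(np.asarray(se, dtype=float), beta.shape).copy()
    z_alpha = st.norm.isf(alpha / 2)
    sign = np.sign(beta)
    mag = np.abs(beta)
    # Work on magnitudes: g(b) = E[obs | b] is increasing with g(0) = 0,
    # g(b) > b, so the root lies in [0, observed magnitude].
    lo = np.zeros_like(mag)
    hi = mag.copy()
    g_hi = _expected_observed(hi, se, z_alpha)
    if np.any(g_hi < mag - 1e-12 * np.maximum(mag, 1.0)):
        bad = np.flatnonzero(g_hi < mag)
        raise SatmapError(
            f"winner's-curse bracket failure at indices {bad[:5].tolist()}: "
            f"observed |z| below the selection threshold?"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = _expected_observed(mid, se, z_alpha)
        too_low = g < mag
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol * np.maximum(1.0, np.max(mag)):
            break
    else:
        raise SatmapError(
            f"winner's-curse bisection did not converge: residual interval "
            f"{np.max(hi - lo):.3e}"
        )
    corrected = sign * 0.5 * (lo + hi)
    return corrected if corrected.size > 1 else float(corrected[0])


@dataclasses.dataclass
class RhoBResult:
    rho_b: float
    se: float
    clipped: bool
    n_snps: int


def _loo_median_sq(sq: np.ndarray) -> np.ndarray:
    """Median of ``sq`` with element i removed, for every i (vectorised)."""
    n = sq.size
    order = np.argsort(sq, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    s = sq[order]
    m = n - 1
    if m % 2 == 1:
        k = (m - 1) // 2
        lo_val, hi_val = s[k], s[k + 1]
        return np.where(rank > k, lo_val, hi_val)
    k1, k2 = m // 2 - 1, m // 2
    # removing rank r shifts which order statistics remain
    v_low = np.where(rank > k1, s[k1], s[k1 + 1])
    v_high = np.where(rank > k2, s[k2], s[k2 + 1])
    return 0.5 * (v_low + v_high)


def estimate_rho_b(
    pairs: pd.DataFrame,
    correct_wc: bool = False,
    alpha: float = 5e-8,
) -> RhoBResult:
    """Noise-corrected correlation of effects between two GWASs.

    rho_b divides the sample covariance of the paired effect estimates by
    the geometric mean of the noise-deflated variances (sample variance
    minus the median squared standard error on each side).  The estimate
    is clipped to [-1, 1] (flagged) and its standard error comes from a
    leave-one-SNP-out jackknife.  With ``correct_wc`` the discovery
    effects are first corrected for winner's curse at threshold ``alpha``.

    Raises
    ------
    SatmapError
        When a deflated variance term is nonpositive (sampling noise
        exceeds the effect-size signal) or fewer than 10 pairs are given.
    """
    if pairs.shape[0] < 10:
        raise SatmapError("estimate_rho_b requires at least 10 SNP pairs")
    bd = pairs["beta_d"].to_numpy(dtype=float)
    br = pairs["beta_r"].to_numpy(dtype=float)
    if correct_wc:
        bd = np.asarray(
            winners_curse_correct(bd, pairs["se_d"].to_numpy(dtype=float), alpha)
        )
    sd2 = pairs["se_d"].to_numpy(dtype=float) ** 2
    sr2 = pairs["se_r"].to_numpy(dtype=float) ** 2
    n = bd.size

    def rho(bd_, br_, med_d, med_r, full_check=False):
        vd = np.var(bd_, ddof=1) - med_d
        vr = np.var(br_, ddof=1) - med_r
        if vd <= 0 or vr <= 0:
            if full_check:
                raise SatmapError(
                    f"deflated variance nonpositive (discovery {vd:.3e}, "
                    f"replication {vr:.3e}): noise exceeds signal"
                )
            return np.nan
        cov = np.cov(bd_, br_, ddof=1)[0, 1]
        return cov / np.sqrt(vd * vr)

    raw = rho(bd, br, np.median(sd2), np.median(sr2), full_check=True)
    est = float(np.clip(raw, -1.0, 1.0))
    clipped = est != raw

    # streaming leave-one-out moments
    sum_d, sum_r = bd.sum(), br.sum()
    ss_d, ss_r, s_dr = (bd**2).sum(), (br**2).sum(), (bd * br).sum()
    m = n - 1
    mean_d = (sum_d - bd) / m
    mean_r = (sum_r - br) / m
    var_d = (ss_d - bd**2 - m * mean_d**2) / (m - 1)
    var_r = (ss_r - br**2 - m * mean_r**2) / (m - 1)
    cov_loo = (s_dr - bd * br - m * mean_d * mean_r) / (m - 1)
    vd_loo = var_d - _loo_median_sq(sd2)
    vr_loo = var_r - _loo_median_sq(sr2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.clip(cov_loo / np.sqrt(vd_loo * vr_loo), -1.0, 1.0)
    theta = theta[np.isfinite(theta)]
    k = theta.size
    se = float(np.sqrt((k - 1) / k * np.sum((theta - theta.mean()) ** 2)))
    return RhoBResult(est, se, clipped, n)


@dataclasses.dataclass(frozen=True)
class ReplicationDesign:
    """Design constants entering the closed-form E[rho_b].

    ``h_d`` / ``h_r`` are the mean heterozygosities 2*MAF*(1-MAF) across
    GWS SNPs in the discovery and replication samples; ``sigma2_b`` is
    estimated as the sample variance of estimated discovery SNP effects
    minus the median squared standard error.  Note the units: that
    estimator yields the variance of true *per-allele* effects, which is
    the quantity the closed form requires — its noise terms
    (1 - sigma2_b h)/(N h) are then exactly the sampling variances of
    per-allele effect estimates, and sigma2_b * h is the mean per-SNP
    variance explained.
    """

    n_d: float
    n_r: float
    h_d: float
    h_r: float
    sigma2_b: float

    def __post_init__(self) -> None:
        if min(self.n_d, self.n_r) <= 0 or not (0 < self.h_d <= 0.5 and 0 < self.h_r <= 0.5):
            raise ValueError("invalid replication design")
        if self.sigma2_b < 0:
            raise ValueError("sigma2_b must be nonnegative")


def expected_rho_b(design: ReplicationDesign) -> float:
    """Expected correlation of estimated effects under shared true effects."""
    s2 = design.sigma2_b
    noise_d = (1 - s2 * design.h_d) / (design.n_d * design.h_d)
    noise_r = (1 - s2 * design.h_r) / (design.n_r * design.h_r)
    return float(s2 / np.sqrt((s2 + noise_d) * (s2 + noise_r)))


def expected_sign_consistency(rho: float) -> float:
    """Orthant probability: P(two standard bivariate normals share sign).

    E[P] = 1/2 + arcsin(rho)/pi.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    return float(0.5 + np.arcsin(rho) / np.pi)


def sign_consistency_test(pairs: pd.DataFrame) -> dict[str, float]:
    """Observed sign-consistency proportion and exact binomial tail vs 1/2.

    Pairs with a zero effect on either side are excluded (and counted).
    The p-value is P(X >= observed | n, 1/2), the exact upper tail.
    """
    bd = pairs["beta_d"].to_numpy(dtype=float)
    br = pairs["beta_r"].to_numpy(dtype=float)
    nonzero = (bd != 0) & (br != 0)
    consistent = int(np.sum(np.sign(bd[nonzero]) == np.sign(br[nonzero])))
    n = int(nonzero.sum())
    if n == 0:
        raise SatmapError("no nonzero effect pairs")
    pval = float(st.binom.sf(consistent - 1, n, 0.5))
    return {
        "n": n,
        "n_consistent": consistent,
        "proportion": consistent / n,
        "pval": pval,
        "n_zero_excluded": int(np.sum(~nonzero)),
    }


def align_effect_pairs(
    discovery: pd.DataFrame, replication: pd.DataFrame
) -> pd.DataFrame:
    """Join discovery and replication tables on SNP id with allele checks.

    Both tables use the canonical summary columns.  Pairs whose effect
    alleles disagree are flipped onto the discovery allele (beta and eaf
    reversed) when the replication's other_allele matches; SNPs with
    irreconcilable alleles are dropped.
    """
    merged = discovery.merge(
        replication, on="snp", suffixes=("_d", "_r"), how="inner"
    )
    if "effect_allele_d" in merged.columns and "effect_allele_r" in merged.columns:
        same = merged["effect_allele_d"] == merged["effect_allele_r"]
        flip = (~same) & (
            merged.get("other_allele_r", pd.Series(index=merged.index, dtype=object))
            == merged["effect_allele_d"]
        )
        merged.loc[flip, "beta_r"] = -merged.loc[flip, "beta_r"]
        if "eaf_r" in merged.columns:
            merged.loc[flip, "eaf_r"] = 1 - merged.loc[flip, "eaf_r"]
        merged = merged.loc[same | flip]
    cols = [c for c in ("snp", "beta_d", "se_d", "beta_r", "se_r", "eaf_d", "eaf_r") if c in merged.columns]
    out = merged[cols].copy()
    if "chrom_d" in merged.columns:
        out["chrom"] = merged["chrom_d"].to_numpy()
    return out.reset_index(drop=True)
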