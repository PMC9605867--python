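"""Polygenic-score prediction accuracy, within and between families.

A polygenic score (PGS) is a weighted sum of effect-allele dosages.
Prediction accuracy is measured as incremental R^2: the variance
explained by a linear model of the (sex-standardised) phenotype on
covariates plus the predictor, minus that of the covariate-only model.
Within-family accuracy is the squared correlation of sibling phenotype
differences with sibling PGS differences, which removes family-shared
environment by construction.

The module also provides the best linear combination of a PGS with the
parental-average phenotype under an additive polygenic model with
phenotypic assortative mating.  With heritability h2, spousal phenotypic
correlation rho and PGS accuracy r2 (all phenotypes standardised to
variance 1 in the parental generation), the child-generation second
moments implied by random transmission are

    var(PA)      = (1 + rho) / 2                    PA = parental phenotype average
    cov(y, PA)   = h2 (1 + rho) / 2
    cov(s, PA)   = r2 (1 + rho) / 2
    var(s)       = r2 (1 + rho r2 / 2)
    cov(y, s)    = r2 (1 + rho h2 / 2)
    var(y)       = 1 + rho h2^2 / 2

where the (1 + rho * /2) factors reflect the parental genetic covariance
induced by phenotypic assortment (cov(g_f, g_m) = rho h2^2, so the
child's genetic variance inflates to h2 (1 + rho h2 / 2)); at rho = 0
everything reduces to the random-mating entries var(s) = cov(y, s) = r2,
var(y) = 1.  The optimal weights are Sigma^-1 c and the combined
accuracy R^2 = c' Sigma^-1 c / var(y).  These moments are exactly those
realised by the package's family simulator
(:func:`satmap.simulate.gen_family_cohort`), which serves as the
independent check.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats import SatmapError

__all__ = [
    "FamilyModel",
    "pgs_score",
    "incremental_r2",
    "sibling_difference_r2",
    "combine_pgs_parental",
    "parent_offspring_r2",
    "family_covariance",
]


@dataclasses.dataclass(frozen=True)
class FamilyModel:
    """Population parameters of the additive family model.

    h2: narrow-sense heritability; rho_spouse: phenotypic correlation
    between spouses; r2_pgs: accuracy (variance explained) of the PGS in
    unrelated individuals of the parental generation.
    """

    h2: float
    rho_spouse: float = 0.0
    r2_pgs: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if not -1 <= self.rho_spouse <= 1:
            raise ValueError("rho_spouse must lie in [-1, 1]")
        if not 0 <= self.r2_pgs <= self.h2:
            raise ValueError("r2_pgs must lie in [0, h2]")


def pgs_score(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    dosage_alleles: Mapping[str, str] | None = None,
) -> tuple[pd.Series, dict]:
    """Weighted sum of effect-allele dosages per individual.

    Parameters
    ----------
    dosages
        Individuals x SNPs table of allele dosages in [0, 2]; columns are
        SNP ids.
    weights
        Three columns: ``snp``, ``effect_allele``, ``weight``.
    dosage_alleles
        Which allele each dosage column counts.  Columns whose counted
        allele differs from the weight's effect allele are flipped
        (dosage -> 2 - dosage).  When omitted, alleles are assumed
        aligned.

    Returns
    -------
    (scores, report)
        ``report`` lists SNPs absent from the dosage table (scoring
        proceeds on the intersection) and the number of flipped columns.
    """
    if weights["snp"].duplicated().any():
        raise SatmapError("duplicate SNP ids in the weight table")
    present = weights.loc[weights["snp"].isin(dosages.columns)]
    missing = sorted(set(weights["snp"]) - set(present["snp"]))
    mat = dosages[present["snp"].tolist()].to_numpy(dtype=float)
    w = present["weight"].to_numpy(dtype=float)
    n_flipped = 0
    if dosage_alleles is not None:
        counted = np.array([dosage_alleles[s] for s in present["snp"]])
        flip = counted != present["effect_allele"].to_numpy()
        n_flipped = int(flip.sum())
        mat = np.where(flip[None, :], 2.0 - mat, mat)
    scores = pd.Series(mat @ w, index=dosages.index, name="pgs")
    return scores, {"missing_snps": missing, "n_flipped": n_flipped}


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of OLS with an intercept (X without the constant column)."""
    X1 = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum(resid**2) / tss


def incremental_r2(
    y,
    covariates,
    predictor,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Incremental R^2 of a predictor over covariates, with bootstrap s.e.

    Fits the full model y ~ covariates + predictor and the reduced model
    y ~ covariates and returns the difference of their R^2, together with
    an individual-level bootstrap standard error (default 1,000 seeded
    resamples).  ``covariates`` may be None or an (n, p) array; the
    statistic is invariant to invertible linear reparameterisations of
    the covariates.
    """
    y = np.asarray(y, dtype=float)
    pred = np.asarray(predictor, dtype=float).reshape(len(y), -1)
    if covariates is None:
        cov = np.empty((len(y), 0))
    else:
        cov = np.asarray(covariates, dtype=float).reshape(len(y), -1)
    if len(y) <= cov.shape[1] + 2:
        raise SatmapError("too few observations for the covariate count")
    if cov.shape[1] and np.linalg.matrix_rank(
        np.column_stack([np.ones(len(y)), cov])
    ) < cov.shape[1] + 1:
        raise SatmapError("collinear covariates")
    full = np.column_stack([cov, pred])
    delta = _ols_r2(y, full) - _ols_r2(y, cov)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        boots[b] = _ols_r2(y[idx], full[idx]) - _ols_r2(y[idx], cov[idx])
    return float(delta), float(boots.std(ddof=1))


def sibling_difference_r2(pairs: pd.DataFrame) -> float:
    """Squared correlation of sibling phenotype and PGS differences.

    ``pairs`` needs columns ``y1, y2, s1, s2`` (phenotype and PGS of the
    two siblings).  Adding any family-shared constant to both siblings'
    phenotypes leaves the statistic unchanged.
    """
    if pairs.shape[0] < 30:
        raise SatmapError("sibling_difference_r2 requires at least 30 pairs")
    dy = pairs["y1"].to_numpy(dtype=float) - pairs["y2"].to_numpy(dtype=float)
    ds = pairs["s1"].to_numpy(dtype=float) - pairs["s2"].to_numpy(dtype=float)
    if np.var(dy) == 0 or np.var(ds) == 0:
        raise SatmapError("zero-variance sibling differences")
    r = np.corrcoef(dy, ds)[0, 1]
    return float(r**2)


def family_covariance(model: FamilyModel) -> tuple[np.ndarray, np.ndarray, float]:
    """Second moments of (PGS, parental average) and the child phenotype.

    Returns ``(Sigma, c, var_y)``: the 2x2 predictor covariance of
    (s, PA), the covariances of the child phenotype with each predictor,
    and the child phenotype variance, per the model documented in the
    module docstring.
    """
    h2, rho, r2 = model.h2, model.rho_spouse, model.r2_pgs
    half = (1 + rho) / 2
    sigma = np.array(
        [
            [r2 * (1 + rho * r2 / 2), r2 * half],
            [r2 * half, half],
        ]
    )
    c = np.array([r2 * (1 + rho * h2 / 2), h2 * half])
    var_y = 1 + rho * h2**2 / 2
    return sigma, c, var_y


def combine_pgs_parental(model: FamilyModel) -> dict[str, float]:
    """Best linear prediction of a child's phenotype from PGS and parental average.

    Solves the normal equations w = Sigma^-1 c for the predictor pair
    (child PGS, parental phenotype average) and reports the weights, the
    combined accuracy R^2 = c' Sigma^-1 c / var(y), and the single-
    predictor accuracies.  Degenerate cases (zero-accuracy PGS, or a
    singular predictor covariance) fall back to the informative predictor
    alone.
    """
    sigma, c, var_y = family_covariance(model)
    pa_only = c[1] ** 2 / sigma[1, 1] / var_y if sigma[1, 1] > 0 else 0.0
    pgs_only = c[0] ** 2 / sigma[0, 0] / var_y if sigma[0, 0] > 0 else 0.0
    if model.r2_pgs == 0:
        return {
            "w_pgs": 0.0,
            "w_pa": c[1] / sigma[1, 1],
            "r2_combined": pa_only,
            "r2_pgs_only": 0.0,
            "r2_pa_only": pa_only,
        }
    det = np.linalg.det(sigma)
    if det <= 1e-14:
        raise SatmapError("singular predictor covariance")
    w = np.linalg.solve(sigma, c)
    return {
        "w_pgs": float(w[0]),
        "w_pa": float(w[1]),
        "r2_combined": float(c @ w / var_y),
        "r2_pgs_only": float(pgs_only),
        "r2_pa_only": float(pa_only),
    }


def parent_offspring_r2(trios: pd.DataFrame) -> dict[str, float]:
    """Squared correlations of child phenotype with father, mother and PA.

    ``trios`` needs columns ``y, y_f, y_m``; missing parent values are
    handled pairwise-complete with counts reported.
    """
    if trios.shape[0] < 30:
        raise SatmapError("parent_offspring_r2 requires at least 30 trios")
    y = trios["y"].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for label, col in (("father", "y_f"), ("mother", "y_m")):
        v = trios[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(v)
        out[f"r2_{label}"] = float(np.corrcoef(y[ok], v[ok])[0, 1] ** 2)
        out[f"n_{label}"] = int(ok.sum())
    pa = 0.5 * (trios["y_f"].to_numpy(dtype=float) + trios["y_m"].to_numpy(dtype=float))
    ok = np.isfinite(y) & np.isfinite(pa)
    out["r2_parental_average"] = float(np.corrcoef(y[ok], pa[ok])[0, 1] ** 2)
    out["n_parental_average"] = int(ok.sum())
    return out
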