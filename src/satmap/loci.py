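"""Non-overlapping GWS loci and signal-density maps.

A *GWS locus* is built by flanking every conditionally independent
genome-wide significant SNP by a fixed window (default 35 kb) and merging,
per chromosome, runs of signals whose consecutive positions are at most
2 x flank apart — equivalently, whose flanked intervals overlap or touch
(ties at exactly 2 x flank merge).  Locus bounds are min(pos) - flank and
max(pos) + flank with no clipping at chromosome ends, so a single-signal
locus has length exactly 2 x flank (70 kb at the default).  Locus length
is defined as end - start (not +1).

The *signal density* of a signal is the number of other independent
signals on the same chromosome within a window (default 100 kb, inclusive)
on either side.  Summary statistics of the density carry standard errors
from a leave-one-chromosome-out (LOCO) jackknife.

Genome coverage divides the cumulative locus length by a fixed genome
length (default 3,039 Mb).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .sumstats import EmptyInputError

__all__ = [
    "GENOME_LENGTH_BP",
    "DEFAULT_FLANK_BP",
    "DEFAULT_DENSITY_WINDOW_BP",
    "LocusSet",
    "merge_loci",
    "signal_density",
    "density_summary",
    "loco_jackknife_se",
    "genome_coverage",
    "loci_to_bed",
]

GENOME_LENGTH_BP = 3_039_000_000
DEFAULT_FLANK_BP = 35_000
DEFAULT_DENSITY_WINDOW_BP = 100_000


@dataclasses.dataclass
class LocusSet:
    """Non-overlapping loci produced by :func:`merge_loci`.

    Attributes
    ----------
    loci : pandas.DataFrame
        Columns ``chrom, start, end, n_signals, length_bp, length_kb``,
        sorted by (chrom, start); ``member_signals`` holds, per locus, the
        integer indices of its signals in the input table.
    flank_bp : int
    genome_length_bp : int
    """

    loci: pd.DataFrame
    flank_bp: int = DEFAULT_FLANK_BP
    genome_length_bp: int = GENOME_LENGTH_BP

    def __len__(self) -> int:
        return self.loci.shape[0]

    @property
    def cumulative_length_bp(self) -> int:
        return int(self.loci["length_bp"].sum())


def merge_loci(
    signals: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
    genome_length_bp: int = GENOME_LENGTH_BP,
) -> LocusSet:
    """Chain signals into non-overlapping loci with fixed flanks.

    Parameters
    ----------
    signals
        Table with ``chrom`` and ``pos`` columns (one row per independent
        GWS signal).  Row order is irrelevant.
    flank_bp
        Half-window added on each side of every signal (default 35 kb).

    Returns
    -------
    LocusSet
        Every input signal belongs to exactly one locus; loci on the same
        chromosome do not overlap and consecutive loci are separated by
        more than 2 x flank between their nearest member signals.
    """
    if signals.shape[0] == 0:
        raise EmptyInputError("merge_loci requires at least one signal")
    if flank_bp < 0:
        raise ValueError("flank_bp must be nonnegative")
    rows = []
    for chrom, grp in signals.groupby("chrom"):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos = grp["pos"].to_numpy()[order]
        idx = grp.index.to_numpy()[order]
        gaps = np.diff(pos)
        # new locus where the gap to the previous signal exceeds 2*flank
        breaks = np.flatnonzero(gaps > 2 * flank_bp) + 1
        for seg_pos, seg_idx in zip(
            np.split(pos, breaks), np.split(idx, breaks)
        ):
            start = int(seg_pos[0]) - flank_bp
            end = int(seg_pos[-1]) + flank_bp
            rows.append(
                {
                    "chrom": int(chrom),
                    "start": start,
                    "end": end,
                    "n_signals": len(seg_pos),
                    "length_bp": end - start,
                    "member_signals": seg_idx.tolist(),
                }
            )
    loci = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
    loci["length_kb"] = loci["length_bp"] / 1_000.0
    return LocusSet(
        loci.reset_index(drop=True), flank_bp=flank_bp, genome_length_bp=genome_length_bp
    )


def signal_density(
    signals: pd.DataFrame, window_bp: int = DEFAULT_DENSITY_WINDOW_BP
) -> np.ndarray:
    """Count, per signal, the other same-chromosome signals within a window.

    The comparison is inclusive (distance <= ``window_bp``) and symmetric:
    if t counts for s then s counts for t, so the densities sum to an even
    number.  Returns an integer array aligned with the input rows.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    dens = np.zeros(signals.shape[0], dtype=int)
    positions = signals["pos"].to_numpy()
    chroms = signals["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        pos = positions[mask]
        srt = np.sort(pos)
        lo = np.searchsorted(srt, pos - window_bp, side="left")
        hi = np.searchsorted(srt, pos + window_bp, side="right")
        dens[mask] = hi - lo - 1  # exclude the signal itself
    return dens


def loco_jackknife_se(values: np.ndarray, chroms: np.ndarray, stat) -> float:
    """Leave-one-chromosome-out jackknife s.e. of ``stat(values)``.

    se = sqrt(((k-1)/k) * sum_j (theta_{-j} - mean_j theta_{-j})^2) over
    the k represented chromosomes.  Returns NaN when fewer than two
    chromosomes are represented.
    """
    uniq = np.unique(chroms)
    k = uniq.size
    if k < 2:
        return float("nan")
    theta = np.array([stat(values[chroms != c]) for c in uniq], dtype=float)
    return float(np.sqrt((k - 1) / k * np.sum((theta - theta.mean()) ** 2)))


def density_summary(densities: np.ndarray, chroms: np.ndarray) -> dict[str, float]:
    """Summarise a density map with LOCO jackknife standard errors.

    Returns mean, median, the share of signals with density >= 1, and the
    LOCO jackknife s.e. of the mean and of the median (NaN when a single
    chromosome is represented).
    """
    densities = np.asarray(densities, dtype=float)
    chroms = np.asarray(chroms)
    if densities.size == 0:
        raise EmptyInputError("density_summary requires at least one signal")
    return {
        "mean": float(densities.mean()),
        "median": float(np.median(densities)),
        "share_ge_1": float(np.mean(densities >= 1)),
        "se_mean": loco_jackknife_se(densities, chroms, np.mean),
        "se_median": loco_jackknife_se(densities, chroms, np.median),
    }


def genome_coverage(locus_set: LocusSet) -> tuple[float, int]:
    """Fraction of the genome covered by the loci, with cumulative length.

    Returns ``(fraction, cumulative_length_bp)`` where fraction divides
    the cumulative locus length by the configured genome length.
    """
    cumulative = locus_set.cumulative_length_bp
    return cumulative / locus_set.genome_length_bp, cumulative


def loci_to_bed(locus_set: LocusSet, path) -> None:
    """Write loci as BED (0-based, half-open: start-1 .. end).

    The in-memory convention is 1-based closed; the conversion happens
    only at this writer boundary.
    """
    bed = pd.DataFrame(
        {
            "chrom": "chr" + locus_set.loci["chrom"].astype(str),
            "start": locus_set.loci["start"] - 1,
            "end": locus_set.loci["end"],
            "name": [
                f"locus_{i+1}_n{n}"
                for i, n in enumerate(locus_set.loci["n_signals"])
            ],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
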