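"""Effective population size across past generations from binned r^2.

Under drift-recombination equilibrium the expected r^2 between markers at
genetic distance c Morgan reflects the effective size roughly 1/(2c)
generations ago, giving the estimator

    Ne = (1 / (4c)) * (1 / mean_r2 - 1),      T = 1 / (2c)

with mean r^2 taken over pairs grouped into four distance bins
(0, 0.01], (0.01, 0.03], (0.03, 0.05] and (0.05, 0.125] Morgan, whose
representative distances c = 0.01, 0.03, 0.05 and 0.1 correspond to
generations 50, 16.6, 10 and 5.  Physical distance converts to genetic
distance at 1 Mb = 1 cM.  No sampling-size correction is applied to mean
r^2, so estimates at small sample sizes carry a downward bias absorbed by
wide validation bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MORGAN_PER_BP, GenotypeMatrix
from .ld import pairwise_r2

__all__ = ["bin_mean_r2", "ne_at", "ne_trajectory", "NeTrajectory",
           "DEFAULT_BIN_EDGES_MORGAN", "DEFAULT_MAX_MORGAN", "REPRESENTATIVE_C"]

#: Inner bin edges in Morgan; the open-ended last bin is capped.
DEFAULT_BIN_EDGES_MORGAN: tuple[float, ...] = (0.01, 0.03, 0.05)
#: Cap of the last bin (12.5 Mb at 1 cM/Mb).
DEFAULT_MAX_MORGAN: float = 0.125
#: Representative genetic distance per bin, chosen as 1/(2T) for the
#: reported generations T = 50, 16.6..., 10, 5.
REPRESENTATIVE_C: tuple[float, ...] = (0.01, 0.03, 0.05, 0.1)


def bin_mean_r2(
    pairs: pd.DataFrame,
    bin_edges_morgan=DEFAULT_BIN_EDGES_MORGAN,
    max_morgan: float = DEFAULT_MAX_MORGAN,
) -> pd.DataFrame:
    """Arithmetic mean r^2 per genetic-distance bin.

    Bins are left-open/right-closed between 0, the given edges, and
    ``max_morgan``.  Empty bins are flagged (``n_pairs = 0``,
    ``mean_r2 = NaN``) rather than fabricated.
    """
    edges = [0.0, *bin_edges_morgan, max_morgan]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly increasing: {edges}")
    c = pairs["dist_bp"].to_numpy(dtype=np.float64) * MORGAN_PER_BP
    r2 = pairs["r2"].to_numpy(dtype=np.float64)
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        sel = (c > lo) & (c <= hi)
        n = int(sel.sum())
        rows.append({
            "bin_lo_morgan": lo,
            "bin_hi_morgan": hi,
            "n_pairs": n,
            "mean_r2": float(r2[sel].mean()) if n else np.nan,
        })
    return pd.DataFrame(rows)


def ne_at(c_morgan: float, mean_r2: float) -> tuple[float, float]:
    """Generations ago and effective size for one (c, mean r^2) point.

    Returns (T, Ne) with T = 1/(2c) and Ne = (1/(4c)) (1/mean_r2 - 1).

    Raises
    ------
    ValueError
        If c <= 0 or mean_r2 is outside (0, 1]; mean_r2 = 0 would imply
        infinite Ne and is rejected rather than returned.
    """
    if not c_morgan > 0:
        raise ValueError(f"c must be > 0 Morgan, got {c_morgan}")
    if not 0.0 < mean_r2 <= 1.0:
        raise ValueError(f"mean r^2 must be in (0, 1], got {mean_r2}")
    t = 1.0 / (2.0 * c_morgan)
    ne = (1.0 / (4.0 * c_morgan)) * (1.0 / mean_r2 - 1.0)
    return t, ne


@dataclass
class NeTrajectory:
    """Per-generation effective-size estimates for one population.

    ``table`` rows: generation T, representative c (Morgan), mean r^2,
    pair count, Ne.  ``delta_ne`` is Ne(T=50) - Ne(T=5), the oldest-vs-
    newest contrast (NaN when either bin is empty).
    """

    population: str
    table: pd.DataFrame

    @property
    def delta_ne(self) -> float:
        t = self.table.set_index("T")["Ne"]
        try:
            return float(t.loc[50.0] - t.loc[5.0])
        except KeyError:
            return float("nan")

    def ne_at_generation(self, t: float) -> float:
        row = self.table.loc[np.isclose(self.table["T"], t)]
        return float(row["Ne"].iloc[0]) if len(row) else float("nan")


def ne_trajectory(
    geno: GenotypeMatrix,
    bin_edges_morgan=DEFAULT_BIN_EDGES_MORGAN,
    max_morgan: float = DEFAULT_MAX_MORGAN,
    representative_c=REPRESENTATIVE_C,
    population: str | None = None,
    pairs: pd.DataFrame | None = None,
) -> NeTrajectory:
    """Estimate Ne per past generation from a genotype panel.

    Runs a wide pair scan out to ``max_morgan`` (no index-separation
    limit — deliberately wider than the LD-decay default window), bins
    mean r^2, and maps each bin to (T, Ne) at its representative genetic
    distance.  Rows for empty bins carry NaN Ne.
    """
    if population is None:
        population = geno.samples["breed"].iloc[0] if geno.n_samples else "NA"
    if pairs is None:
        pairs = pairwise_r2(
            geno, max_dist_kb=max_morgan / MORGAN_PER_BP / 1000.0,
            max_snp_sep=None, population=population,
        )
    binned = bin_mean_r2(pairs, bin_edges_morgan, max_morgan)
    if len(binned) != len(representative_c):
        raise ValueError(
            f"{len(binned)} bins but {len(representative_c)} representative distances"
        )
    rows = []
    for (_, b), c in zip(binned.iterrows(), representative_c):
        t = 1.0 / (2.0 * c)
        if b["n_pairs"] > 0 and b["mean_r2"] > 0:
            _, ne = ne_at(c, b["mean_r2"])
        else:
            ne = np.nan
        rows.append({
            "population": population, "T": t, "c_morgan": c,
            "mean_r2": b["mean_r2"], "n_pairs": int(b["n_pairs"]), "Ne": ne,
        })
    return NeTrajectory(population=population, table=pd.DataFrame(rows))
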