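"""Core containers shared by every analysis stage.

A genotype panel is held as a dense dosage matrix (samples x markers) of
minor-allele counts in {0, 1, 2} with a dedicated missing sentinel, plus a
marker map and per-sample breed labels.  Physical positions are 1-based bp;
genetic positions assume the cattle-standard 1 Mb = 1 cM conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-genotype sentinel in dosage matrices.  Distinct from dosage 0.
MISSING: int = -1

#: Morgan per bp under the 1 Mb = 1 cM convention.
MORGAN_PER_BP: float = 1e-8


class PanelError(ValueError):
    """Raised for malformed or degenerate genotype panels."""


def marker_map(
    marker_id, chromosome, position_bp, *, sort: bool = True
) -> pd.DataFrame:
    """Build a marker map frame with derived genetic positions.

    Parameters
    ----------
    marker_id, chromosome, position_bp
        Per-marker identifier, chromosome label (opaque string), and
        1-based physical position.
    sort
        Sort by (chromosome, position) and check positions are strictly
        increasing within each chromosome.

    Returns
    -------
    DataFrame with columns ``marker_id, chrom, pos_bp, genetic_pos_morgan``.
    """
    m = pd.DataFrame(
        {
            "marker_id": np.asarray(marker_id, dtype=object),
            "chrom": np.asarray(chromosome, dtype=object).astype(str),
            "pos_bp": np.asarray(position_bp, dtype=np.int64),
        }
    )
    if (m["pos_bp"] < 1).any():
        bad = m.loc[m["pos_bp"] < 1, "marker_id"].iloc[0]
        raise PanelError(f"marker {bad!r}: position_bp must be >= 1 (1-based)")
    if sort:
        m = m.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        dup = m.duplicated(["chrom", "pos_bp"])
        if dup.any():
            bad = m.loc[dup, "marker_id"].iloc[0]
            raise PanelError(f"marker {bad!r}: duplicate position on its chromosome")
    m["genetic_pos_morgan"] = m["pos_bp"].to_numpy(dtype=np.float64) * MORGAN_PER_BP
    return m


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix with metadata.

    Attributes
    ----------
    samples : DataFrame
        Columns ``sample_id`` and ``breed``; row order matches matrix rows.
    markers : DataFrame
        Marker map (see :func:`marker_map`); row order matches columns.
    dosages : ndarray of int8
        Entries in {0, 1, 2, MISSING}.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise PanelError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise PanelError("dosages must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with missing calls as NaN."""
        x = self.dosages.astype(np.float64)
        x[self.dosages == MISSING] = np.nan
        return x

    def breeds(self) -> list[str]:
        """Distinct breed labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["breed"]))

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            samples=self.samples.iloc[si].reset_index(drop=True),
            markers=self.markers.iloc[mi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, mi)],
        )

    def by_breed(self, breed: str) -> "GenotypeMatrix":
        """Sub-panel of the samples carrying the given breed label."""
        idx = np.flatnonzero((self.samples["breed"] == breed).to_numpy())
        if idx.size == 0:
            raise PanelError(f"no samples with breed label {breed!r}")
        return self.subset(sample_idx=idx)


@dataclass
class QCReport:
    """Bookkeeping from :func:`bovarch.io.qc_filter`."""

    n_markers_in: int
    n_samples_in: int
    markers_removed_callrate: int = 0
    markers_removed_maf: int = 0
    samples_removed_callrate: int = 0
    marker_call_rate: float = 0.95
    maf_min: float = 0.01
    sample_call_rate: float = 0.85

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - self.markers_removed_callrate - self.markers_removed_maf

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_callrate

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, getattr(self, k)) for k in (
            "n_markers_in", "n_samples_in", "markers_removed_callrate",
            "markers_removed_maf", "samples_removed_callrate",
            "marker_call_rate", "maf_min", "sample_call_rate",
        )]
        rows += [("n_markers_out", self.n_markers_out), ("n_samples_out", self.n_samples_out)]
        return pd.DataFrame(rows, columns=["field", "value"])
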