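"""Genotype panel I/O, quality control, and per-marker summaries.

Supports the PLINK 1.x whitespace-delimited PED/MAP text dialect and a
plain dosage-matrix TSV (rows = samples, header = marker ids, cells
0/1/2/NA).  Alleles are recoded on read to minor-allele dosage per marker;
"0" is the conventional missing-allele code.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PanelError, QCReport, marker_map

logger = logging.getLogger(__name__)

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "qc_filter",
    "allele_frequencies",
    "marker_call_rates",
    "sample_call_rates",
    "minor_allele_frequencies",
]


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PanelError(f"{map_path}: line {ln}: expected 4 columns, got {len(parts)}")
            chrom, mid, _gpos, bp = parts[:4]
            rows.append((mid, chrom, int(bp)))
    if not rows:
        raise PanelError(f"{map_path}: empty MAP file")
    mid, chrom, bp = zip(*rows)
    return marker_map(mid, chrom, bp, sort=False)


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a PED/MAP pair into a minor-allele dosage matrix.

    PED rows carry 6 metadata columns (family, individual, father, mother,
    sex, phenotype) followed by two allele columns per marker.  The family
    id becomes the breed label.  Allele pairs "0 0" become missing.  Per
    marker the minor allele is the less frequent one across the panel,
    lexicographically smaller on a 0.5/0.5 tie; dosage counts minor-allele
    copies.  Markers are returned sorted by (chromosome, position).

    Raises
    ------
    PanelError
        On a PED/MAP dimension mismatch (names the offending row) or a
        marker with more than two distinct alleles (names the marker).
    """
    unsorted_map = _read_map(map_path)
    n_markers = len(unsorted_map)

    fam, iid = [], []
    a1_rows, a2_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise PanelError(
                    f"{ped_path}: row {ln} (sample {parts[1] if len(parts) > 1 else '?'}): "
                    f"expected {6 + 2 * n_markers} fields for {n_markers} MAP markers, "
                    f"got {len(parts)}"
                )
            fam.append(parts[0])
            iid.append(parts[1])
            alleles = parts[6:]
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])
    if not fam:
        raise PanelError(f"{ped_path}: empty PED file")

    a1 = np.asarray(a1_rows, dtype=object)
    a2 = np.asarray(a2_rows, dtype=object)
    n_samples = len(fam)
    dosages = np.full((n_samples, n_markers), MISSING, dtype=np.int8)

    for j in range(n_markers):
        c1, c2 = a1[:, j], a2[:, j]
        miss = (c1 == "0") | (c2 == "0")
        observed = np.concatenate([c1[~miss], c2[~miss]])
        symbols, counts = np.unique(observed, return_counts=True)
        if len(symbols) > 2:
            raise PanelError(
                f"marker {unsorted_map['marker_id'].iloc[j]!r}: more than two alleles "
                f"({', '.join(map(str, symbols))})"
            )
        if len(symbols) == 0:
            continue  # all missing; stays MISSING
        if len(symbols) == 1:
            minor = None  # monomorphic: every non-missing call has dosage 0
        elif counts[0] < counts[1]:
            minor = symbols[0]
        elif counts[1] < counts[0]:
            minor = symbols[1]
        else:  # exact tie: lexicographically smaller symbol is the minor
            minor = min(symbols)
        ok = ~miss
        if minor is None:
            dosages[ok, j] = 0
        else:
            dosages[ok, j] = (c1[ok] == minor).astype(np.int8) + (c2[ok] == minor).astype(np.int8)

    order = unsorted_map.sort_values(["chrom", "pos_bp"], kind="stable").index.to_numpy()
    markers = marker_map(
        unsorted_map["marker_id"].to_numpy()[order],
        unsorted_map["chrom"].to_numpy()[order],
        unsorted_map["pos_bp"].to_numpy()[order],
        sort=False,
    )
    samples = pd.DataFrame({"sample_id": iid, "breed": fam})
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dosages[:, order])


def write_ped_map(geno: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a panel back to PED/MAP text.

    Dosages are encoded with synthetic alleles A (major) / B (minor), so a
    read/write round trip preserves dosages and positions exactly.
    """
    with open(map_path, "w") as fh:
        for _, m in geno.markers.iterrows():
            fh.write(f"{m.chrom}\t{m.marker_id}\t{m.pos_bp * 1e-6:g}\t{m.pos_bp}\n")
    code = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, s in geno.samples.iterrows():
            geno_str = " ".join(code[int(d)] for d in geno.dosages[i])
            fh.write(f"{s.breed} {s.sample_id} 0 0 0 -9 {geno_str}\n")


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as TSV: rows = samples, NA = missing."""
    x = pd.DataFrame(
        geno.dosages.astype(object),
        index=pd.Index(geno.samples["sample_id"], name="sample_id"),
        columns=geno.markers["marker_id"],
    )
    x[geno.dosages == MISSING] = "NA"
    x.insert(0, "breed", geno.samples["breed"].to_numpy())
    x.to_csv(path, sep="\t")


def read_dosage_tsv(path, map_path=None, markers: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a dosage TSV written by :func:`write_dosage_tsv`.

    A marker map must come from ``map_path`` (MAP text) or ``markers``;
    marker ids must match the TSV header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    breed = df.pop("breed").astype(str)
    if markers is None:
        if map_path is None:
            raise PanelError("read_dosage_tsv needs map_path or markers")
        markers = _read_map(map_path)
        markers = markers.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        markers = marker_map(markers["marker_id"], markers["chrom"], markers["pos_bp"], sort=False)
    if list(df.columns) != list(markers["marker_id"]):
        df = df.reindex(columns=list(markers["marker_id"]))
        if df.isna().all(axis=None):
            raise PanelError("dosage TSV marker ids do not match the marker map")
    x = df.to_numpy(dtype=object)
    dosages = np.full(x.shape, MISSING, dtype=np.int8)
    ok = ~pd.isna(x) & (x != "NA")
    dosages[ok] = np.asarray(x[ok], dtype=np.float64).astype(np.int8)
    samples = pd.DataFrame({"sample_id": df.index.astype(str), "breed": breed.to_numpy()})
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dosages)


def marker_call_rates(geno: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per marker."""
    return (geno.dosages != MISSING).mean(axis=0)


def sample_call_rates(geno: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample."""
    return (geno.dosages != MISSING).mean(axis=1)


def minor_allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF over non-missing calls (NaN where all calls missing)."""
    p = _counted_allele_freq(geno.dosages)
    return np.minimum(p, 1.0 - p)


def _counted_allele_freq(dosages: np.ndarray) -> np.ndarray:
    ok = dosages != MISSING
    n = ok.sum(axis=0)
    tot = np.where(ok, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, tot / (2.0 * n), np.nan)


def qc_filter(
    geno: GenotypeMatrix,
    marker_call_rate: float = 0.95,
    maf_min: float = 0.01,
    sample_call_rate: float = 0.85,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker then sample quality filters in a single pass.

    A marker is removed iff its call rate is below ``marker_call_rate`` or
    its MAF is below ``maf_min`` (markers failing both count against the
    call-rate tally).  Sample call rates are then computed on the retained
    markers; samples below ``sample_call_rate`` are removed.  Marker
    statistics are not recomputed after sample removal: the pass is
    deterministic and idempotent.

    Raises
    ------
    PanelError
        If every marker is removed ("empty panel").
    """
    for name, v in (("marker_call_rate", marker_call_rate), ("maf_min", maf_min),
                    ("sample_call_rate", sample_call_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    cr = marker_call_rates(geno)
    maf = minor_allele_frequencies(geno)
    fail_cr = cr < marker_call_rate
    # NaN MAF means zero non-missing calls, already caught by any call-rate
    # threshold > 0; NaN never fails the MAF filter so (0, 0, 0) is identity
    fail_maf = ~fail_cr & ~np.isnan(maf) & (maf < maf_min)
    keep_m = ~(fail_cr | fail_maf)
    if not keep_m.any():
        raise PanelError("QC removed every marker: empty panel")

    filtered = geno.subset(marker_idx=np.flatnonzero(keep_m))
    scr = sample_call_rates(filtered)
    keep_s = scr >= sample_call_rate
    out = filtered.subset(sample_idx=np.flatnonzero(keep_s))

    report = QCReport(
        n_markers_in=geno.n_markers,
        n_samples_in=geno.n_samples,
        markers_removed_callrate=int(fail_cr.sum()),
        markers_removed_maf=int(fail_maf.sum()),
        samples_removed_callrate=int((~keep_s).sum()),
        marker_call_rate=marker_call_rate,
        maf_min=maf_min,
        sample_call_rate=sample_call_rate,
    )
    logger.info(
        "QC: %d/%d markers removed (call rate %d, MAF %d); %d/%d samples removed",
        report.markers_removed_callrate + report.markers_removed_maf, geno.n_markers,
        report.markers_removed_callrate, report.markers_removed_maf,
        report.samples_removed_callrate, geno.n_samples,
    )
    return out, report


def allele_frequencies(geno: GenotypeMatrix, by_breed: bool = False) -> pd.DataFrame:
    """Counted-allele frequency per marker, overall or per breed.

    Frequency = (sum of dosages) / (2 x non-missing count).  A population
    with zero non-missing calls at a marker yields NaN there, never 0.

    Returns
    -------
    DataFrame indexed by marker_id with one column per population (or a
    single ``all`` column).
    """
    if by_breed:
        cols = {b: _counted_allele_freq(geno.by_breed(b).dosages) for b in geno.breeds()}
    else:
        cols = {"all": _counted_allele_freq(geno.dosages)}
    return pd.DataFrame(cols, index=pd.Index(geno.markers["marker_id"], name="marker_id"))
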