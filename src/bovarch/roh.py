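"""Runs of homozygosity: sliding-window calling, length classes, shared
islands, and gene annotation.

The caller mirrors the PLINK sliding-window approach: a window of
``window_snp`` consecutive markers is homozygous when it holds at most
``window_het_max`` heterozygotes and ``window_missing_max`` missing calls;
each marker is scored by the fraction of covering windows that are
homozygous; maximal stretches of markers scoring above
``window_hit_threshold`` become candidate runs, split at large inter-marker
gaps and filtered on physical length and SNP count.  Islands are regions
where more than half of a population's individuals carry a run.

Coordinates are 1-based inclusive marker positions; segment and island
length is end - start (the convention of the downstream report tables).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ROHParams", "window_scan", "call_roh", "call_roh_panel",
    "roh_length_summary", "find_islands", "island_length",
    "annotate_islands", "read_gene_intervals", "write_segments_tsv",
    "write_islands_bed",
]


@dataclass
class ROHParams:
    """Sliding-window ROH parameters (defaults: dense-array cattle panel).

    window_snp
        Scanning window size in markers.
    window_het_max / window_missing_max
        Heterozygote and missing-call budgets for a window to count as
        homozygous.  Missing calls never count as heterozygotes.
    window_hit_threshold
        Minimum fraction of homozygous covering windows for a marker to
        join a run (strict >).
    min_length_kb / min_snp
        Minimum physical length and marker count of an emitted segment.
    min_density_snp
        Optional per-segment floor on markers per Mb-scale density
        (disabled by default; its precise intent in published parameter
        lists is ambiguous, so it is exposed but off).
    max_gap_kb
        Runs are split where adjacent markers are further apart than this.
    """

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    min_length_kb: float = 1000.0
    min_snp: int = 120
    min_density_snp: int | None = None
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("window_snp", "window_het_max", "window_missing_max",
                     "min_snp", "min_length_kb", "max_gap_kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.window_snp < 1:
            raise ValueError("window_snp must be >= 1")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must be in (0, 1]")


SEGMENT_COLUMNS = ["sample_id", "breed", "chrom", "start_bp", "end_bp",
                   "length_bp", "n_snp", "n_het", "n_missing"]
ISLAND_COLUMNS = ["population", "chrom", "start_bp", "end_bp", "length_bp",
                  "n_snp", "carrier_fraction", "genes"]


def _window_sums(flags: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of a 0/1 vector for all length-w windows."""
    c = np.concatenate([[0], np.cumsum(flags)])
    return c[w:] - c[:-w]


def window_scan(dosages_1d: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-marker homozygous-window proportion for one sample+chromosome.

    ``dosages_1d`` is the dosage vector of the chromosome's markers in map
    order.  When the chromosome carries fewer markers than ``window_snp``,
    the single truncated window spanning the whole chromosome scores every
    marker.
    """
    d = np.asarray(dosages_1d)
    m = d.size
    het = (d == 1).astype(np.int64)
    miss = (d == MISSING).astype(np.int64)
    w = min(params.window_snp, m)
    hom_win = (
        (_window_sums(het, w) <= params.window_het_max)
        & (_window_sums(miss, w) <= params.window_missing_max)
    ).astype(np.float64)
    # windows covering marker i: starts in [i-w+1, i] clipped to [0, m-w]
    cw = np.concatenate([[0.0], np.cumsum(hom_win)])
    i = np.arange(m)
    lo = np.clip(i - w + 1, 0, m - w)
    hi = np.clip(i, 0, m - w)
    covered_hom = cw[hi + 1] - cw[lo]
    n_windows = hi - lo + 1
    return covered_hom / n_windows


def _runs(mask: np.ndarray):
    """(start, end) index pairs (inclusive) of maximal True stretches."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    return list(zip(starts, ends))


def call_roh(
    scores: np.ndarray,
    dosages_1d: np.ndarray,
    positions_bp: np.ndarray,
    params: ROHParams,
) -> list[tuple[int, int, int, int, int]]:
    """Segments for one sample on one chromosome.

    Candidate runs are maximal marker stretches with score strictly above
    ``window_hit_threshold``, split where adjacent markers are more than
    ``max_gap_kb`` apart; a run is emitted iff its physical length
    (end - start) reaches ``min_length_kb`` AND it holds ``min_snp``
    markers.  Returns tuples (start_idx, end_idx, n_snp, n_het, n_missing)
    with inclusive marker indices.
    """
    d = np.asarray(dosages_1d)
    pos = np.asarray(positions_bp, dtype=np.int64)
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    out = []
    for s, e in _runs(scores > params.window_hit_threshold):
        # split on large physical gaps
        gaps = np.flatnonzero(np.diff(pos[s:e + 1]) > max_gap_bp) + s
        bounds = [s, *(g + 1 for g in gaps), e + 1]
        for a, b in zip(bounds, bounds[1:]):
            b -= 1
            n_snp = b - a + 1
            length = pos[b] - pos[a]
            if length < min_len_bp or n_snp < params.min_snp:
                continue
            if params.min_density_snp is not None:
                # density floor: markers per Mb of segment
                if n_snp < params.min_density_snp * length / 1e6:
                    continue
            seg = d[a:b + 1]
            out.append((int(a), int(b), n_snp, int((seg == 1).sum()),
                        int((seg == MISSING).sum())))
    return out


def call_roh_panel(geno: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Call ROH for every sample of a panel.

    Returns a segment table with columns ``sample_id, breed, chrom,
    start_bp, end_bp, length_bp, n_snp, n_het, n_missing``, ordered by
    sample then genome position (invariant to input sample order up to
    that sort).
    """
    params = params or ROHParams()
    mk = geno.markers
    rows = []
    for chrom, idx in mk.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = mk["pos_bp"].to_numpy()[idx]
        for i in range(geno.n_samples):
            d = geno.dosages[i, idx]
            scores = window_scan(d, params)
            for a, b, n_snp, n_het, n_miss in call_roh(scores, d, pos, params):
                rows.append({
                    "sample_id": geno.samples["sample_id"].iloc[i],
                    "breed": geno.samples["breed"].iloc[i],
                    "chrom": chrom,
                    "start_bp": int(pos[a]),
                    "end_bp": int(pos[b]),
                    "length_bp": int(pos[b] - pos[a]),
                    "n_snp": n_snp, "n_het": n_het, "n_missing": n_miss,
                })
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return df.sort_values(["sample_id", "chrom", "start_bp"], kind="stable").reset_index(drop=True)


DEFAULT_CATEGORIES_MB: tuple[float, ...] = (5.0, 10.0, 20.0, 31.0)


def roh_length_summary(
    segments: pd.DataFrame,
    categories_mb=DEFAULT_CATEGORIES_MB,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Total ROH length per sample and percentage per length class.

    Segment lengths are binned into (min_len, c1], (c1, c2], ..., (ck, inf)
    Mb classes.  Returns (per_sample, per_population): per-sample total
    length per class, and per-population percentages
    100 * class_sum / total ROH length (zeros when a population has no
    ROH).
    """
    edges = [0.0, *categories_mb, np.inf]
    names = [f"<={hi:g}Mb" if np.isfinite(hi) else f">{lo:g}Mb"
             for lo, hi in zip(edges, edges[1:])]
    names[0] = f"<{edges[1]:g}Mb"
    if segments.empty:
        per_sample = pd.DataFrame(columns=["sample_id", "breed", *names])
        per_pop = pd.DataFrame(columns=["breed", *names])
        return per_sample, per_pop
    seg = segments.copy()
    seg["length_mb"] = seg["length_bp"] / 1e6
    seg["category"] = pd.cut(seg["length_mb"], bins=edges, labels=names, right=True)
    per_sample = (
        seg.pivot_table(index=["sample_id", "breed"], columns="category",
                        values="length_bp", aggfunc="sum", fill_value=0, observed=False)
        .reindex(columns=names, fill_value=0).reset_index()
    )
    per_sample.columns.name = None
    pop_sum = (
        seg.pivot_table(index="breed", columns="category", values="length_bp",
                        aggfunc="sum", fill_value=0, observed=False)
        .reindex(columns=names, fill_value=0)
    )
    total = pop_sum.sum(axis=1)
    per_pop = pop_sum.div(total.where(total > 0, 1.0), axis=0) * 100.0
    per_pop.columns.name = None
    return per_sample, per_pop.reset_index()


def island_length(start_bp: int, end_bp: int) -> int:
    """Region length as end - start (the report-table convention)."""
    if start_bp >= end_bp:
        raise ValueError(f"start_bp {start_bp} must be < end_bp {end_bp}")
    return int(end_bp) - int(start_bp)


def find_islands(
    segments: pd.DataFrame,
    markers: pd.DataFrame,
    n_samples: int,
    threshold: float = 0.5,
    population: str = "NA",
) -> pd.DataFrame:
    """Regions where ROH incidence exceeds ``threshold`` (strictly).

    Per-marker incidence is the fraction of the population's individuals
    whose segments cover the marker; islands are maximal marker runs with
    incidence > threshold, with bounds at the outermost qualifying markers
    and ``carrier_fraction`` the minimum incidence across the island.
    Invariant to segment input order.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rows = []
    for chrom, idx in markers.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = markers["pos_bp"].to_numpy()[idx]
        cover = np.zeros(pos.size, dtype=np.int64)
        segs = segments.loc[segments["chrom"] == chrom]
        # one sample may have several segments; a marker counts once per sample
        for _sid, ss in segs.groupby("sample_id", sort=False):
            hit = np.zeros(pos.size, dtype=bool)
            for _, r in ss.iterrows():
                a = np.searchsorted(pos, r["start_bp"], side="left")
                b = np.searchsorted(pos, r["end_bp"], side="right")
                hit[a:b] = True
            cover += hit
        incidence = cover / n_samples
        for a, b in _runs(incidence > threshold):
            rows.append({
                "population": population,
                "chrom": chrom,
                "start_bp": int(pos[a]),
                "end_bp": int(pos[b]),
                "length_bp": island_length(pos[a], pos[b]) if pos[b] > pos[a] else 0,
                "n_snp": int(b - a + 1),
                "carrier_fraction": float(incidence[a:b + 1].min()),
                "genes": "",
            })
    df = pd.DataFrame(rows, columns=ISLAND_COLUMNS)
    return df.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)


def read_gene_intervals(path) -> pd.DataFrame:
    """Load gene intervals from BED (0-based half-open) or GFF3.

    BED start coordinates are shifted to the package's 1-based inclusive
    convention.  For GFF3 only ``gene`` features are kept and the gene id
    comes from the ``ID`` (falling back to ``Name``/``gene_id``) attribute.
    Returns columns ``chrom, start_bp, end_bp, gene_id``.
    """
    path = str(path)
    rows = []
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("Name") or attrs.get("gene_id") or f[8]
                rows.append((f[0], int(f[3]), int(f[4]), gid))
    else:  # BED
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                f = line.split()
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                rows.append((f[0], int(f[1]) + 1, int(f[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "gene_id"])


def annotate_islands(islands: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach overlapping gene ids to each island (any-overlap, >= 1 bp).

    Both tables use 1-based inclusive coordinates; gene ids are listed in
    genomic order, comma-separated.  Genes on chromosome labels absent
    from the island table trigger a single warning and are skipped.
    """
    out = islands.copy()
    known = set(out["chrom"].astype(str))
    unknown = sorted(set(genes["chrom"].astype(str)) - known)
    if unknown:
        warnings.warn(
            f"gene annotation chromosomes not present among islands, skipped: "
            f"{', '.join(unknown)}", stacklevel=2,
        )
    g = genes.sort_values(["chrom", "start_bp"], kind="stable")
    gene_lists = []
    for _, isl in out.iterrows():
        sel = g.loc[
            (g["chrom"].astype(str) == str(isl["chrom"]))
            & (g["start_bp"] <= isl["end_bp"])
            & (g["end_bp"] >= isl["start_bp"])
        ]
        gene_lists.append(",".join(sel["gene_id"].astype(str)))
    out["genes"] = gene_lists
    return out


def write_segments_tsv(segments: pd.DataFrame, path) -> None:
    """Write segments in a PLINK ``.hom``-style column layout."""
    df = pd.DataFrame({
        "FID": segments["breed"], "IID": segments["sample_id"],
        "CHR": segments["chrom"], "POS1": segments["start_bp"],
        "POS2": segments["end_bp"],
        "KB": segments["length_bp"] / 1000.0,
        "NSNP": segments["n_snp"],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_islands_bed(islands: pd.DataFrame, path) -> None:
    """Write islands as BED (coordinates converted to 0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in islands.iterrows():
            name = f"{r['population']}_island"
            fh.write(f"{r['chrom']}\t{r['start_bp'] - 1}\t{r['end_bp']}\t{name}\t"
                     f"{r['carrier_fraction']:.4f}\n")
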