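"""Breed-level structure: allele-frequency distances, neighbor-joining
trees, and genotype PCA.

Populations are compared by the Euclidean distance between their
allele-frequency vectors over shared markers.  The distance matrix feeds
Saitou-Nei neighbor joining (deterministic tie-breaking, negative branch
lengths clamped to zero); individual-level structure comes from an
eigen-decomposition of the centered dosage matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["population_distance", "nj_tree", "genotype_pca", "ld_prune",
           "PhyloTree", "PCAResult"]


def population_distance(freqs: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between population allele-frequency vectors.

    ``freqs`` is markers x populations (as from
    :func:`bovarch.io.allele_frequencies` with ``by_breed=True``); markers
    with an undefined (NaN) frequency in any population are dropped first
    and the count logged.  Requires >= 2 populations.
    """
    if freqs.shape[1] < 2:
        raise ValueError("need >= 2 populations for a distance matrix")
    complete = freqs.dropna(axis=0)
    dropped = len(freqs) - len(complete)
    if dropped:
        logger.info("population_distance: dropped %d markers with undefined frequencies", dropped)
    if complete.empty:
        raise ValueError("no markers with defined frequencies in all populations")
    x = complete.to_numpy(dtype=np.float64).T  # populations x markers
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(sq)
    return pd.DataFrame(d, index=freqs.columns, columns=freqs.columns)


@dataclass
class _Node:
    name: str | None
    children: list[tuple["_Node", float]] = field(default_factory=list)
    # deterministic tie-break key: smallest leaf label under this node
    key: str = ""

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree from neighbor joining."""

    newick: str
    leaves: list[str]
    n_negative_clamped: int = 0


def nj_tree(dist: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbor joining on a labelled distance matrix.

    Standard Q-matrix agglomeration with the usual branch-length formulas.
    Ties in Q are broken by the lexicographically lowest pair of node keys
    (a node's key is the smallest leaf label it contains), so the result
    is independent of input order.  Negative branch lengths are clamped to
    zero and counted.  Requires >= 3 populations and a symmetric matrix.
    """
    labels = list(map(str, dist.index))
    if len(labels) < 3:
        raise ValueError("need >= 3 populations for neighbor joining")
    d = dist.to_numpy(dtype=np.float64)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")

    nodes: list[_Node] = [_Node(name=l, key=l) for l in labels]
    dm = {(i, j): d[i, j] for i in range(len(labels)) for j in range(len(labels))}
    active = list(range(len(labels)))
    next_id = len(labels)
    n_clamped = 0

    def get(i, j):
        return 0.0 if i == j else dm[(min(i, j), max(i, j))]

    node_of = {i: nodes[i] for i in active}

    while len(active) > 3:
        n = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * get(i, j) - r[i] - r[j]
                key = tuple(sorted((node_of[i].key, node_of[j].key)))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        for l in (li, lj):
            if l < 0:
                n_clamped += 1
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(name=None,
                    children=[(node_of[i], li), (node_of[j], lj)],
                    key=min(node_of[i].key, node_of[j].key))
        node_of[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dm[(min(k, next_id), max(k, next_id))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    lens = []
    for l in (la, lb, lc):
        if l < 0:
            n_clamped += 1
        lens.append(max(l, 0.0))
    kids = sorted(zip((node_of[a], node_of[b], node_of[c]), lens), key=lambda t: t[0].key)
    inner = ",".join(f"{nd.newick()}:{bl:.10g}" for nd, bl in kids)
    if n_clamped:
        logger.info("nj_tree: clamped %d negative branch lengths to 0", n_clamped)
    return PhyloTree(newick=f"({inner});", leaves=sorted(labels),
                     n_negative_clamped=n_clamped)


@dataclass
class PCAResult:
    """Sample scores and explained-variance fractions."""

    scores: pd.DataFrame                 # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # markers x components


def genotype_pca(
    geno: GenotypeMatrix,
    n_components: int = 10,
    standardize: bool = False,
) -> PCAResult:
    """PCA of the dosage matrix.

    Missing calls are mean-imputed per marker and zero-variance markers
    dropped before column centering; ``standardize`` additionally scales
    each marker by sqrt(p(1-p)) of its counted-allele frequency.  The sign
    of each component is fixed so its largest-magnitude loading is
    positive.  ``n_components`` greater than the matrix rank is reduced
    with a warning.
    """
    x = geno.dosages_float()
    col_mean = np.nanmean(x, axis=0)
    nan = np.isnan(x)
    x[nan] = np.take(col_mean, np.nonzero(nan)[1])
    var = x.var(axis=0)
    keep = var > 0
    x = x[:, keep]
    marker_ids = geno.markers["marker_id"].to_numpy()[keep]
    xc = x - x.mean(axis=0)
    if standardize:
        p = x.mean(axis=0) / 2.0
        xc = xc / np.sqrt(p * (1.0 - p))
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = max(xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if n_components > rank:
        import warnings

        warnings.warn(f"n_components reduced from {n_components} to rank {rank}",
                      stacklevel=2)
        n_components = rank
    # sign convention: largest-magnitude loading positive
    for c in range(n_components):
        jmax = np.argmax(np.abs(vt[c]))
        if vt[c, jmax] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=geno.samples["sample_id"], columns=cols),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(vt[:n_components].T, index=marker_ids, columns=cols),
    )


def ld_prune(
    geno: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window_markers: int = 50,
) -> np.ndarray:
    """Greedy LD pruning: indices of markers to keep.

    Scans markers in map order; a marker is kept when its r^2 with every
    already-kept marker in the trailing ``window_markers`` window stays
    below ``r2_threshold``.  Plumbing for structure analyses; off by
    default in the pipeline.
    """
    x = geno.dosages_float()
    mk = geno.markers
    keep: list[int] = []
    for chrom, idx in mk.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        kept_local: list[int] = []
        for j in idx:
            ok = True
            for prev in kept_local[-window_markers:]:
                a, b = x[:, prev], x[:, j]
                m = ~np.isnan(a) & ~np.isnan(b)
                if m.sum() < 2:
                    continue
                va, vb = a[m].var(), b[m].var()
                if va == 0 or vb == 0:
                    continue
                r = np.corrcoef(a[m], b[m])[0, 1]
                if r * r >= r2_threshold:
                    ok = False
                    break
            if ok:
                kept_local.append(j)
        keep.extend(kept_local)
    return np.asarray(sorted(keep))
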