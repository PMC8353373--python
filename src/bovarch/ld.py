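"""Linkage disequilibrium decay: pairwise r^2, hyperbolic decay fits,
curve-equality tests, and clustering of populations on the decay rate.

The LD statistic is the composite (unphased) r^2: the squared Pearson
correlation of diploid dosage vectors over samples non-missing at both
markers.  Decay with physical distance d is modelled as

    E[r^2] = 1 / (1 + 4*beta*d)

where smaller beta means LD extends further.  beta is estimated per
population by nonlinear least squares; populations are compared by Wald
tests on the estimates and grouped by Ward hierarchical clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy

from .core import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_r2",
    "fit_sved",
    "sved_curve",
    "curve_equality_test",
    "cluster_breeds",
    "SvedFit",
    "CurveComparison",
    "BreedClustering",
    "write_pairs_tsv",
]

PAIR_COLUMNS = ["chrom", "id_a", "pos_a", "id_b", "pos_b", "dist_bp", "r2", "population"]


def sved_curve(d, beta):
    """Expected r^2 at distance d for decay rate beta."""
    return 1.0 / (1.0 + 4.0 * beta * np.asarray(d, dtype=np.float64))


def _offset_r2(x: np.ndarray, k: int, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised r^2 for marker pairs (j, j+k), j in ``cols``.

    Handles missing data (NaN) with pairwise-complete observations.
    Returns (r2, n_used); r2 is NaN where a pair is degenerate (fewer than
    two complete samples or zero variance at either marker).
    """
    a = x[:, cols]
    b = x[:, cols + k]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a0 = np.where(ok, a, 0.0)
    b0 = np.where(ok, b, 0.0)
    n = ok.sum(axis=0).astype(np.float64)
    sa, sb = a0.sum(axis=0), b0.sum(axis=0)
    saa, sbb = (a0 * a0).sum(axis=0), (b0 * b0).sum(axis=0)
    sab = (a0 * b0).sum(axis=0)
    cov = n * sab - sa * sb
    va = n * saa - sa * sa
    vb = n * sbb - sb * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((n >= 2) & (va > 0) & (vb > 0), cov * cov / (va * vb), np.nan)
    return r2, n


def pairwise_r2(
    geno: GenotypeMatrix,
    max_dist_kb: float = 1000.0,
    max_snp_sep: int | None = 5,
    population: str | None = None,
) -> pd.DataFrame:
    """Composite r^2 for same-chromosome marker pairs within a window.

    A pair qualifies when the markers sit within ``max_snp_sep`` index
    positions of each other AND within ``max_dist_kb`` physical distance
    (``max_snp_sep=None`` removes the index limit, as the effective-size
    estimator needs long-range pairs).  Pairs with fewer than two complete
    samples or zero dosage variance at either marker are skipped.

    Returns a frame with columns
    ``chrom, id_a, pos_a, id_b, pos_b, dist_bp, r2, population``.
    """
    x = geno.dosages_float()
    mk = geno.markers
    label = population if population is not None else (
        geno.samples["breed"].iloc[0] if geno.n_samples else "NA")
    max_dist_bp = int(round(max_dist_kb * 1000))
    out = []
    for chrom, idx in mk.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = mk["pos_bp"].to_numpy()[idx]
        m = idx.size
        if m < 2:
            continue
        sep_cap = m - 1 if max_snp_sep is None else min(max_snp_sep, m - 1)
        xc = x[:, idx]
        ids = mk["marker_id"].to_numpy()[idx]
        for k in range(1, sep_cap + 1):
            dist = pos[k:] - pos[:-k]
            cols = np.flatnonzero(dist <= max_dist_bp)
            if cols.size == 0:
                # positions are sorted, so larger separations only grow
                if (dist > max_dist_bp).all():
                    break
                continue
            r2, _n = _offset_r2(xc, k, cols)
            keep = ~np.isnan(r2)
            if not keep.any():
                continue
            j = cols[keep]
            out.append(pd.DataFrame({
                "chrom": chrom,
                "id_a": ids[j],
                "pos_a": pos[j],
                "id_b": ids[j + k],
                "pos_b": pos[j + k],
                "dist_bp": pos[j + k] - pos[j],
                "r2": r2[keep],
                "population": label,
            }))
    if not out:
        warnings.warn("no qualifying marker pairs in the requested window", stacklevel=2)
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(out, ignore_index=True)


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    """Write a pair table in the PLINK ``.ld`` column dialect."""
    df = pd.DataFrame({
        "CHR_A": pairs["chrom"], "BP_A": pairs["pos_a"], "SNP_A": pairs["id_a"],
        "CHR_B": pairs["chrom"], "BP_B": pairs["pos_b"], "SNP_B": pairs["id_b"],
        "R2": pairs["r2"],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class SvedFit:
    """Per-population hyperbolic decay fit."""

    beta_hat: float
    se: float
    residual_sd: float
    n_pairs: int
    population: str = "NA"

    def predict(self, d):
        return sved_curve(d, self.beta_hat)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the restart trace."""

    def __init__(self, message: str, trace: list[str]):
        super().__init__(message + "\n" + "\n".join(trace))
        self.trace = trace


def fit_sved(pairs: pd.DataFrame, population: str | None = None) -> SvedFit:
    """Nonlinear least-squares fit of r^2 = 1/(1 + 4*beta*d).

    Start value beta0 = 1/(4 * median distance) puts the curve's half-way
    point mid-cloud; on failure up to 5 restarts perturb beta0 by factors
    10^{+-1, +-2, +3}.  beta is constrained positive; the standard error
    comes from the asymptotic covariance of the least-squares problem.
    Requires >= 3 pairs spanning >= 2 distinct distances.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs to fit the decay curve, got {len(pairs)}")
    d = pairs["dist_bp"].to_numpy(dtype=np.float64)
    r2 = pairs["r2"].to_numpy(dtype=np.float64)
    if np.unique(d).size < 2:
        raise ValueError("degenerate pair set: all pairs at one distance")
    if population is None:
        population = str(pairs["population"].iloc[0]) if "population" in pairs else "NA"

    beta0 = 1.0 / (4.0 * float(np.median(d)))
    trace: list[str] = []
    for factor in (1.0, 10.0, 0.1, 100.0, 0.01, 1000.0):
        p0 = beta0 * factor
        try:
            popt, pcov = optimize.curve_fit(
                sved_curve, d, r2, p0=[p0],
                jac=lambda dd, b: (-4.0 * dd / (1.0 + 4.0 * b * dd) ** 2).reshape(-1, 1),
                bounds=(1e-300, np.inf), xtol=5e-16, ftol=5e-16, gtol=5e-16,
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            trace.append(f"start {p0:.3e}: {exc}")
            continue
        beta = float(popt[0])
        se = float(np.sqrt(pcov[0, 0]))
        if np.isfinite(beta) and beta > 0:
            resid = r2 - sved_curve(d, beta)
            dof = max(len(d) - 1, 1)
            return SvedFit(
                beta_hat=beta,
                se=se,
                residual_sd=float(np.sqrt((resid @ resid) / dof)),
                n_pairs=len(d),
                population=population,
            )
        trace.append(f"start {p0:.3e}: non-finite or non-positive estimate {beta}")
    raise FitError("decay fit did not converge after restarts", trace)


@dataclass
class CurveComparison:
    """Pairwise Wald comparison of decay coefficients."""

    populations: list[str]
    z: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    adjustment: str = "bonferroni"


def curve_equality_test(fits: list[SvedFit]) -> CurveComparison:
    """Test equality of decay curves through their beta estimates.

    For each population pair, z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2)
    with a two-sided normal p-value, Bonferroni-adjusted across the
    n*(n-1)/2 pairs.  Diagonal p-values are 1 by convention.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare curves")
    for f in fits:
        if not (np.isfinite(f.se) and f.se > 0):
            raise ValueError(f"population {f.population!r}: non-finite or non-positive SE")
    labels = [f.population for f in fits]
    beta = np.array([f.beta_hat for f in fits])
    var = np.array([f.se**2 for f in fits])
    z = (beta[:, None] - beta[None, :]) / np.sqrt(var[:, None] + var[None, :])
    p = 2.0 * stats.norm.sf(np.abs(z))
    np.fill_diagonal(p, 1.0)
    n_tests = len(fits) * (len(fits) - 1) // 2
    p_adj = np.minimum(p * n_tests, 1.0)
    np.fill_diagonal(p_adj, 1.0)
    mk = lambda a: pd.DataFrame(a, index=labels, columns=labels)
    return CurveComparison(populations=labels, z=mk(z), p_raw=mk(p), p_adjusted=mk(p_adj))


@dataclass
class BreedClustering:
    """Ward clustering of populations on their decay coefficients."""

    populations: list[str]
    k: int
    labels: np.ndarray            # cluster id per population, 1-based
    linkage: np.ndarray           # scipy linkage matrix
    newick: str

    def members(self, cluster_id: int) -> list[str]:
        return [p for p, c in zip(self.populations, self.labels) if c == cluster_id]

    def cluster_of(self, population: str) -> int:
        return int(self.labels[self.populations.index(population)])


def _linkage_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.10g}"

    if tree.is_leaf():
        return f"{labels[tree.id]}:0;"
    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


def cluster_breeds(fits: list[SvedFit], k: int | None = None) -> BreedClustering:
    """Group populations by decay coefficient (Euclidean distance, Ward
    linkage on the scalar beta values).

    ``k=None`` picks the cut maximising the mean silhouette over
    k in [2, min(8, n-1)].  Ties in beta resolve by input order through
    the stable pairwise-distance computation.  The dendrogram is also
    returned as newick with merge heights as branch lengths.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to cluster")
    labels_in = [f.population for f in fits]
    x = np.array([[f.beta_hat] for f in fits])
    Z = hierarchy.linkage(x, method="ward", metric="euclidean")
    if k is None:
        from sklearn.metrics import silhouette_score

        best_k, best_s = 2, -np.inf
        for kk in range(2, min(8, len(fits) - 1) + 1):
            lab = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(x, lab)
            if s > best_s + 1e-12:
                best_k, best_s = kk, s
        k = best_k
    if not 1 <= k <= len(fits):
        raise ValueError(f"k must be in [1, {len(fits)}], got {k}")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return BreedClustering(
        populations=labels_in, k=int(k), labels=labels, linkage=Z,
        newick=_linkage_newick(Z, labels_in),
    )
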