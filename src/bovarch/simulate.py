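"""Synthetic genotype panels with known ground truth.

Three generators back the test pyramid for the analysis stages:

* a forward-in-time diploid Wright-Fisher simulator with recombination,
  giving panels whose linkage disequilibrium and drift history are known;
* an ROH implanter that forces homozygous tracts into chosen samples, the
  ground truth for run-of-homozygosity calling and island detection;
* a Sved-curve pair generator emitting (distance, r^2) clouds from
  E[r^2] = 1 / (1 + 4*beta*d) plus Gaussian noise, the ground truth for
  decay-model fitting.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, MORGAN_PER_BP, GenotypeMatrix, PanelError, marker_map

__all__ = [
    "SimConfig",
    "ImplantSpec",
    "simulate_population",
    "simulate_two_epoch",
    "implant_roh",
    "implant_carriers",
    "sved_pair_generator",
]


@dataclass
class SimConfig:
    """Wright-Fisher run parameters.

    effective_size
        Diploid population size N (constant within the run; compose runs
        for piecewise-constant histories via ``start_from``).
    sample_n
        Diploids drawn without replacement at the end; must be <= N.
    chromosome_length_bp / n_chromosomes / marker_spacing_bp
        Uniformly spaced biallelic markers on each chromosome.
    generations
        Generations of random mating after the standing-variation start
        (every marker at allele frequency 0.5, linkage equilibrium).
    recomb_rate
        Morgan per bp; the default 1e-8 is the 1 cM/Mb convention.
    missing_rate
        Per-call masking probability applied to the sampled panel.
    """

    effective_size: int = 100
    sample_n: int = 50
    n_chromosomes: int = 10
    chromosome_length_bp: int = 50_000_000
    marker_spacing_bp: int = 50_000
    generations: int = 150
    recomb_rate: float = MORGAN_PER_BP
    missing_rate: float = 0.0
    seed: int = 0
    breed_label: str = "SIM"

    def __post_init__(self) -> None:
        if self.effective_size < 2:
            raise ValueError("effective_size must be >= 2")
        if self.sample_n < 1:
            raise ValueError("sample_n must be >= 1")
        if self.sample_n > self.effective_size:
            raise ValueError(
                f"cannot sample {self.sample_n} diploids from a population of "
                f"{self.effective_size}"
            )
        for name in ("n_chromosomes", "chromosome_length_bp", "marker_spacing_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.recomb_rate < 0.0:
            raise ValueError("recomb_rate must be >= 0")


@dataclass
class ImplantSpec:
    """A homozygous tract to force into part of a panel."""

    chromosome: str
    start_bp: int
    end_bp: int
    carrier_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")


def _chrom_positions(cfg: SimConfig) -> np.ndarray:
    return np.arange(cfg.marker_spacing_bp, cfg.chromosome_length_bp + 1,
                     cfg.marker_spacing_bp, dtype=np.int64)


def _next_generation(hap: np.ndarray, pos_frac: np.ndarray, genetic_len: float,
                     n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """One generation of random mating for one chromosome.

    ``hap`` is (2N, m) uint8; returns (n_gametes, m).  Crossover counts are
    Poisson(genetic_len) with uniform placement, no interference.
    """
    n_parents = hap.shape[0] // 2
    parent = rng.integers(0, n_parents, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes)
    n_co = rng.poisson(genetic_len, size=n_gametes)
    out = np.empty((n_gametes, hap.shape[1]), dtype=np.uint8)
    plain = n_co == 0
    out[plain] = hap[2 * parent[plain] + start[plain]]
    for g in np.flatnonzero(~plain):
        cuts = np.sort(rng.random(n_co[g]))
        # phase flips at each crossover: haplotype index per marker
        phase = (start[g] + np.searchsorted(cuts, pos_frac, side="right")) % 2
        rows = hap[2 * parent[g] : 2 * parent[g] + 2]
        out[g] = np.where(phase == 0, rows[0], rows[1])
    return out


def simulate_population(cfg: SimConfig) -> GenotypeMatrix:
    """Forward Wright-Fisher simulation of a diploid panel.

    Gametes start from standing variation (allele frequency 0.5 per marker,
    linkage equilibrium, no mutation thereafter).  After
    ``cfg.generations`` rounds of random mating, ``cfg.sample_n`` diploids
    are drawn without replacement and missing calls are masked at
    ``cfg.missing_rate``.  Size changes are modelled by
    :func:`simulate_two_epoch`.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = _chrom_positions(cfg)
    m_per_chrom = positions.size
    if m_per_chrom == 0:
        raise PanelError("marker_spacing_bp larger than chromosome_length_bp: no markers")
    genetic_len = cfg.chromosome_length_bp * cfg.recomb_rate
    pos_frac = positions / cfg.chromosome_length_bp
    n_gam = 2 * cfg.effective_size

    chrom_haps: list[np.ndarray] = []
    for _ in range(cfg.n_chromosomes):
        hap = rng.integers(0, 2, size=(n_gam, m_per_chrom), dtype=np.uint8)
        chrom_haps.append(hap)

    for _ in range(cfg.generations):
        chrom_haps = [
            _next_generation(h, pos_frac, genetic_len, n_gam, rng) for h in chrom_haps
        ]

    pick = rng.choice(cfg.effective_size, size=cfg.sample_n, replace=False)
    dos_blocks = []
    for hap in chrom_haps:
        d = hap[2 * pick] + hap[2 * pick + 1]
        dos_blocks.append(d.astype(np.int8))
    dosages = np.concatenate(dos_blocks, axis=1)

    if cfg.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING

    chroms = np.repeat([str(c + 1) for c in range(cfg.n_chromosomes)], m_per_chrom)
    pos_all = np.tile(positions, cfg.n_chromosomes)
    ids = [f"snp{c + 1}_{i + 1}" for c in range(cfg.n_chromosomes) for i in range(m_per_chrom)]
    markers = marker_map(ids, chroms, pos_all, sort=False)
    samples = pd.DataFrame(
        {"sample_id": [f"{cfg.breed_label}_{i + 1}" for i in range(cfg.sample_n)],
         "breed": cfg.breed_label}
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dosages)


def simulate_two_epoch(cfg: SimConfig, n_recent: int, generations_recent: int) -> GenotypeMatrix:
    """Population-size change: ``cfg`` for the ancient epoch, then
    ``generations_recent`` generations at size ``n_recent``.

    Implemented as one forward run whose per-generation gamete pool shrinks
    (or grows) at the epoch boundary; sampling uses the recent size.
    """
    if n_recent < 2:
        raise ValueError("n_recent must be >= 2")
    if cfg.sample_n > n_recent:
        raise ValueError("cannot sample more diploids than the recent population size")
    rng = np.random.default_rng(cfg.seed)
    positions = _chrom_positions(cfg)
    genetic_len = cfg.chromosome_length_bp * cfg.recomb_rate
    pos_frac = positions / cfg.chromosome_length_bp

    sizes = [2 * cfg.effective_size] * cfg.generations + [2 * n_recent] * generations_recent
    chrom_haps = [
        rng.integers(0, 2, size=(2 * cfg.effective_size, positions.size), dtype=np.uint8)
        for _ in range(cfg.n_chromosomes)
    ]
    for n_gam in sizes:
        chrom_haps = [_next_generation(h, pos_frac, genetic_len, n_gam, rng) for h in chrom_haps]

    pick = rng.choice(n_recent, size=cfg.sample_n, replace=False)
    dosages = np.concatenate(
        [(h[2 * pick] + h[2 * pick + 1]).astype(np.int8) for h in chrom_haps], axis=1
    )
    if cfg.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    chroms = np.repeat([str(c + 1) for c in range(cfg.n_chromosomes)], positions.size)
    ids = [f"snp{c + 1}_{i + 1}" for c in range(cfg.n_chromosomes) for i in range(positions.size)]
    markers = marker_map(ids, chroms, np.tile(positions, cfg.n_chromosomes), sort=False)
    samples = pd.DataFrame(
        {"sample_id": [f"{cfg.breed_label}_{i + 1}" for i in range(cfg.sample_n)],
         "breed": cfg.breed_label}
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dosages)


def implant_roh(geno: GenotypeMatrix, spec: ImplantSpec) -> GenotypeMatrix:
    """Force a homozygous major-allele tract into part of the panel.

    ceil(carrier_fraction * n_samples) carriers are the first samples of a
    seeded shuffle (so tests can enumerate them via the same seed); within
    [start_bp, end_bp] on the given chromosome each carrier is set to
    dosage 0, the major-allele homozygote.  Everything else is untouched.

    Raises
    ------
    PanelError
        If the region contains no markers.
    """
    mk = geno.markers
    in_region = (
        (mk["chrom"] == str(spec.chromosome))
        & (mk["pos_bp"] >= spec.start_bp)
        & (mk["pos_bp"] <= spec.end_bp)
    ).to_numpy()
    if not in_region.any():
        raise PanelError(
            f"implant region {spec.chromosome}:{spec.start_bp}-{spec.end_bp} contains no markers"
        )
    n_carriers = math.ceil(spec.carrier_fraction * geno.n_samples)
    rng = np.random.default_rng(spec.seed)
    carriers = rng.permutation(geno.n_samples)[:n_carriers]
    dosages = geno.dosages.copy()
    dosages[np.ix_(carriers, np.flatnonzero(in_region))] = 0
    return GenotypeMatrix(samples=geno.samples.copy(), markers=mk.copy(), dosages=dosages)


def implant_carriers(n_samples: int, spec: ImplantSpec) -> np.ndarray:
    """Indices of the carrier samples :func:`implant_roh` would modify."""
    n_carriers = math.ceil(spec.carrier_fraction * n_samples)
    rng = np.random.default_rng(spec.seed)
    return np.sort(rng.permutation(n_samples)[:n_carriers])


def sved_pair_generator(
    beta: float,
    distances_bp,
    noise_sd: float = 0.0,
    seed: int = 0,
    population: str = "SIM",
) -> pd.DataFrame:
    """(distance, r^2) pairs from the hyperbolic decay curve plus noise.

    r^2 = 1 / (1 + 4*beta*d) + eps with eps ~ N(0, noise_sd^2), truncated
    into [0, 1].  Output follows the pair-table layout of
    :func:`bovarch.ld.pairwise_r2`.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    d = np.round(np.asarray(distances_bp, dtype=np.float64))
    if (d <= 0).any():
        raise ValueError("distances must be positive")
    rng = np.random.default_rng(seed)
    r2 = 1.0 / (1.0 + 4.0 * beta * d)
    if noise_sd > 0.0:
        r2 = r2 + rng.normal(0.0, noise_sd, size=d.size)
    r2 = np.clip(r2, 0.0, 1.0)
    n = d.size
    return pd.DataFrame(
        {
            "chrom": "1",
            "id_a": [f"a{i}" for i in range(n)],
            "pos_a": 1,
            "id_b": [f"b{i}" for i in range(n)],
            "pos_b": 1 + d.astype(np.int64),
            "dist_bp": d.astype(np.int64),
            "r2": r2,
            "population": population,
        }
    )
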