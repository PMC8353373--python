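"""One-config orchestration: QC -> LD decay -> Ne -> ROH -> islands ->
breed structure over a multi-breed panel, with a reproducibility manifest.

Every stage runs per population where the analysis is population-level; a
failure in one breed is logged and does not sink the others.  All outputs
are plain TSV/newick/JSON written with fixed numeric formatting, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, ld, ne, roh, simulate, structure
from .core import GenotypeMatrix, PanelError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline", "PipelineResult"]

_FLOAT_FMT = "%.10g"

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "bovarch_out",
    "log_level": "INFO",
    "input": {"ped": None, "map": None, "dosage_tsv": None},
    "simulate": {
        "enabled": False,
        "effective_size": 100,
        "sample_n": 50,
        "n_chromosomes": 3,
        "chromosome_length_bp": 25_000_000,
        "marker_spacing_bp": 25_000,
        "generations": 100,
        "recomb_rate": 1e-8,
        "missing_rate": 0.0,
        "breed_label": "SIM",
    },
    "qc": {"marker_call_rate": 0.95, "maf_min": 0.01, "sample_call_rate": 0.85},
    "ld": {"max_dist_kb": 1000.0, "max_snp_sep": 5, "cluster_k": None},
    "ne": {"bin_edges_morgan": [0.01, 0.03, 0.05], "max_morgan": 0.125},
    "roh": {
        "window_snp": 50,
        "window_het_max": 1,
        "window_missing_max": 5,
        "window_hit_threshold": 0.05,
        "min_length_kb": 1000.0,
        "min_snp": 120,
        "max_gap_kb": 1000.0,
        "island_threshold": 0.5,
        "gene_file": None,
    },
    "structure": {"n_components": 10, "prune": False, "prune_r2": 0.2},
}

# (min, max, min_exclusive) range constraints for scalar keys
_RANGES: dict[str, tuple[float, float, bool]] = {
    "qc.marker_call_rate": (0.0, 1.0, False),
    "qc.maf_min": (0.0, 1.0, False),
    "qc.sample_call_rate": (0.0, 1.0, False),
    "simulate.missing_rate": (0.0, 1.0, False),
    "roh.window_hit_threshold": (0.0, 1.0, True),
    "roh.island_threshold": (0.0, 1.0, False),
    "ld.max_dist_kb": (0.0, float("inf"), True),
    "ne.max_morgan": (0.0, float("inf"), True),
}


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class RunConfig:
    """Normalized pipeline configuration (defaults merged in)."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]


def _merge(defaults: dict, user: dict, path: str, errors: list[str]) -> dict:
    out = {}
    for key, dval in defaults.items():
        here = f"{path}.{key}" if path else key
        if key not in user:
            out[key] = dval
            continue
        uval = user[key]
        if isinstance(dval, dict):
            if not isinstance(uval, dict):
                errors.append(f"{here}: expected a mapping, got {type(uval).__name__}")
                out[key] = dval
            else:
                out[key] = _merge(dval, uval, here, errors)
            continue
        if dval is not None and uval is not None:
            if isinstance(dval, bool) != isinstance(uval, bool):
                errors.append(f"{here}: expected {type(dval).__name__}, "
                              f"got {type(uval).__name__}")
                out[key] = dval
                continue
            if isinstance(dval, (int, float)) and not isinstance(dval, bool):
                if not isinstance(uval, (int, float)) or isinstance(uval, bool):
                    errors.append(f"{here}: expected a number, got {type(uval).__name__}")
                    out[key] = dval
                    continue
            elif isinstance(dval, str) and not isinstance(uval, str):
                errors.append(f"{here}: expected a string, got {type(uval).__name__}")
                out[key] = dval
                continue
            elif isinstance(dval, list) and not isinstance(uval, list):
                errors.append(f"{here}: expected a list, got {type(uval).__name__}")
                out[key] = dval
                continue
        out[key] = uval
    for key in user:
        if key not in defaults:
            here = f"{path}.{key}" if path else key
            errors.append(f"{here}: unknown key")
    return out


def validate_config(path_or_dict) -> RunConfig:
    """Load, validate, and normalize a YAML run configuration.

    All problems (unknown keys, type mismatches, out-of-range values,
    missing input files) are collected and reported in one pass.  An
    empty file yields the full default configuration.
    """
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError([f"{path_or_dict}: top level must be a mapping"])
    errors: list[str] = []
    cfg = _merge(DEFAULTS, user, "", errors)

    for dotted, (lo, hi, lo_excl) in _RANGES.items():
        block, key = dotted.split(".")
        v = cfg[block][key]
        if v is None:
            continue
        bad = (v <= lo if lo_excl else v < lo) or v > hi
        if bad:
            errors.append(f"{dotted}: value {v} outside "
                          f"{'(' if lo_excl else '['}{lo}, {hi}]")

    inp = cfg["input"]
    has_ped = inp["ped"] is not None or inp["map"] is not None
    if has_ped and (inp["ped"] is None or inp["map"] is None):
        errors.append("input: ped and map must be given together")
    for key in ("ped", "map", "dosage_tsv"):
        p = inp[key]
        if p is not None and not Path(p).exists():
            errors.append(f"input.{key}: file not found: {p}")
    gf = cfg["roh"]["gene_file"]
    if gf is not None and not Path(gf).exists():
        errors.append(f"roh.gene_file: file not found: {gf}")
    if not has_ped and inp["dosage_tsv"] is None and not cfg["simulate"]["enabled"]:
        errors.append("no input: give input.ped/map, input.dosage_tsv, or "
                      "simulate.enabled: true")

    if errors:
        raise ConfigError(errors)
    logger.info("configuration normalized; defaults injected for absent keys")
    return RunConfig(data=cfg)


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the root seed and stage name."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineResult:
    outputs: dict[str, Path] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_panel(cfg: RunConfig) -> GenotypeMatrix:
    inp = cfg["input"]
    if inp["ped"] is not None:
        return io.read_ped_map(inp["ped"], inp["map"])
    if inp["dosage_tsv"] is not None:
        return io.read_dosage_tsv(inp["dosage_tsv"], map_path=inp["map"])
    sim = dict(cfg["simulate"])
    sim.pop("enabled")
    return simulate.simulate_population(
        simulate.SimConfig(seed=stage_seed(cfg["seed"], "simulate"), **sim)
    )


def run_pipeline(cfg: RunConfig, output_dir=None) -> PipelineResult:
    """Execute every stage over the configured panel.

    Emits per-breed decay-coefficient and curve-comparison tables, Ne
    trajectories, ROH segment/length-class/island tables, the breed
    distance matrix with its neighbor-joining tree, PCA scores, and a
    manifest holding versions, parameters, and input checksums.  A stage
    failure in one population is recorded and skips that population's
    dependent stages only.
    """
    out_dir = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        result.outputs[name] = path

    panel = _load_panel(cfg)
    qc_cfg = cfg["qc"]
    panel_qc, report = io.qc_filter(panel, **qc_cfg)
    emit("qc_report.tsv", lambda p: report.to_frame().to_csv(
        p, sep="\t", index=False, float_format=_FLOAT_FMT))

    breeds = panel_qc.breeds()
    roh_cfg = dict(cfg["roh"])
    island_threshold = roh_cfg.pop("island_threshold")
    gene_file = roh_cfg.pop("gene_file")
    params = roh.ROHParams(**roh_cfg)

    fits: list[ld.SvedFit] = []
    trajectories, seg_tables, island_tables = [], [], []
    for breed in breeds:
        sub = panel_qc.by_breed(breed)
        try:
            pairs = ld.pairwise_r2(sub, max_dist_kb=cfg["ld"]["max_dist_kb"],
                                   max_snp_sep=cfg["ld"]["max_snp_sep"],
                                   population=breed)
            fits.append(ld.fit_sved(pairs, population=breed))
        except Exception as exc:  # per-population isolation
            result.failures[f"ld:{breed}"] = str(exc)
            logger.error("LD stage failed for %s: %s", breed, exc)
        try:
            traj = ne.ne_trajectory(sub, bin_edges_morgan=cfg["ne"]["bin_edges_morgan"],
                                    max_morgan=cfg["ne"]["max_morgan"], population=breed)
            trajectories.append(traj.table)
        except Exception as exc:
            result.failures[f"ne:{breed}"] = str(exc)
            logger.error("Ne stage failed for %s: %s", breed, exc)
        try:
            segs = roh.call_roh_panel(sub, params)
            seg_tables.append(segs)
            islands = roh.find_islands(segs, sub.markers, sub.n_samples,
                                       threshold=island_threshold, population=breed)
            island_tables.append(islands)
        except Exception as exc:
            result.failures[f"roh:{breed}"] = str(exc)
            logger.error("ROH stage failed for %s: %s", breed, exc)

    if fits:
        beta_tbl = pd.DataFrame(
            [{"population": f.population, "beta_hat": f.beta_hat, "se": f.se,
              "residual_sd": f.residual_sd, "n_pairs": f.n_pairs} for f in fits]
        )
        emit("ld_decay_beta.tsv", lambda p: beta_tbl.to_csv(
            p, sep="\t", index=False, float_format=_FLOAT_FMT))
    if len(fits) >= 2:
        comp = ld.curve_equality_test(fits)
        emit("ld_curve_pvalues.tsv", lambda p: comp.p_adjusted.to_csv(
            p, sep="\t", float_format=_FLOAT_FMT))
        clustering = ld.cluster_breeds(fits, k=cfg["ld"]["cluster_k"])
        assign = pd.DataFrame({"population": clustering.populations,
                               "cluster": clustering.labels})
        emit("ld_beta_clusters.tsv", lambda p: assign.to_csv(p, sep="\t", index=False))
        emit("ld_beta_dendrogram.nwk",
             lambda p: Path(p).write_text(clustering.newick + "\n"))

    if trajectories:
        traj_all = pd.concat(trajectories, ignore_index=True)
        emit("ne_trajectories.tsv", lambda p: traj_all.to_csv(
            p, sep="\t", index=False, float_format=_FLOAT_FMT))

    segments = (pd.concat(seg_tables, ignore_index=True)
                if seg_tables else pd.DataFrame(columns=roh.SEGMENT_COLUMNS))
    emit("roh_segments.tsv", lambda p: roh.write_segments_tsv(segments, p))
    per_sample, per_pop = roh.roh_length_summary(segments)
    emit("roh_length_by_sample.tsv", lambda p: per_sample.to_csv(
        p, sep="\t", index=False, float_format=_FLOAT_FMT))
    emit("roh_length_percent.tsv", lambda p: per_pop.to_csv(
        p, sep="\t", index=False, float_format=_FLOAT_FMT))
    islands_all = (pd.concat(island_tables, ignore_index=True)
                   if island_tables else pd.DataFrame(columns=roh.ISLAND_COLUMNS))
    if gene_file is not None and not islands_all.empty:
        genes = roh.read_gene_intervals(gene_file)
        islands_all = roh.annotate_islands(islands_all, genes)
    emit("roh_islands.tsv", lambda p: islands_all.to_csv(
        p, sep="\t", index=False, float_format=_FLOAT_FMT))
    emit("roh_islands.bed", lambda p: roh.write_islands_bed(islands_all, p))

    try:
        st = cfg["structure"]
        pca_panel = panel_qc
        if st["prune"]:
            keep = structure.ld_prune(panel_qc, r2_threshold=st["prune_r2"])
            pca_panel = panel_qc.subset(marker_idx=keep)
        if len(breeds) >= 2:
            freqs = io.allele_frequencies(panel_qc, by_breed=True)
            dist = structure.population_distance(freqs)
            emit("breed_distance.tsv", lambda p: dist.to_csv(
                p, sep="\t", float_format=_FLOAT_FMT))
            if len(breeds) >= 3:
                tree = structure.nj_tree(dist)
                emit("nj_tree.nwk", lambda p: Path(p).write_text(tree.newick + "\n"))
        n_comp = min(st["n_components"], pca_panel.n_samples - 1, pca_panel.n_markers)
        pca = structure.genotype_pca(pca_panel, n_components=max(n_comp, 1))
        scores = pca.scores.copy()
        scores.insert(0, "breed", pca_panel.samples["breed"].to_numpy())
        emit("pca_scores.tsv", lambda p: scores.to_csv(
            p, sep="\t", float_format=_FLOAT_FMT))
    except Exception as exc:
        result.failures["structure"] = str(exc)
        logger.error("structure stage failed: %s", exc)

    checksums = {}
    for key in ("ped", "map", "dosage_tsv"):
        p = cfg["input"][key]
        if p is not None:
            checksums[key] = _sha256(p)
    if gene_file is not None:
        checksums["gene_file"] = _sha256(gene_file)
    versions = {"bovarch": __version__, "numpy": np.__version__,
                "pandas": pd.__version__}
    import scipy

    versions["scipy"] = scipy.__version__
    # parameters that cannot change results are excluded so that reruns
    # into different directories stay comparable checksum-for-checksum
    params = {k: v for k, v in cfg.data.items() if k not in ("output_dir", "log_level")}
    result.manifest = {
        "versions": versions,
        "parameters": params,
        "input_checksums": checksums,
        "failures": result.failures,
    }
    emit("manifest.json", lambda p: Path(p).write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True, default=str) + "\n"))
    return result
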