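"""Pipeline orchestration: simulate -> normalize -> infer -> groups -> seqfeat.

A single YAML config drives the stages; every stage writes its outputs
before the next starts, and a run manifest records the config hash, per-file
SHA-256 checksums and wall-clock time per stage, so that re-running an
identical config can be verified to reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formats, grouptest, normalize, seqfeat, simdata, tailtest
from .errors import ConfigError, DataValidationError, StageError

logger = logging.getLogger("tailfrac")

STAGES = ("simulate", "normalize", "infer", "groups", "seqfeat", "report")

_KNOWN_KEYS = {
    "version", "seed", "outdir", "stages", "inputs", "simulate", "normalize",
    "infer", "groups", "seqfeat", "report",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (fail-fast on unknown keys)."""

    outdir: Path
    seed: int = 0
    stages: tuple = STAGES
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("version", 1) != 1:
            raise ConfigError(f"unsupported config version {raw.get('version')!r}")
        if "outdir" not in raw:
            raise ConfigError("config must set 'outdir'")
        stages = tuple(raw.get("stages", STAGES))
        bad = set(stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        stages = tuple(s for s in STAGES if s in stages)  # dependency order
        if "simulate" in stages and "seed" not in raw:
            raise ConfigError("simulation enabled but no 'seed' set")
        params = {k: dict(raw.get(k) or {}) for k in STAGES}
        cfg = cls(outdir=Path(raw["outdir"]), seed=int(raw.get("seed", 0)),
                  stages=stages, inputs=dict(raw.get("inputs") or {}),
                  params=params)
        if "simulate" not in stages:
            needed = {"counts", "meta"}
            missing = needed - set(cfg.inputs)
            if missing and set(stages) & {"normalize", "infer", "groups"}:
                raise ConfigError(
                    f"no simulation stage and inputs missing: {sorted(missing)}")
            for key, p in cfg.inputs.items():
                if not Path(p).exists():
                    raise ConfigError(f"input {key!r} does not exist: {p}")
        return cfg


@dataclass
class RunManifest:
    """Checksums and timings that make a run verifiable."""

    config_hash: str
    stages: dict = field(default_factory=dict)  # stage -> {files: {path: sha}, seconds}
    version: str = "tailfrac-0.1.0"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "config_hash": self.config_hash,
                       "stages": self.stages}, fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_map(paths) -> dict:
    return {str(Path(p).name): _sha256(p) for p in paths}


def run(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and emit a manifest.

    A stage failure raises :class:`StageError` after writing the partial
    manifest to ``<outdir>/manifest.partial.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(
        {"seed": config.seed, "stages": config.stages, "params": config.params,
         "inputs": {k: str(v) for k, v in config.inputs.items()}},
        sort_keys=True)
    manifest = RunManifest(hashlib.sha256(cfg_repr.encode()).hexdigest())

    state: dict = {"paths": dict(config.inputs)}
    for stage in config.stages:
        t0 = time.perf_counter()
        logger.info("[%s] starting", stage)
        try:
            written = _STAGE_FUNCS[stage](config, state, outdir)
        except (ConfigError, DataValidationError):
            manifest.to_json(outdir / "manifest.partial.json")
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            manifest.to_json(outdir / "manifest.partial.json")
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {
            "files": _checksum_map(written),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("[%s] done (%.1fs)", stage, manifest.stages[stage]["seconds"])
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, outdir):
    params = dict(config.params.get("simulate") or {})
    params.setdefault("seed", config.seed)
    sim_cfg = simdata.SimConfig(**params)
    exp = simdata.simulate_experiment(sim_cfg)
    simdir = outdir / "sim"
    paths = simdata.write_experiment(exp, simdir)
    state["experiment"] = exp
    state["paths"].update({k: str(v) for k, v in paths.items()})
    return list(paths.values())


def _load_matrix(state):
    if "matrix" in state:
        return state["matrix"]
    exp = state.get("experiment")
    if exp is not None:
        spikes = exp.counts.spike_genes
        matrix = exp.counts
    else:
        paths = state["paths"]
        spikes = ()
        if "truth" in paths:
            truth = pd.read_csv(paths["truth"], sep="\t", index_col=0)
            if "is_spike" in truth:
                spikes = tuple(truth.index[truth["is_spike"]])
        matrix = formats.read_counts(paths["counts"], paths["meta"], spikes)
    state["matrix"] = matrix
    return matrix


def _stage_normalize(config, state, outdir):
    params = config.params.get("normalize") or {}
    matrix = _load_matrix(state)
    filtered = normalize.filter_low_counts(
        matrix, int(params.get("min_count", 6)))
    norm = normalize.tmm_factors(filtered,
                                 trim_m=float(params.get("trim_m", 0.30)),
                                 trim_a=float(params.get("trim_a", 0.05)))
    state["filtered"] = filtered
    state["norm"] = norm
    path = outdir / "normalization.tsv"
    pd.DataFrame({
        "library_size": norm.library_sizes,
        "tmm_factor": norm.factors,
        "effective_size": norm.effective_sizes,
    }).to_csv(path, sep="\t", index_label="sample")
    return [path]


def _require(state, key, stage, needed_by):
    if key not in state:
        raise ConfigError(f"stage {needed_by!r} requires stage {stage!r} to run first")
    return state[key]


def _stage_infer(config, state, outdir):
    params = config.params.get("infer") or {}
    filtered = _require(state, "filtered", "normalize", "infer")
    norm = _require(state, "norm", "normalize", "infer")
    non_spike = filtered.subset_genes(
        filtered.genes[~filtered.spike_mask])
    tail = tailtest.test_tail_change(non_spike, _subset_state(norm, non_spike),
                                     reference=params.get("reference"))
    abundance = tailtest.test_abundance_change(
        non_spike, _subset_state(norm, non_spike),
        reference=params.get("reference"))
    state["tail"] = tail
    state["abundance"] = abundance
    p_tail = outdir / "tailchange.tsv"
    p_ab = outdir / "abundance.tsv"
    tail.index.name = "gene"
    abundance.index.name = "gene"
    formats.write_results(tail.reset_index(), p_tail)
    abundance.reset_index().to_csv(p_ab, sep="\t", index=False, na_rep="NA",
                                   float_format="%.10g")
    return [p_tail, p_ab]


def _subset_state(norm, matrix):
    return normalize.NormalizationState(
        norm.library_sizes[matrix.counts.columns],
        norm.factors[matrix.counts.columns])


def _stage_groups(config, state, outdir):
    params = config.params.get("groups") or {}
    tail = _require(state, "tail", "infer", "groups")
    paths = state["paths"]
    written = []
    values = tail["log2FC_ratio"].dropna()
    if "categories" in paths:
        cats = formats.read_category_map(paths["categories"])
        sweep = grouptest.category_sweep(values, cats,
                                         min_size=int(params.get("min_size", 5)))
        p = outdir / "groups.tsv"
        sweep.to_csv(p, sep="\t", index=False, na_rep="NA")
        state["groups"] = sweep
        written.append(p)
    if "modules" in paths:
        modules = pd.read_csv(paths["modules"], sep="\t", index_col=0)
        assign = modules.iloc[:, 0]
        table, ecdfs = grouptest.module_cdf_compare(values, assign)
        p = outdir / "modules.tsv"
        table.to_csv(p, sep="\t", index=False, na_rep="NA")
        state["modules"] = (table, ecdfs)
        written.append(p)
    if not written:
        raise ConfigError("groups stage enabled but no categories/modules input")
    return written


def _stage_seqfeat(config, state, outdir):
    params = config.params.get("seqfeat") or {}
    tail = _require(state, "tail", "infer", "seqfeat")
    paths = state["paths"]
    exp = state.get("experiment")
    window = int(params.get("window", 100))
    if exp is not None:
        windows = {g: s[-window:] if len(s) > window else s
                   for g, s in exp.sequences.items()}
        annotation, genome = exp.annotation, exp.genome
    else:
        if "genome" not in paths or "utr_bed" not in paths:
            raise ConfigError("seqfeat stage needs 'genome' and 'utr_bed' inputs")
        genome = formats.read_fasta(paths["genome"])
        annotation = formats.read_utr_annotation(paths["utr_bed"], "bed")
        windows = seqfeat.extract_terminal_window(annotation, genome, window)
    values = tail["log2FC_ratio"].dropna()
    sweep = seqfeat.hexamer_sweep(windows, values)
    profile = seqfeat.base_composition_profile(
        annotation, genome, flank=int(params.get("flank", 200)))
    p_hex = outdir / "hexamers.tsv"
    p_prof = outdir / "composition.tsv"
    sweep.to_csv(p_hex, sep="\t", index=False, na_rep="NA")
    profile.to_csv(p_prof, sep="\t", na_rep="NA")
    state["hexamers"] = sweep
    state["composition"] = profile
    return [p_hex, p_prof]


def _stage_report(config, state, outdir):
    return report(outdir, state)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "infer": _stage_infer,
    "groups": _stage_groups,
    "seqfeat": _stage_seqfeat,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(results_dir, state: dict | None = None) -> list:
    """Summary plots and a text digest of whatever results are present.

    Missing results are listed in the summary and skipped.  Regeneration is
    deterministic given fixed result files.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    state = state or {}
    written, missing = [], []

    def _load(key, fname, **kw):
        if key in state:
            return state[key]
        path = results_dir / fname
        if path.exists():
            return pd.read_csv(path, sep="\t", na_values=["NA"], **kw)
        missing.append(fname)
        return None

    tail = _load("tail", "tailchange.tsv")
    if tail is not None and "gene" in getattr(tail, "columns", ()):
        tail = tail.set_index("gene")
    groups = _load("groups", "groups.tsv")
    hexamers = _load("hexamers", "hexamers.tsv")
    composition = _load("composition", "composition.tsv", index_col=0)

    lines = ["tailfrac report", "=" * 15]
    if tail is not None:
        sig = tail["BH_p_value"].dropna() < 0.05
        lines.append(f"genes tested: {len(tail)}; significant tail change "
                     f"(BH<0.05): {int(sig.sum())}")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(tail["logCPM"], tail["log2FC_ratio"], s=4, alpha=0.3,
                   c=np.where(tail["BH_p_value"] < 0.05, "crimson", "grey"))
        ax.set_xlabel("logCPM")
        ax.set_ylabel("log2FC of long/short ratio")
        ax.axhline(0.0, lw=0.5, color="k")
        fig.tight_layout()
        p = results_dir / "ma_tailchange.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        # ECDF of the full distribution as background reference
        if groups is not None and len(groups):
            fig, ax = plt.subplots(figsize=(5, 4))
            bg = np.sort(tail["log2FC_ratio"].dropna().to_numpy())
            ax.step(bg, np.arange(1, bg.size + 1) / bg.size,
                    label="background", color="grey")
            top = groups.iloc[0]
            lines.append("top category: "
                         f"{top['category']} ({top['name']}), n={top['n']}, "
                         f"median={top['median_log2FC']:.3f}, "
                         f"BH p={top['BH_p_value']:.3g}")
            ax.set_xlabel("log2FC of long/short ratio")
            ax.set_ylabel("ECDF")
            ax.legend()
            fig.tight_layout()
            p = results_dir / "ecdf_categories.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    if hexamers is not None and len(hexamers):
        top = hexamers.iloc[0]
        lines.append(f"top hexamer: {top['motif']} "
                     f"(p={top['p_value']:.3g}, BH={top['BH_p_value']:.3g}, "
                     f"n_with={top['n_with']})")
    if composition is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        for base in ("A", "C", "G", "T"):
            if base in composition.columns:
                ax.plot(composition.index, composition[base], label=base, lw=1)
        ax.axvline(0, ls="--", lw=0.7, color="k")
        ax.set_xlabel("position relative to cleavage site")
        ax.set_ylabel("frequency")
        ax.legend(ncol=4)
        fig.tight_layout()
        p = results_dir / "composition.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if missing:
        lines.append("missing results skipped: " + ", ".join(missing))
    summary = results_dir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
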