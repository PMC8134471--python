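"""End-to-end orchestration: simulate/load -> CPM -> permutation -> localization.

A single YAML (or dict) config drives the run.  Every stage writes
machine-readable outputs (JSON for scalars, TSV for tables) into the output
directory, and a ``manifest.json`` records the full config echo, package
version, per-stage timings, warnings, and SHA-256 checksums of every output
file — re-running the same config reproduces the outputs bit-identically.

Config layout::

    seed: 42
    out_dir: runs/demo
    stages: [simulate, cpm, permute, localize]
    simulate: {n_subjects: 69, n_nodes: 60, ...}     # or:
    inputs: {manifest: ..., atlas: ..., phenotypes: ...}
    cpm: {target: child_ari, condition: frustration, covariates: [motion],
          n_iterations: 100, n_folds: 10, selection_alpha: 0.01, ...}
    permute: {n_perm: 1000, perm_seed: 7}
    localize: {distance_threshold_mm: 60}
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (Atlas, load_atlas, load_matrices, load_phenotypes,
                    PhenotypeTable, vectorize)
from .cpm import CPMConfig, CPMResult, predictions_table, run_cpm
from .inference import permutation_test
from .localization import export_edge_list, summarize_network
from .synthetic import SyntheticSpec, generate_dataset, save_dataset

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "cpm", "permute", "localize")
_CPM_KEYS = {"target", "condition"} | {f.name for f in fields(CPMConfig)}


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    n_analyzed: int | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_config(cfg: dict) -> dict:
    """Collect every schema problem before raising."""
    problems = []
    if "seed" not in cfg:
        problems.append("missing required field: seed")
    stages = cfg.get("stages")
    if not stages:
        problems.append("missing or empty field: stages")
    else:
        for s in stages:
            if s not in KNOWN_STAGES:
                problems.append(f"unknown stage: {s}")
        if "simulate" not in stages and "inputs" not in cfg:
            problems.append("need either a simulate stage or an inputs block")
    if "cpm" in (stages or []):
        cpm_cfg = cfg.get("cpm", {})
        if "target" not in cpm_cfg:
            problems.append("cpm stage requires cpm.target")
        for key in cpm_cfg:
            if key not in _CPM_KEYS:
                problems.append(f"unknown cpm option: {key}")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return cfg


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    return yaml.safe_load(Path(config).read_text())


def run_pipeline(config: str | Path | dict,
                 out_dir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order and write all outputs.

    Returns the manifest (also written to ``manifest.json``).  A stage
    failure aborts the run after writing a manifest that records the stages
    completed so far.
    """
    cfg = _validate_config(_load_config(config))
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    collector = _WarningCollector()
    collector.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root_logger = logging.getLogger("cpmflow")
    root_logger.addHandler(collector)
    file_handler = logging.FileHandler(out / "run.log", mode="w")
    file_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger.addHandler(file_handler)

    manifest = RunManifest(config=cfg, version=__version__)
    seed = int(cfg["seed"])
    state: dict = {}
    try:
        for stage in cfg["stages"]:
            t0 = time.perf_counter()
            logger.info("stage %s started", stage)
            _STAGE_FNS[stage](cfg, seed, out, state, manifest)
            manifest.stages.append({
                "name": stage, "seconds": round(time.perf_counter() - t0, 3)})
    finally:
        manifest.warnings = list(collector.messages)
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                manifest.outputs[str(p.relative_to(out))] = _sha256(p)
        manifest.save(out / "manifest.json")
        root_logger.removeHandler(collector)
        root_logger.removeHandler(file_handler)
        file_handler.close()
    return manifest


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(cfg, seed, out, state, manifest):
    opts = dict(cfg.get("simulate", {}))
    opts.setdefault("seed", seed)
    spec = SyntheticSpec(**opts)
    dataset = generate_dataset(spec)
    save_dataset(dataset, out / "data")
    state["dataset"] = dataset
    state["atlas"] = dataset.atlas
    state["phenotypes"] = dataset.phenotypes


def _load_inputs(cfg, state):
    inputs = cfg["inputs"]
    state["atlas"] = load_atlas(inputs["atlas"])
    state["phenotypes"] = load_phenotypes(inputs["phenotypes"])
    state["manifest_path"] = inputs["manifest"]


def _edge_matrix_for(cfg, state, condition: str):
    """n_subjects x E edge matrix and subject ids for one condition."""
    if "dataset" in state:
        ds = state["dataset"]
        return ds.edge_matrix(condition), ds.subject_ids
    if "atlas" not in state:
        _load_inputs(cfg, state)
    if condition == "difference":
        frus = load_matrices(state["manifest_path"], "frustration")
        non = load_matrices(state["manifest_path"], "nonfrustration")
        ids = [m.subject_id for m in frus]
        order = {m.subject_id: m for m in non}
        x = np.stack([vectorize(f.values - order[f.subject_id].values)
                      for f in frus])
        return x, ids
    mats = load_matrices(state["manifest_path"], condition)
    return np.stack([vectorize(m) for m in mats]), [m.subject_id for m in mats]


def _stage_cpm(cfg, seed, out, state, manifest):
    opts = dict(cfg.get("cpm", {}))
    target = opts.pop("target")
    condition = opts.pop("condition", "frustration")
    opts.setdefault("seed", seed)
    opts["covariates"] = tuple(opts.get("covariates", ()))
    config = CPMConfig(**opts)

    x, subject_ids = _edge_matrix_for(cfg, state, condition)
    pheno: PhenotypeTable = state["phenotypes"]
    y = pheno.values_for(target, subject_ids)
    cov_tbl = pheno.table.set_index("subject_id").loc[subject_ids].reset_index()
    # listwise drop of subjects missing the target or a named covariate, so
    # downstream stages (permutation) see the same analyzable sample
    keep = np.isfinite(y)
    if config.covariates:
        keep &= np.all(np.isfinite(
            cov_tbl[list(config.covariates)].to_numpy(dtype=float)), axis=1)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    cov_tbl = cov_tbl.loc[keep].reset_index(drop=True)
    subject_ids = [s for s, k in zip(subject_ids, keep) if k]
    if n_dropped:
        logger.warning("dropped %d subject(s) missing %s or covariates",
                       n_dropped, target)
    result = run_cpm(x, y, config, cov_tbl if config.covariates else None,
                     subject_ids=subject_ids)
    result.n_dropped = n_dropped
    state.update(cpm_result=result, edge_matrix=x, behavior=y,
                 cpm_config=config, covariate_table=cov_tbl,
                 condition=condition, target=target)
    manifest.n_analyzed = len(result.behavior)

    predictions_table(result).to_csv(out / "predictions.tsv", sep="\t",
                                     index=False)
    atlas: Atlas = state["atlas"]
    export_edge_list(result.consensus_pos, atlas, out / "consensus_pos_edges.tsv")
    export_edge_list(result.consensus_neg, atlas, out / "consensus_neg_edges.tsv")
    summary = {
        "target": target, "condition": condition,
        "n_analyzed": manifest.n_analyzed, "n_dropped": result.n_dropped,
        "rho_median": result.rho_median, "rmse_median": result.rmse_median,
        "n_consensus_pos": int(result.consensus_pos.sum()),
        "n_consensus_neg": int(result.consensus_neg.sum()),
        "config": {**asdict(config), "covariates": list(config.covariates)},
    }
    (out / "cpm_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_permute(cfg, seed, out, state, manifest):
    if "cpm_result" not in state:
        raise RuntimeError("permute stage requires a completed cpm stage")
    opts = dict(cfg.get("permute", {}))
    n_perm = int(opts.get("n_perm", 1000))
    perm_seed = int(opts.get("perm_seed", seed + 10_000))
    config: CPMConfig = state["cpm_config"]
    cov = (state["covariate_table"][list(config.covariates)].to_numpy(dtype=float)
           if config.covariates else None)
    null = permutation_test(
        state["edge_matrix"], state["behavior"], config,
        rho_observed=state["cpm_result"].rho_median,
        n_perm=n_perm, perm_seed=perm_seed, covariate_matrix=cov,
        iterations_per_perm=int(opts.get("iterations_per_perm", 1)),
        reuse_folds=bool(opts.get("reuse_folds", False)))
    np.savetxt(out / "null_rho.txt", null.rho_null, fmt="%.10g")
    (out / "permutation.json").write_text(json.dumps({
        "rho_median": null.rho_observed, "p": null.p, "n_perm": null.n_perm,
        "perm_seed": perm_seed, "tail": "one-tailed"}, indent=2))
    state["permutation"] = null


def _stage_localize(cfg, seed, out, state, manifest):
    if "cpm_result" not in state:
        raise RuntimeError("localize stage requires a completed cpm stage")
    opts = dict(cfg.get("localize", {}))
    atlas: Atlas = state["atlas"]
    result: CPMResult = state["cpm_result"]
    loc = {}
    for sign, mask in (("pos", result.consensus_pos),
                       ("neg", result.consensus_neg)):
        if not mask.any():
            loc[sign] = {"total_edges": 0, "note": "empty network, skipped"}
            continue
        s = summarize_network(
            mask, atlas,
            distance_threshold_mm=float(opts.get("distance_threshold_mm", 60.0)),
            expected_proportions=opts.get("expected_proportions"))
        s.network_matrix.to_csv(out / f"network_matrix_{sign}.tsv", sep="\t")
        s.region_matrix.to_csv(out / f"region_matrix_{sign}.tsv", sep="\t")
        loc[sign] = {
            "total_edges": s.total_edges,
            "degree": s.degree.tolist(),
            "hemisphere_counts": s.hemisphere_counts,
            "range_counts": {
                "long": s.range_counts.long, "short": s.range_counts.short,
                "chi2": s.range_counts.chi2, "p": s.range_counts.p,
                "threshold_mm": s.range_counts.threshold_mm,
                "expected_proportions": list(s.range_counts.expected_proportions),
            },
        }
    (out / "localization.json").write_text(json.dumps(loc, indent=2))


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "cpm": _stage_cpm,
    "permute": _stage_permute,
    "localize": _stage_localize,
}


# ---------------------------------------------------------------------------
# Reporting


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run, from its JSON outputs."""
    run = Path(run_dir)
    cpm_path = run / "cpm_summary.json"
    if not cpm_path.exists():
        raise FileNotFoundError(f"no cpm_summary.json in {run} (cpm stage missing)")
    cpm = json.loads(cpm_path.read_text())
    lines = [
        f"CPM prediction of {cpm['target']} from {cpm['condition']} connectivity",
        f"  n = {cpm['n_analyzed']} subjects analyzed"
        + (f" ({cpm['n_dropped']} dropped for missing data)" if cpm["n_dropped"] else ""),
        f"  median model of {cpm['config']['n_iterations']} iterations of "
        f"{cpm['config']['n_folds']}-fold cross-validation:",
    ]
    perm_path = run / "permutation.json"
    if perm_path.exists():
        perm = json.loads(perm_path.read_text())
        lines.append(
            f"  ρ = {cpm['rho_median']:.2f}, RMSE = {cpm['rmse_median']:.2f}, "
            f"p = {perm['p']:.3g} (permutation testing, {perm['n_perm']} "
            f"iterations, one-tailed)")
    else:
        lines.append(
            f"  ρ = {cpm['rho_median']:.2f}, RMSE = {cpm['rmse_median']:.2f} "
            "(no permutation stage run; p not available)")
    lines.append(
        f"  consensus networks: {cpm['n_consensus_pos']} positive, "
        f"{cpm['n_consensus_neg']} negative edges")
    loc_path = run / "localization.json"
    if loc_path.exists():
        loc = json.loads(loc_path.read_text())
        for sign, label in (("pos", "positive"), ("neg", "negative")):
            if sign not in loc:
                continue
            d = loc[sign]
            if d.get("total_edges", 0) == 0:
                lines.append(f"  {label} network: 0 edges, localization skipped")
                continue
            h = d["hemisphere_counts"]
            r = d["range_counts"]
            pct_long = 100.0 * r["long"] / d["total_edges"]
            lines.append(
                f"  {label} network: {d['total_edges']} edges — "
                f"{h['ipsi_R']} ipsilateral right, {h['ipsi_L']} ipsilateral left, "
                f"{h['inter']} interhemispheric; "
                f"{pct_long:.0f}% long range at {r['threshold_mm']:.0f} mm "
                f"(χ² = {r['chi2']:.2f}, p = {r['p']:.2g})")
    return "\n".join(lines)
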