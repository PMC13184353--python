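"""Pipeline orchestration: staged runs, per-stage seeds, output manifest.

A run is described by one structured config (YAML/dict): a master seed, an
output directory, an ordered stage list and per-stage parameter blocks.
Stage seeds are derived by stable hashing of (master seed, stage name), so
adding or reordering stages never perturbs another stage's draws.  Every
output file is recorded in a manifest with its SHA-256 hash; rerunning the
same config reproduces all outputs bit-exactly.
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

from . import __version__
from .cfa import cfa_fit, default_ami_spec
from .efa import run_efa
from .lifespan import WindowSpec, lifespan_scan_by_cohort, mode_sensitivity, purity_anova
from .network import (
    spearman_network,
    stable_partition,
    summarise_modules,
    between_domain_connectivity,
    to_graphml,
)
from .scales import CohortDataset, battery_scale, builtin_scale, read_dataset, write_dataset
from .simulate import CohortSimSpec, planted_module_spec, scale_factor_spec, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "efa", "cfa", "network", "lifespan", "sensitivity")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of '(master):(stage)', below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated run description."""

    stages: list[str]
    seed: int = 0
    outdir: Path = Path("apathynet_out")
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")


def load_config(path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(
        stages=list(raw.get("stages", [])),
        seed=int(raw.get("seed", 0)),
        outdir=Path(raw.get("outdir", "apathynet_out")),
        params={k: v for k, v in raw.items() if k in STAGES and isinstance(v, dict)},
    )


def _resolve_scale(name: str):
    if name == "battery":
        return battery_scale()
    return builtin_scale(name)


def _validate_config(cfg: RunConfig) -> None:
    """Fail before any stage runs: check inputs exist and carry the needed columns."""
    for stage in cfg.stages:
        p = cfg.params.get(stage, {})
        path = p.get("input")
        if path is None:
            continue
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"stage {stage!r}: input file {path} does not exist")
        header = pd.read_csv(path, nrows=0, sep=None, engine="python").columns.tolist()
        needed = ["id", "cohort", "age"]
        scale_name = p.get("scale", "AMI")
        needed += list(_resolve_scale(scale_name).items)
        missing = [c for c in needed if c not in header]
        if missing:
            raise ValueError(f"stage {stage!r}: input {path} lacks columns {missing}")


def _model_from_params(p: dict):
    m = p.get("model", {"kind": "scale", "scale": "AMI"})
    kind = m.get("kind", "scale")
    if kind == "scale":
        return scale_factor_spec(
            _resolve_scale(m.get("scale", "AMI")),
            within_load=float(m.get("within_load", 0.7)),
            between_corr=float(m.get("between_corr", 0.3)),
        )
    if kind == "planted":
        return planted_module_spec(
            int(m.get("k_modules", 3)),
            int(m.get("items_per_module", 6)),
            float(m.get("within_load", 0.7)),
            float(m.get("between_corr", 0.3)),
        )
    raise ValueError(f"unknown model kind {m.get('kind')!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_stage_dataset(p: dict, ds_in_memory: CohortDataset | None) -> CohortDataset:
    if "input" in p:
        return read_dataset(p["input"], _resolve_scale(p.get("scale", "AMI")))
    if ds_in_memory is None:
        raise ValueError("stage needs an 'input' file or an upstream simulate stage")
    return ds_in_memory


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write the manifest.

    On stage failure the manifest records partial completion and the
    exception propagates (the CLI exits non-zero).
    """
    _validate_config(cfg)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": cfg.seed,
        "stages": [],
        "completed": False,
        "log": [],
    }

    def log(stage: str, msg: str) -> None:
        entry = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, "message": msg}
        manifest["log"].append(entry)
        logger.info("[%s] %s", stage, msg)

    def record(stage: str, seed: int | None, params: dict, outputs: list[Path]) -> None:
        manifest["stages"].append({
            "name": stage,
            "seed": seed,
            "params": params,
            "outputs": [{"path": str(o), "sha256": _sha256(o)} for o in outputs],
        })

    dataset: CohortDataset | None = None
    try:
        for stage in cfg.stages:
            p = dict(cfg.params.get(stage, {}))
            seed = stage_seed(cfg.seed, stage)
            log(stage, "started")
            if stage == "simulate":
                spec = CohortSimSpec(
                    n=int(p.get("n", 1000)),
                    model=_model_from_params(p),
                    cohort_label=p.get("cohort_label", "HC"),
                    age_min=float(p.get("age_min", 16)),
                    age_max=float(p.get("age_max", 90)),
                    mode_probs=p.get("mode_probs"),
                    seed=seed,
                )
                dataset = simulate_cohort(spec)
                out = cfg.outdir / "dataset.csv"
                write_dataset(dataset, out)
                record(stage, seed, p, [out])
            elif stage == "efa":
                ds = _load_stage_dataset(p, dataset)
                rep = run_efa(
                    ds,
                    k=p.get("k"),
                    rotation=p.get("rotation", "promax"),
                    promax_power=int(p.get("promax_power", 4)),
                )
                loadings = pd.DataFrame(
                    rep.solution.pattern,
                    index=list(rep.solution.item_ids),
                    columns=[f"F{j + 1}" for j in range(rep.n_factors)],
                )
                outs = []
                for name, obj in [
                    ("efa_loadings.csv", loadings),
                    ("efa_factor_corr.csv", pd.DataFrame(rep.solution.factor_corr)),
                    ("efa_purity.csv", rep.purity.per_item),
                ]:
                    out = cfg.outdir / name
                    obj.to_csv(out)
                    outs.append(out)
                out = cfg.outdir / "efa_log.txt"
                chi2, dof, pval = rep.bartlett
                lines = [
                    f"n = {rep.n}",
                    f"KMO = {rep.kmo:.4f} ({rep.kmo_label})",
                    f"Bartlett chi2({dof}) = {chi2:.1f}, p = {pval:.3g}",
                    f"factors retained (Kaiser) = {rep.n_factors}",
                ]
                if rep.solution.fit is not None:
                    c2, fdf, fp = rep.solution.fit
                    lines.append(f"ML fit chi2 = {c2:.1f}, df = {int(fdf)}, p = {fp:.3g}")
                out.write_text("\n".join(lines) + "\n", encoding="utf-8")
                outs.append(out)
                record(stage, None, p, outs)
            elif stage == "cfa":
                ds = _load_stage_dataset(p, dataset)
                spec = default_ami_spec(tuple(p.get("excluded", ("AMI-2", "AMI-6", "AMI-8"))))
                fit = cfa_fit(ds, spec)
                out = cfg.outdir / "cfa_fit.json"
                out.write_text(json.dumps({
                    "chi2": fit.chi2, "df": fit.df, "p": fit.p,
                    "cfi": fit.cfi, "tli": fit.tli, "rmsea": fit.rmsea,
                    "rmsea_ci90": list(fit.rmsea_ci90), "srmr": fit.srmr,
                    "n": fit.n, "converged": fit.converged,
                    "loadings": fit.loadings.to_dict(),
                    "factor_corr": fit.factor_corr.to_dict(),
                }, indent=2), encoding="utf-8")
                record(stage, None, p, [out])
            elif stage == "network":
                ds = _load_stage_dataset(p, dataset)
                if "cohort" in p:
                    ds = ds.subset(np.asarray(ds.cohort) == p["cohort"])
                net = spearman_network(ds)
                census = stable_partition(net, n_restarts=int(p.get("n_restarts", 1000)), seed=seed)
                modules = summarise_modules(net, census.modal)
                rows = [{
                    "module": i, "modal_domain": m.modal_domain, "purity": m.purity,
                    "central_node": m.central_node, "members": ";".join(m.members),
                    "modal_share": census.modal_share,
                } for i, m in enumerate(modules)]
                outs = []
                out = cfg.outdir / "network_modules.csv"
                pd.DataFrame(rows).to_csv(out, index=False)
                outs.append(out)
                out = cfg.outdir / "network_weights.csv"
                pd.DataFrame(net.W, index=list(net.items), columns=list(net.items)).to_csv(out)
                outs.append(out)
                out = cfg.outdir / "network_bdc.csv"
                between_domain_connectivity(net).to_csv(out)
                outs.append(out)
                out = cfg.outdir / "network.graphml"
                to_graphml(net, out, census.modal, threshold=float(p.get("threshold", 0.1)))
                outs.append(out)
                record(stage, seed, p, outs)
            elif stage == "lifespan":
                ds = _load_stage_dataset(p, dataset)
                spec = WindowSpec.from_ages(
                    ds.age,
                    step=float(p.get("step", 1.0)),
                    width=float(p.get("width", 10.0)),
                    sigma=float(p.get("sigma", 5.0)),
                    min_ess=float(p.get("min_ess", 30.0)),
                )
                trajs = lifespan_scan_by_cohort(
                    ds, spec, n_restarts=int(p.get("n_restarts", 1000)), seed=seed
                )
                table = pd.concat([t.table for t in trajs.values()], ignore_index=True)
                outs = []
                out = cfg.outdir / "lifespan_trajectory.csv"
                table.to_csv(out, index=False)
                outs.append(out)
                records = pd.concat([t.purity_records() for t in trajs.values()], ignore_index=True)
                if records["group"].nunique() >= 2 and records["domain"].nunique() >= 2:
                    out = cfg.outdir / "lifespan_anova.csv"
                    purity_anova(records).to_csv(out)
                    outs.append(out)
                record(stage, seed, p, outs)
            elif stage == "sensitivity":
                ds = _load_stage_dataset(p, dataset)
                rep = mode_sensitivity(ds, n_restarts=int(p.get("n_restarts", 1000)), seed=seed)
                rows = []
                for mode, r in rep["modes"].items():
                    for i, m in enumerate(r["modules"]):
                        rows.append({
                            "mode": mode, "n": r["n"], "module": i,
                            "modal_domain": m.modal_domain, "purity": m.purity,
                            "central_node": m.central_node,
                            "modal_share": r["census"].modal_share,
                            "members": ";".join(m.members),
                        })
                outs = []
                out = cfg.outdir / "sensitivity_modules.csv"
                pd.DataFrame(rows).to_csv(out, index=False)
                outs.append(out)
                if rep["agreement"] is not None:
                    out = cfg.outdir / "sensitivity_agreement.csv"
                    rep["agreement"]["per_item"].to_csv(out, index=False)
                    outs.append(out)
                record(stage, seed, p, outs)
            log(stage, "finished")
    except Exception as exc:
        log("pipeline", f"FAILED: {exc}")
        (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        raise
    manifest["completed"] = True
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
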