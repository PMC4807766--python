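"""End-to-end orchestration: cluster -> project -> fit -> consensus -> compare.

A run is driven by a flat INI-style configuration; every stage's outputs are
written under one directory and listed, with checksums, in a manifest so the
provenance of each artifact is auditable.  A resolved copy of the
configuration is written next to the outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import consensus as cns
from . import sensitivity as sens
from .clustering import cluster_scenarios, result_to_dict
from .errors import ValidationError
from .fixtures import (GradientSpec, VirtualSpeciesSpec, make_baseline_grid,
                       make_virtual_species, table2_fixture)
from .projection import ClimateGrid, apply_change_field, percentile_fields
from .scenario_io import (CellTable, read_cell_table, read_scenario_table,
                          write_cell_table, write_scenario_table)
from .sdm import (OccurrenceData, default_algorithm_slots, fit_ensemble,
                  project_stack, stack_to_frame)

log = logging.getLogger("scenoset.pipeline")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    table: str | None = None          # scenario delta table; packaged table if None
    baseline: str | None = None       # baseline climatology; synthetic if None
    occurrences: str | None = None    # occurrence table; virtual species if None
    n_cells: int = 900
    fixture_seed: int = 0
    k: str = "auto"
    restarts: int = 999
    cluster_seed: int = 0
    cost_weight: float = 1.0
    repeats: int = 20
    slots: int = 7
    sdm_seed: int = 0
    run_sensitivity: bool = False
    sensitivity_cap: int = 10_000
    out_dir: str = "scenoset_run"

    @classmethod
    def from_ini(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        parser = configparser.ConfigParser()
        parser.read(path)
        kw: dict = {}
        get = {"inputs": ("table", "baseline", "occurrences"),
               "fixtures": ("n_cells", "fixture_seed"),
               "cluster": ("k", "restarts", "cluster_seed", "cost_weight"),
               "sdm": ("repeats", "slots", "sdm_seed"),
               "sensitivity": ("run_sensitivity", "sensitivity_cap"),
               "output": ("out_dir",)}
        for section in parser.sections():
            if section not in get:
                raise ValidationError(f"unknown config section [{section}]")
            for name in parser.options(section):
                if name not in get[section]:
                    raise ValidationError(
                        f"unknown config key {name!r} in section [{section}]")
                kw[name] = parser.get(section, name)
        if overrides:
            kw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**_coerce(kw))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("table", "baseline", "occurrences"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"configured {attr} path does not exist: {p}")
        if self.k != "auto":
            int(self.k)
        for name in ("restarts", "repeats", "slots", "n_cells"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def _coerce(kw: dict) -> dict:
    types = {f.name: f.type for f in RunConfig.__dataclass_fields__.values()}
    out = {}
    for name, val in kw.items():
        if name not in types:
            raise ValidationError(f"unknown config key {name!r}")
        if val is None or name in ("table", "baseline", "occurrences", "k", "out_dir"):
            out[name] = val
        elif name == "run_sensitivity":
            out[name] = str(val).strip().lower() in ("1", "true", "yes", "on")
        elif name == "cost_weight":
            out[name] = float(val)
        else:
            out[name] = int(val)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}}

    def emit(stage: str, name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(name)
        return path

    # resolved config snapshot
    emit("config", "config.resolved.json",
         lambda p: p.write_text(json.dumps(asdict(config), indent=2)))

    # --- inputs ------------------------------------------------------------
    table = (read_scenario_table(config.table) if config.table
             else table2_fixture())
    emit("inputs", "scenarios.csv", lambda p: write_scenario_table(table, p))
    if config.baseline:
        baseline = ClimateGrid(read_cell_table(config.baseline))
    else:
        baseline = make_baseline_grid(config.n_cells, rng_seed=config.fixture_seed)
    emit("inputs", "baseline.csv", lambda p: write_cell_table(baseline.cells, p))
    if config.occurrences:
        occ_cells = read_cell_table(config.occurrences)
        occ = OccurrenceData(occ_cells)
    else:
        occ = make_virtual_species(
            baseline, VirtualSpeciesSpec(rng_seed=config.fixture_seed))
    if not occ.cells.same_cells(baseline.cells):
        raise ValidationError("occurrence cells do not match the baseline grid")
    emit("inputs", "occurrences.csv", lambda p: write_cell_table(occ.cells, p))

    # --- clustering --------------------------------------------------------
    res = cluster_scenarios(table, k=config.k, restarts=config.restarts,
                            rng_seed=config.cluster_seed,
                            cost_weight=config.cost_weight)
    emit("cluster", "solution.json",
         lambda p: p.write_text(json.dumps(result_to_dict(res, table), indent=2)))

    # --- projection --------------------------------------------------------
    future_all = [apply_change_field(baseline, s) for s in table.scenarios]
    rep_keys = res.representatives.keys
    future_rep = [g for g, s in zip(future_all, table.scenarios) if s.key in rep_keys]
    for g in future_rep:
        safe = g.period.replace(":", "_").replace(" ", "").replace("/", "-")
        emit("project", f"future_{safe}.csv", lambda p, g=g: write_cell_table(g.cells, p))
    pf_all = percentile_fields(future_all)
    pf_rep = percentile_fields(future_rep, weights=res.representatives.weights)

    def _pf_table(pf):
        cols = {}
        for v in pf.mean:
            cols[f"{v}_p10"] = pf.p10[v]
            cols[f"{v}_mean"] = pf.mean[v]
            cols[f"{v}_p90"] = pf.p90[v]
        return CellTable(pf.cell_ids, cols)

    emit("project", "percentiles_full.csv",
         lambda p: write_cell_table(_pf_table(pf_all), p))
    emit("project", "percentiles_representative.csv",
         lambda p: write_cell_table(_pf_table(pf_rep), p))

    # --- SDM ensemble ------------------------------------------------------
    models = fit_ensemble(occ, repeats=config.repeats,
                          slots=default_algorithm_slots(config.slots),
                          rng_seed=config.sdm_seed)
    emit("fit", "models.json", lambda p: p.write_text(json.dumps(
        [{"model_id": m.model_id, "auc": m.auc, "converged": m.converged}
         for m in models], indent=2)))

    # --- reference consensus and threshold ---------------------------------
    ref_stack = project_stack(models, [baseline])
    ref_cons = cns.consensus_auc_weighted(ref_stack)
    thr = cns.max_sss_threshold(ref_cons, occ)
    ref_bin = cns.binarize(ref_cons, thr)
    emit("consensus", "reference_consensus.csv", lambda p: write_cell_table(
        CellTable(ref_bin.cell_ids, {"p": ref_bin.probability,
                                     "presence": ref_bin.binary.astype(float)}), p))
    emit("consensus", "threshold.json",
         lambda p: p.write_text(json.dumps({"threshold": thr}, indent=2)))

    # --- future consensus, both modes --------------------------------------
    stack_full = project_stack(models, future_all)
    stack_rep = stack_full.subset_scenarios(rep_keys)
    cons_full = cns.binarize(cns.consensus_auc_weighted(stack_full), thr)
    cons_eq1 = cns.binarize(cns.consensus_eq1(stack_rep, res.representatives), thr)
    emit("consensus", "future_consensus_full.csv", lambda p: write_cell_table(
        CellTable(cons_full.cell_ids, {"p": cons_full.probability,
                                       "presence": cons_full.binary.astype(float)}), p))
    emit("consensus", "future_consensus_eq1.csv", lambda p: write_cell_table(
        CellTable(cons_eq1.cell_ids, {"p": cons_eq1.probability,
                                      "presence": cons_eq1.binary.astype(float)}), p))

    # --- comparison --------------------------------------------------------
    rc_full = cns.range_change(ref_bin, cons_full)
    rc_eq1 = cns.range_change(ref_bin, cons_eq1)
    diff = cns.difference_map(cons_full, cons_eq1)
    emit("compare", "range_change.json", lambda p: p.write_text(json.dumps({
        "full_27": asdict(rc_full), "eq1_representatives": asdict(rc_eq1),
        "difference_counts": diff.counts()}, indent=2)))
    emit("compare", "difference_map.csv", lambda p: write_cell_table(
        CellTable(diff.cell_ids,
                  {"category": np.array([{"agree-presence": 0, "agree-absence": 1,
                                          "only-in-a": 2, "only-in-b": 3}[c]
                                         for c in diff.category], dtype=float)}), p))

    # --- sensitivity (optional) --------------------------------------------
    if config.run_sensitivity:
        runs, spread = sens.run_sensitivity(stack_full, ref_bin, thr,
                                            cap=config.sensitivity_cap,
                                            rng_seed=config.cluster_seed)
        emit("sensitivity", "sensitivity.json", lambda p: p.write_text(json.dumps({
            "runs": [asdict(r) for r in runs],
            "gain_spread": spread.gain_spread,
            "loss_spread": spread.loss_spread}, indent=2)))

    emit("manifest", "manifest.json",
         lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True)))
    return manifest
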