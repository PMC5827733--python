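"""End-to-end orchestration of the coupling workflow.

``run_pipeline`` executes the full chain — load → xenobiotic extension →
fasted-state bounds → expression scores → iMAT → flux minimization → PK
simulation (or user rate table) → dynamic MOMA → perturbation report —
and writes machine-readable outputs plus a manifest (config hash,
package/solver versions, per-stage timing) into the output directory.

Defaults mirror the workflow's published operating point: 72 h total
simulation (4320 min), 1-min coupling step, activity threshold
ε = 1e-5 µmol·liver⁻¹·min⁻¹ and biomass minimum 1e-4 µmol·liver⁻¹·min⁻¹.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from dynamoma._version import __version__ as _pkg_version
from dynamoma.coupling import DynamicMOMA
from dynamoma.fixtures import generate_toy_fixture
from dynamoma.metrics import PathwayClustering, compare_reports, perturbation_report
from dynamoma.network import load_network
from dynamoma.pbpk import acetylator_preset, multi_dose, read_rate_table, resample
from dynamoma.reference import (
    DEFAULT_BIOMASS_MIN,
    DEFAULT_EPSILON,
    ExpressionProfile,
    build_reference_state,
    read_utilization_table,
)
from dynamoma.xenobiotic import extend_network, isoniazid_preset, load_xenobiotic_specs

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (YAML-loadable)."""

    network_path: str = ""
    network_format: str = "json"
    expression_path: str = ""
    utilization_path: str = ""
    clusters_path: str = ""
    #: "isoniazid" or a path to a xenobiotic spec JSON
    xenobiotic: str = "isoniazid"
    #: acetylator phenotype for the built-in PK driver
    phenotype: str = "fast"
    #: path to a user-supplied rate table CSV; empty = simulate
    rate_table_path: str = ""
    dose_umol: float = 300e3 / 137.14
    n_doses: int = 1
    dose_interval_min: float = 1440.0
    duration_min: float = 4320.0
    dt_min: float = 1.0
    epsilon: float = DEFAULT_EPSILON
    biomass_min: float = DEFAULT_BIOMASS_MIN
    relax: bool = False
    outdir: str = "dynamoma_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, timings: dict[str, float], outdir: str) -> None:
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.digest(),
        "versions": {
            "dynamoma": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "solver": "scipy HiGHS (LP/MILP) + dense active-set QP",
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def run_pipeline(cfg: RunConfig) -> str:
    """Execute all stages; returns the output directory path."""
    os.makedirs(cfg.outdir, exist_ok=True)
    timings: dict[str, float] = {}
    state: dict = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            # leave a replayable partial-state bundle behind
            with open(os.path.join(cfg.outdir, "error.json"), "w") as fh:
                json.dump(
                    {"stage": name, "error": str(exc),
                     "completed_stages": list(timings)},
                    fh, indent=1,
                )
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %-14s %.2fs", name, timings[name])

    def s_load():
        state["net"] = load_network(cfg.network_path, cfg.network_format)

    def s_extend():
        if cfg.xenobiotic == "isoniazid":
            specs = isoniazid_preset(state["net"])
        else:
            specs = load_xenobiotic_specs(cfg.xenobiotic)
        state["net_x"] = extend_network(state["net"], specs)

    def s_reference():
        expr = ExpressionProfile.from_tsv(cfg.expression_path)
        util = read_utilization_table(cfg.utilization_path)
        ref = build_reference_state(
            state["net_x"], expr, util, eps=cfg.epsilon, biomass_min=cfg.biomass_min
        )
        ref.save(os.path.join(cfg.outdir, "reference"))
        state["ref"] = ref

    def s_rates():
        if cfg.rate_table_path:
            series = read_rate_table(cfg.rate_table_path)
        else:
            model = acetylator_preset(cfg.phenotype, dose_umol=cfg.dose_umol)
            if cfg.n_doses > 1:
                model = multi_dose(model, cfg.n_doses, cfg.dose_interval_min)
            sim = model.simulate(duration=cfg.duration_min, dt=1.0)
            series = sim.series
            sim.excretion_ledger().to_csv(
                os.path.join(cfg.outdir, "excretion_ledger.csv"), index=False
            )
        if cfg.dt_min != series.dt:
            series = resample(series, cfg.dt_min)
        # drop driver columns with no counterpart in the context network
        keep = [
            i for i, rid in enumerate(series.reaction_ids)
            if state["ref"].network.has_reaction(rid)
        ]
        if len(keep) < len(series.reaction_ids):
            dropped = [r for i, r in enumerate(series.reaction_ids) if i not in keep]
            logger.warning("rate columns without network reactions dropped: %s", dropped)
            from dynamoma.pbpk import RateTimeSeries

            series = RateTimeSeries(
                times=series.times,
                rates=series.rates[:, keep],
                reaction_ids=[series.reaction_ids[i] for i in keep],
            )
        series.to_csv(os.path.join(cfg.outdir, "rate_table.csv"))
        state["series"] = series

    def s_dmoma():
        model = DynamicMOMA(state["ref"], state["series"], relax=cfg.relax)
        res = model.fit()
        res.flux_matrix.save(
            os.path.join(cfg.outdir, "flux_matrix.csv"),
            os.path.join(cfg.outdir, "flux_matrix.json"),
        )
        state["results"] = res

    def s_report():
        net_ctx = state["ref"].network
        clustering = PathwayClustering.from_network(net_ctx)
        if cfg.clusters_path:
            # user labels override network labels; entries for reactions
            # pruned during contextualization are dropped
            user = PathwayClustering.from_csv(cfg.clusters_path).restrict_to(net_ctx)
            clustering = PathwayClustering({**clustering.mapping, **user.mapping})
        rep = perturbation_report(state["results"].flux_matrix, state["ref"], clustering)
        tables = rep.to_tables()
        tables["reactions"].to_csv(os.path.join(cfg.outdir, "report_reactions.csv"), index=False)
        tables["clusters"].to_csv(os.path.join(cfg.outdir, "report_clusters.csv"), index=False)
        tables["exchanges"].to_csv(os.path.join(cfg.outdir, "report_exchanges.csv"), index=False)
        pd.DataFrame(
            {"time_min": rep.times, "altered_fraction": rep.altered_fraction}
        ).to_csv(os.path.join(cfg.outdir, "altered_fraction.csv"), index=False)
        at = {cl: curve for cl, curve in rep.at_mp.items() if curve.size}
        if at:
            pd.DataFrame(at, index=rep.times[1:]).rename_axis("time_min").to_csv(
                os.path.join(cfg.outdir, "attenuation.csv")
            )
        with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
            json.dump(rep.to_json_dict(), fh, indent=1)
            fh.write("\n")
        state["report"] = rep

    stage("load", s_load)
    stage("extend", s_extend)
    stage("reference", s_reference)
    stage("rates", s_rates)
    stage("dmoma", s_dmoma)
    stage("report", s_report)
    _write_manifest(cfg, timings, cfg.outdir)
    return cfg.outdir


def compare_runs(run_a: str, run_b: str) -> dict[str, pd.DataFrame]:
    """Per-cluster pathway-score and per-exchange pool differences (b − a).

    Both runs must have used the same context network (checked through the
    reference network files).
    """
    net_a = os.path.join(run_a, "reference", "context_network.json")
    net_b = os.path.join(run_b, "reference", "context_network.json")
    if os.path.exists(net_a) and os.path.exists(net_b):
        with open(net_a) as fa, open(net_b) as fb:
            if fa.read() != fb.read():
                raise ValueError("runs used different context networks")

    def _read(run):
        clusters = pd.read_csv(os.path.join(run, "report_clusters.csv"))
        pools = pd.read_csv(os.path.join(run, "report_exchanges.csv"))
        return clusters, pools

    ca, pa = _read(run_a)
    cb, pb = _read(run_b)
    cl = pd.merge(ca, cb, on="cluster", how="outer", suffixes=("_a", "_b")).fillna(0.0)
    cl["score_diff_b_minus_a"] = cl["pathway_score_b"] - cl["pathway_score_a"]
    px = pd.merge(
        pa[["exchange_id", "signed_change_umol"]],
        pb[["exchange_id", "signed_change_umol"]],
        on="exchange_id", how="outer", suffixes=("_a", "_b"),
    ).fillna(0.0)
    px["signed_diff_b_minus_a"] = (
        px["signed_change_umol_b"] - px["signed_change_umol_a"]
    )
    return {"pathway_scores": cl, "pools": px}


def make_fixture(seed: int, size: str, outdir: str) -> dict[str, str]:
    """Generate and write the toy fixture bundle; returns file paths."""
    return generate_toy_fixture(seed=seed, size=size).write(outdir)
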