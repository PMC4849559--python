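"""End-to-end pipeline: simulate → fit → stratify → run → psa → price.

Each stage reads its inputs from, and writes its artefacts to, the run
directory, so stages can be re-run independently.  A single global seed
is fanned out into per-stage substreams; a manifest records seeds,
artefact hashes and fit diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from scadmodel import io as sio
from scadmodel.config import RunConfig
from scadmodel.costs import CostModel, fit_cost_model
from scadmodel.equations import RiskEquationSet, fit_equation_set
from scadmodel.markov import TreatmentEffect, run_cohort
from scadmodel.pricing import pricing_grid
from scadmodel.stratify import assign_risk_groups, group_summary, run_psa
from scadmodel.synthetic import (
    default_true_parameters,
    generate_cohort,
    simulate_cost_panel,
    simulate_event_histories,
    synthetic_life_table,
    synthetic_utility_catalogue,
)

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "stratify", "run", "psa", "price")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _outdir(config: RunConfig) -> Path:
    d = Path(config.output_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(config: RunConfig) -> None:
    out = _outdir(config)
    seeds = _stage_seeds(config.seed)
    truth = default_true_parameters(config.generator)
    cohort = generate_cohort(config.cohort_size, seeds["simulate"], config.generator)
    histories = simulate_event_histories(cohort, truth, seeds["simulate"] + 1)
    panel = simulate_cost_panel(cohort, histories, truth, seeds["simulate"] + 2)
    cohort.to_csv(out / "cohort.csv", index=False)
    histories.to_csv(out / "histories.csv", index=False)
    panel.to_csv(out / "cost_panel.csv", index=False)
    sio.write_life_table(synthetic_life_table(), out / "life_table.csv")
    sio.write_utility_catalogue(synthetic_utility_catalogue(), out / "utility_catalogue.csv")
    log.info("simulate: %d patients, %d panel rows", len(cohort), len(panel))


def stage_fit(config: RunConfig) -> None:
    out = _outdir(config)
    cohort = pd.read_csv(out / "cohort.csv")
    histories = pd.read_csv(out / "histories.csv")
    panel = pd.read_csv(out / "cost_panel.csv")
    life_table = sio.read_life_table(out / "life_table.csv")
    equations = fit_equation_set(
        cohort, histories, life_table,
        candidate_families=config.families, splice_time=config.splice_time,
    )
    cost_model = fit_cost_model(panel, cohort)
    (out / "equations.json").write_text(json.dumps(equations.to_dict()))
    (out / "cost_model.json").write_text(json.dumps(cost_model.to_dict()))
    diagnostics = {
        "primary": {
            k: {"family": f.family, "aic": f.aic, "loglik": f.loglik, "n_events": f.n_events}
            for k, f in equations.primary.items()
        },
        "post": {
            f"{e}|{c}": {"family": f.family, "aic": f.aic, "loglik": f.loglik,
                         "n_events": f.n_events}
            for (e, c), f in equations.post.items()
        },
    }
    (out / "fit_diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    log.info("fit: %d equations", equations.n_equations)


def _load_fitted(out: Path):
    equations = RiskEquationSet.from_dict(json.loads((out / "equations.json").read_text()))
    cost_model = CostModel.from_dict(json.loads((out / "cost_model.json").read_text()))
    utilities = sio.read_utility_catalogue(out / "utility_catalogue.csv")
    return equations, cost_model, utilities


def stage_stratify(config: RunConfig) -> None:
    out = _outdir(config)
    cohort = pd.read_csv(out / "cohort.csv")
    equations, _, _ = _load_fitted(out)
    groups = assign_risk_groups(cohort, equations, k=config.n_groups)
    group_summary(groups).to_csv(out / "groups.csv", index=False)
    assignments = pd.concat(
        [pd.DataFrame({"patient_id": g.members["patient_id"], "risk_group": g.index,
                       "risk_5yr": g.risks}) for g in groups],
        ignore_index=True,
    )
    assignments.to_csv(out / "group_assignments.csv", index=False)
    log.info("stratify: %d groups", len(groups))


def _group_profiles(out: Path, config: RunConfig) -> pd.DataFrame:
    groups = pd.read_csv(out / "groups.csv")
    cols = [c for c in groups.columns if c.startswith("mean_") and c != "mean_5yr_risk"]
    prof = groups[["risk_group", *cols]].rename(
        columns={c: c[len("mean_"):] for c in cols}
    )
    return prof


def stage_run(config: RunConfig) -> None:
    out = _outdir(config)
    equations, cost_model, utilities = _load_fitted(out)
    profiles = _group_profiles(out, config)
    rows = []
    traces = []
    for _, row in profiles.iterrows():
        gi = int(row["risk_group"])
        profile = row.drop("risk_group")
        for rho in (0.0, *config.rho_list):
            treatment = None if rho == 0.0 else TreatmentEffect(
                rho, config.treat_haemorrhagic, config.treat_post_event
            )
            trace, outputs = run_cohort(
                profile, equations, cost_model, utilities,
                discount_rate=config.discount_rate, treatment=treatment,
                horizon_years=config.horizon_years,
            )
            rows.append({"risk_group": gi, "rho": rho, **outputs.to_dict()})
            if rho == 0.0:
                tf = trace.to_frame()
                tf.insert(0, "risk_group", gi)
                traces.append(tf)
    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    pd.concat(traces, ignore_index=True).to_csv(out / "occupancy_traces.csv", index=False)
    log.info("run: %d model runs", len(rows))


def stage_psa(config: RunConfig) -> None:
    out = _outdir(config)
    seeds = _stage_seeds(config.seed)
    equations, cost_model, utilities = _load_fitted(out)
    profiles = _group_profiles(out, config)
    rows = []
    for i, (_, row) in enumerate(profiles.iterrows()):
        gi = int(row["risk_group"])
        res = run_psa(
            row.drop("risk_group"), equations, cost_model, utilities,
            n_iter=config.psa_iterations, seed=seeds["psa"] + i,
            discount_rate=config.discount_rate, horizon_years=config.horizon_years,
        )
        for name, point in res.point.to_dict().items():
            rows.append({"risk_group": gi, "output": name, "point": point,
                         "ci_lower": res.ci_lower[name], "ci_upper": res.ci_upper[name]})
    pd.DataFrame(rows).to_csv(out / "psa.csv", index=False)
    log.info("psa: %d iterations per group", config.psa_iterations)


def stage_price(config: RunConfig) -> None:
    out = _outdir(config)
    results = pd.read_csv(out / "results.csv")
    from scadmodel.markov import ModelOutputs

    grids = []
    for gi, sub in results.groupby("risk_group"):
        base = ModelOutputs.from_dict(sub[sub["rho"] == 0.0].iloc[0].to_dict())
        treated = {
            float(r["rho"]): ModelOutputs.from_dict(r.to_dict())
            for _, r in sub[sub["rho"] > 0.0].iterrows()
        }
        grids.append(pricing_grid(base, treated, config.threshold_list, group_index=int(gi)))
    pd.concat(grids, ignore_index=True).to_csv(out / "pricing.csv", index=False)
    log.info("price: wrote pricing grid")


_STAGE_FNS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "stratify": stage_stratify,
    "run": stage_run,
    "psa": stage_psa,
    "price": stage_price,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write a manifest; returns the run directory."""
    config.validate()
    out = _outdir(config)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("scadmodel")
    root.addHandler(handler)
    try:
        config.to_yaml(out / "config.yaml")
        for stage in STAGES:
            log.info("stage %s starting", stage)
            try:
                _STAGE_FNS[stage](config)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest = {
            "seed": config.seed,
            "stage_seeds": _stage_seeds(config.seed),
            "artefacts": {
                p.name: _sha256(p)
                for p in sorted(out.iterdir())
                if p.suffix in (".csv", ".json", ".yaml") and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
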