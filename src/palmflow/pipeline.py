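"""End-to-end orchestration: diversity -> SGS -> effective size -> gene flow.

``run_pipeline`` sequences the whole analysis on one dataset and returns a
JSON-serialisable report with per-stage diversity tables, SGS correlograms
and Sp summaries, group-coancestry effective sizes, parentage/gene-flow and
dispersal summaries, the neighborhood-model fit, and full provenance (input
hash, seeds, parameters, package version).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

import palmflow
from palmflow.diversity import diversity_summary
from palmflow.effective_size import group_coancestry
from palmflow.genotype_io import GenotypeDataset, read_genotypes
from palmflow.neighborhood import fit_neighborhood_model
from palmflow.parentage import (
    ParentageModel,
    assign_parentage,
    assignments_to_dataframe,
    dispersal_summaries,
    exclusion_probability_pairs,
)
from palmflow.genotype_io import allele_frequencies
from palmflow.sgs import analyze_stage_sgs, loiselle_coancestry
from palmflow.synthetic import SimulationConfig, simulate_population

# permutation profiles: field-standard defaults and a fast profile for smoke runs
PROFILES = {
    "default": {"f_perm": 1000, "sgs_perm": 10000, "delta_sim": 10000},
    "fast": {"f_perm": 100, "sgs_perm": 1000, "delta_sim": 1000},
}


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_json_ready(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: dict) -> dict:
    """Run the full analysis from a config dict; returns the report.

    Config keys: ``input`` (path to genotype CSV) or ``synthetic`` (dict of
    SimulationConfig overrides), ``seed``, ``profile`` (default|fast),
    ``candidate_stage``, ``error_rate``, ``skip`` (list of section names),
    ``exclude_ids``, ``out`` (optional path for the JSON report).
    """
    t0 = time.time()
    seed = int(config.get("seed", 20140000))
    profile = PROFILES[config.get("profile", "default")]
    skip = set(config.get("skip", []))
    candidate_stage = config.get("candidate_stage", "reproductive")
    error_rate = float(config.get("error_rate", 0.01))

    if "input" in config:
        data = read_genotypes(config["input"], dialect=config.get("dialect", "csv"),
                              coords_path=config.get("coords"))
        input_id = _file_hash(config["input"])
    else:
        sim_over = dict(config.get("synthetic", {}))
        sim_over.setdefault("seed", seed)
        sim_cfg = SimulationConfig(**sim_over)
        data, truth = simulate_population(sim_cfg)
        input_id = f"synthetic(seed={sim_cfg.seed})"
    if config.get("exclude_ids"):
        data = data.drop_ids(config["exclude_ids"])

    report: dict = {
        "provenance": {
            "package": "palmflow",
            "version": palmflow.__version__,
            "input": input_id,
            "seed": seed,
            "profile": config.get("profile", "default"),
            "parameters": {
                "candidate_stage": candidate_stage,
                "error_rate": error_rate,
                **profile,
            },
        },
        "errors": {},
    }
    stages = sorted(set(data.stages))

    if "diversity" not in skip:
        try:
            div = diversity_summary(
                data, n_perm=profile["f_perm"], seed=seed
            )
            report["diversity"] = div.table.to_dict(orient="records")
        except Exception as exc:  # pragma: no cover - defensive
            report["errors"]["diversity"] = str(exc)

    F_by_stage = {
        row["stage"]: row["F"] for row in report.get("diversity", [])
    }

    if "sgs" not in skip:
        report["sgs"] = {}
        for s in stages:
            try:
                corr, summ = analyze_stage_sgs(
                    data, s, n_perm=profile["sgs_perm"], seed=seed
                )
                report["sgs"][s] = {
                    "theta1": summ.theta1,
                    "first_class_bound_m": summ.first_class_bound,
                    "bk": summ.bk,
                    "bk_p_value": summ.bk_p_value,
                    "sp": summ.sp,
                    "correlogram": corr.to_dataframe().to_dict(orient="records"),
                }
            except Exception as exc:
                report["errors"][f"sgs:{s}"] = str(exc)

    if "ne" not in skip:
        report["effective_size"] = {}
        for s in stages:
            try:
                cm = loiselle_coancestry(data, s)
                res = group_coancestry(cm, F=F_by_stage.get(s, 0.0))
                report["effective_size"][s] = {
                    "theta_group": res.theta_group,
                    "F_used": res.F_used,
                    "n": res.n,
                    "ne": res.ne,
                    "ratio": res.ratio,
                }
            except Exception as exc:
                report["errors"][f"ne:{s}"] = str(exc)

    assignments = None
    if "parentage" not in skip:
        try:
            freqs = allele_frequencies(data)
            model = ParentageModel(
                error_rate=error_rate,
                n_sim=profile["delta_sim"],
                candidate_stage=candidate_stage,
            )
            assignments, summary = assign_parentage(
                data, model, freqs=freqs, seed=seed
            )
            disp = dispersal_summaries(
                assignments, data, candidate_stage=candidate_stage
            )
            report["gene_flow"] = {
                "total": summary.total,
                "both_parents_within": summary.both_parents_within,
                "selfed": summary.selfed,
                "no_father": summary.no_father,
                "no_parent": summary.no_parent,
                "selfing_rate": summary.selfing_rate,
                "pollen_immigration": summary.pollen_immigration,
                "seed_immigration": summary.seed_immigration,
                "fraction_candidates_participating": (
                    summary.fraction_candidates_participating
                ),
            }
            report["dispersal"] = {
                "pollen_mean_m": disp.pollen_mean,
                "pollen_median_m": disp.pollen_median,
                "pollen_sd_m": disp.pollen_sd,
                "seed_mean_m": disp.seed_mean,
                "seed_median_m": disp.seed_median,
                "seed_sd_m": disp.seed_sd,
                "sigma_p2_m2": disp.sigma_p2,
                "aep_m2": disp.aep_m2,
                "aep_ha": disp.aep_ha,
                "radius_m": disp.radius_m,
                "rp2": disp.rp2,
                "rs2": disp.rs2,
                "ks_d": disp.ks_d,
                "ks_p": disp.ks_p,
            }
            report["exclusion_probability_pairs"] = exclusion_probability_pairs(
                freqs
            )
            report["assignments"] = assignments_to_dataframe(
                assignments
            ).to_dict(orient="records")
        except Exception as exc:
            report["errors"]["parentage"] = str(exc)

    if "nm" not in skip:
        try:
            mothers = None
            if assignments is not None:
                by_id = {a.offspring_id: a.mother_id for a in assignments}
                off_ids = [
                    i for i, s in zip(data.ids, data.stages)
                    if s != candidate_stage
                ]
                mothers = [by_id.get(i) for i in off_ids]
            fit = fit_neighborhood_model(
                data,
                mothers=mothers,
                candidate_stage=candidate_stage,
                error_rate=error_rate,
                starts=int(config.get("nm_starts", 8)),
                seed=seed,
            )
            report["neighborhood_model"] = {
                "s": fit.s,
                "mp": fit.mp,
                "a": fit.kernel.a,
                "b": fit.kernel.b,
                "delta_m": fit.delta,
                "seed_kernel_a": fit.seed_kernel.a if fit.seed_kernel else None,
                "seed_kernel_b": fit.seed_kernel.b if fit.seed_kernel else None,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "n_offspring": fit.n_offspring,
                "mother_mode": fit.mother_mode,
            }
        except Exception as exc:
            report["errors"]["nm"] = str(exc)

    report["provenance"]["runtime_s"] = time.time() - t0
    report = _json_ready(report)
    if config.get("out"):
        out = Path(config["out"])
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return f"sha256:{h.hexdigest()[:16]}"
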