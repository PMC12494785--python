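"""End-to-end pipeline: filter -> quantify -> stratify -> trajectories -> concordance.

Reads the six canonical input tables from ``config.input_dir``, runs every
stage, and writes the derived tables plus a manifest to
``config.output_dir``.  Re-running with an identical configuration
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (build_presence_matrix, eligible_for_comparison,
                          find_discrepancies, temporal_heterogeneity,
                          annotate_actionability)
from .config import PipelineConfig
from .exceptions import CtdnaBurdenError, DomainError
from .filters import filter_ctdna, filter_tissue_somatic
from .io import read_table, write_table
from .quant import quantify_samples
from .survival import assign_groups, cox_fit, find_optimal_cutpoint, km_median, logrank_z
from .trajectories import compute_delta_events, concordance_table

logger = logging.getLogger(__name__)

INPUT_TABLES = ("patients", "samples", "variants", "copy_states",
                "tissue_variants", "workups")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CtdnaBurdenError as err:
                raise type(err)(f"[stage {name}] {err}") from err
        return wrapped
    return deco


def load_inputs(input_dir: str | Path) -> dict[str, pd.DataFrame]:
    input_dir = Path(input_dir)
    return {name: read_table(input_dir / f"{name}.tsv", name) for name in INPUT_TABLES}


@_stage("filter")
def _filter(tables, cfg: PipelineConfig):
    plasma = filter_ctdna(
        tables["variants"], min_consensus_reads=cfg.min_consensus_reads,
        rescue_min_reads=cfg.rescue_min_reads,
        normal_override_vaf=cfg.normal_override_vaf,
        normal_override_max_normal_vaf=cfg.normal_override_max_normal_vaf)
    tissue = filter_tissue_somatic(tables["tissue_variants"], min_vaf=cfg.tissue_vaf)
    return plasma, tissue


@_stage("quantify")
def _quantify(tables, plasma, cfg: PipelineConfig):
    return quantify_samples(tables["samples"], plasma, tables["copy_states"],
                            amplified_cn_threshold=cfg.amplified_cn_threshold)


def baseline_burden(patients: pd.DataFrame, quantified: pd.DataFrame) -> pd.DataFrame:
    """Attach each patient's baseline mGE: the earliest assessable sample."""
    q = quantified[quantified["ctdna_status"].isin(["positive", "negative"])]
    q = q.sort_values("days_from_baseline")
    first = q.groupby("patient_id").first().reset_index()
    out = patients.merge(first[["patient_id", "mge_per_ml"]], on="patient_id", how="left")
    return out.rename(columns={"mge_per_ml": "baseline_mge"})


@_stage("stratify")
def _stratify(patients: pd.DataFrame, cfg: PipelineConfig):
    pall = patients[(patients["arm"] == "palliative") & patients["baseline_mge"].notna()]
    if "exclude_from_search" in pall.columns:
        search = pall[~pall["exclude_from_search"].astype(bool)]
    else:
        search = pall
    if cfg.cutoff is not None:
        cutpoint, cut_info = float(cfg.cutoff), {"cutpoint": float(cfg.cutoff),
                                                 "source": "fixed"}
    else:
        res = find_optimal_cutpoint(search["baseline_mge"], search["os_months"],
                                    search["death_event"], minprop=cfg.minprop)
        cutpoint = res.cutpoint
        cut_info = {"cutpoint": res.cutpoint, "statistic": res.statistic,
                    "minprop": res.minprop, "n_search": int(len(search)),
                    "candidate_grid": [float(c) for c in res.candidate_grid],
                    "source": "maxstat"}
    grouped = assign_groups(patients, cutpoint)
    grouped.loc[grouped["arm"] != "palliative", "group"] = "unassigned"
    return grouped, cutpoint, cut_info


def _km_and_cox(grouped: pd.DataFrame, cfg: PipelineConfig):
    pall = grouped[grouped["group"].isin(["ctDNA_high", "ctDNA_low"])].copy()
    km_rows = []
    for g, d in pall.groupby("group"):
        med = km_median(d["os_months"], d["death_event"])
        km_rows.append([g, len(d), int(d["death_event"].sum()),
                        med if med is not None else np.nan])
    km = pd.DataFrame(km_rows, columns=["group", "n", "events", "km_median_months"])
    try:
        z = logrank_z(pall["os_months"], pall["death_event"],
                      pall["group"] == "ctDNA_high")
    except DomainError:
        z = np.nan

    cox_rows = []
    pall["mge_per_1000"] = pall["baseline_mge"] / 1000.0
    pall["high"] = (pall["group"] == "ctDNA_high").astype(int)
    # ECOG levels 2 and 3 carry too few patients to separate; combined
    pall["ecog_comb"] = pall["ecog"].clip(upper=2)
    fits = [
        ("univariable_mge_per_1000", ["mge_per_1000"], "mge_per_1000"),
        ("univariable_group", ["high"], "high"),
        ("multivariable_group", ["high", "ecog_comb", "crp", "albumin"], "high"),
    ]
    for label, covs, exposure in fits:
        try:
            r = cox_fit(pall, "os_months", "death_event", covs, exposure=exposure)
            cox_rows.append([label, exposure, r.hr, r.ci_low, r.ci_high, r.p])
        except CtdnaBurdenError as err:
            logger.warning("Cox fit %s skipped: %s", label, err)
            cox_rows.append([label, exposure, np.nan, np.nan, np.nan, np.nan])
    cox = pd.DataFrame(cox_rows, columns=["model", "exposure", "hr", "ci_low",
                                          "ci_high", "p"])
    return km, float(z) if z == z else None, cox


@_stage("trajectories")
def _trajectories(quantified, workups, grouped, cfg: PipelineConfig, cutpoint: float):
    events = compute_delta_events(quantified, workups, grouped, cutoff=cutpoint,
                                  band=cfg.band,
                                  death_window_months=cfg.death_window_months)
    return events, concordance_table(events)


@_stage("concordance")
def _concordance(plasma, tissue, quantified, cfg: PipelineConfig):
    report = {"detect_floor": cfg.detect_floor,
              "eligibility_min_frac": cfg.min_frac_concordance,
              "patients": {}}
    matrix_rows = []
    pids = sorted(set(plasma["patient_id"]) | set(tissue["patient_id"]))
    for pid in pids:
        pm = build_presence_matrix(plasma, tissue, quantified, pid,
                                   detect_floor=cfg.detect_floor)
        eligible = eligible_for_comparison(pm, cfg.min_frac_concordance)
        entry = {"eligible": eligible,
                 "n_plasma_samples": len(pm.plasma_samples),
                 "n_tissue_samples": len(pm.tissue_samples)}
        if eligible:
            disc = find_discrepancies(pm)
            entry["discrepancies"] = [{"variant": k, "direction": d} for k, d in disc]
            th = temporal_heterogeneity(pm)
            entry["temporal_heterogeneity"] = th
        report["patients"][pid] = entry
        m = pm.matrix.reset_index(names="variant").melt(
            id_vars="variant", var_name="sample_id", value_name="call")
        m.insert(0, "patient_id", pid)
        matrix_rows.append(m)
    matrices = (pd.concat(matrix_rows, ignore_index=True) if matrix_rows
                else pd.DataFrame(columns=["patient_id", "variant", "sample_id", "call"]))
    actionable = annotate_actionability(pd.concat([plasma, tissue], ignore_index=True)
                                        if len(tissue) else plasma)
    report["actionable"] = actionable.to_dict(orient="records")
    return report, matrices


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns artifact paths."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = load_inputs(config.input_dir)

    plasma, tissue = _filter(tables, config)
    quantified = _quantify(tables, plasma, config)
    patients = baseline_burden(tables["patients"], quantified)
    grouped, cutpoint, cut_info = _stratify(patients, config)
    km, logrank_stat, cox = _km_and_cox(grouped, config)
    events, dyn_table = _trajectories(quantified, tables["workups"], grouped,
                                      config, cutpoint)
    report, matrices = _concordance(plasma, tissue, quantified, config)

    write_table(quantified, outdir / "quantified_samples.tsv")
    write_table(grouped[["patient_id", "arm", "baseline_mge", "group"]],
                outdir / "groups.tsv")
    write_table(km, outdir / "km_summary.tsv")
    write_table(cox, outdir / "cox_summary.tsv")
    write_table(events, outdir / "events.tsv")
    write_table(matrices, outdir / "presence_matrices.tsv")
    with open(outdir / "cutpoint.json", "w") as fh:
        json.dump(cut_info, fh, indent=2, sort_keys=True)
    with open(outdir / "concordance_dynamics.json", "w") as fh:
        json.dump({"logrank_z_groups": logrank_stat,
                   "table": dyn_table.to_dict(orient="records")},
                  fh, indent=2, sort_keys=True)
    with open(outdir / "concordance_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    cfg_dict = config.to_dict()
    cfg_dict.pop("output_dir")  # the bundle's content must not depend on where it lives
    manifest = {"version": __version__, "config": cfg_dict,
                "inputs": {n: f"{config.input_dir}/{n}.tsv" for n in INPUT_TABLES},
                "cutpoint": cutpoint}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"outdir": str(outdir), "cutpoint": cutpoint, "km": km, "cox": cox,
            "events": events, "report": report}
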