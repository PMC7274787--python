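"""Full-session analysis pipeline and machine-readable report.

Stages: kinematics -> speed filter -> spatial information and the 0.8
bits/spike classification (with a Poisson surrogate control) -> direction-
split place-field detection and shape statistics -> field locations and
reward-distance histograms -> HPC-LS pair matching and shuffle-corrected
cross-correlograms -> statistics table.  Exclusion counts are logged at
each filter and all tables are deterministically ordered, so a fixed seed
reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Session
from .coupling import (match_pairs, pair_ccgs, session_thirds,
                       summarize_pairs)
from .fields import analyze_unit_fields, detect_fields, speed_accel_regression
from .geometry import assign_field_locations, field_probability_by_distance
from .information import SessionContext, classify_units, surrogate_population
from .kinematics import kinematic_maps
from .stats import StatsError, TestResult, compare_groups, two_proportion_z

log = logging.getLogger("pfls")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ReportBundle:
    """All pipeline outputs: tables, summaries and the config snapshot."""

    config: AnalysisConfig
    seed: int
    unit_info: pd.DataFrame
    surrogate_info: pd.DataFrame
    fields_table: pd.DataFrame
    locations: pd.DataFrame
    distance_histograms: pd.DataFrame
    pairs: pd.DataFrame
    group_summary: pd.DataFrame
    thirds_summary: pd.DataFrame
    stats_table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "unit_info": self.unit_info,
            "surrogate_info": self.surrogate_info,
            "fields": self.fields_table,
            "locations": self.locations,
            "distance_histograms": self.distance_histograms,
            "pairs": self.pairs,
            "group_summary": self.group_summary,
            "thirds_summary": self.thirds_summary,
            "stats": self.stats_table,
        }
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump({"config": asdict(self.config), "seed": self.seed,
                       "summary": self.summary}, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return out


def _info_df(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit_id": r.unit_id, "region": r.region,
        "mean_rate": r.mean_rate, "bits_per_spike": r.bits_per_spike,
        "bits_per_second": r.bits_per_second, "mutual_info": r.mutual_info,
        "passes_cutoff": r.passes_cutoff,
        "excluded_reason": r.excluded_reason or "",
    } for r in results])


def _safe_test(rows: list, name: str, *args, **kwargs):
    try:
        r: TestResult = compare_groups(*args, **kwargs)
    except StatsError as exc:
        log.info("stat %s skipped: %s", name, exc)
        return None
    rows.append({"name": name, "test": r.test, "statistic": r.statistic,
                 "df": r.df if r.df is not None else np.nan, "p": r.p,
                 "n1": r.n1, "n2": r.n2 if r.n2 is not None else 0})
    return r


def run_full_analysis(session: Session, config: Optional[AnalysisConfig] = None,
                      seed: int = 0, out_dir=None,
                      n_surrogates: Optional[int] = None) -> ReportBundle:
    """Run every analysis stage on one session.

    ``n_surrogates`` defaults to one Poisson surrogate per LS unit, using
    the recorded LS mean rates, as in the surrogate control.  With
    ``out_dir`` the tables and a JSON report are written there.
    """
    config = config or AnalysisConfig()
    stage = "kinematics/occupancy"
    try:
        ctx = SessionContext(session, config)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "spatial information"
    try:
        info = classify_units(session, config, ctx)
        unit_info = _info_df(info)
        n_excluded = int((unit_info.excluded_reason != "").sum())
        log.info("information: %d units, %d excluded, %d pass cutoff",
                 len(info), n_excluded, int(unit_info.passes_cutoff.sum()))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "surrogate control"
    try:
        ls_rates = [r.mean_rate for r in info
                    if r.region == "LS" and r.mean_rate > 0]
        if not ls_rates:
            ls_rates = [r.mean_rate for r in info if r.mean_rate > 0] or [1.0]
        n_sur = n_surrogates if n_surrogates is not None else len(ls_rates)
        sur = surrogate_population(session, n_sur, ls_rates,
                                   np.random.SeedSequence(seed).spawn(1)[0],
                                   config, ctx)
        surrogate_info = _info_df(sur)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "place fields"
    try:
        passing = [r.unit_id for r in info if r.passes_cutoff]
        speed_map, accel_map = kinematic_maps(ctx.fp, ctx.field_occ)
        all_fields, field_rows = [], []
        both_fields = {}  # unit -> fields on the all-travel map, for coupling
        for uid in passing:
            region = session.unit(uid).region
            rm_all = ctx.unit_rate_map(session.unit(uid).spike_times, "field",
                                       uid)
            mean_rate = float(
                unit_info.loc[unit_info.unit_id == uid, "mean_rate"].iloc[0])
            both_fields[uid] = detect_fields(rm_all, session.maze, config,
                                             "both", mean_rate)
            try:
                r2 = speed_accel_regression(rm_all, speed_map, accel_map)
            except Exception:
                r2 = np.nan
            fields = analyze_unit_fields(session, uid, ctx)
            for f in fields:
                zone = session.maze.zone_label(f.center_u, f.arm_label,
                                               config.junction_halfwidth)
                lap = f.lap_center_distances
                field_rows.append({
                    "unit_id": uid, "region": region, "field_id": f.field_id,
                    "direction": f.direction, "bidirectional": f.bidirectional,
                    "center_u_cm": f.center_u, "center_x_cm": f.center_xy[0],
                    "center_y_cm": f.center_xy[1], "arm_label": f.arm_label,
                    "zone": zone, "length_cm": f.length,
                    "peak_rate_hz": f.peak_rate, "skew": f.skew,
                    "frai": f.frai, "n_traversals": f.n_traversals,
                    "mean_lap_center_distance_cm":
                        float(np.mean(lap)) if lap is not None else np.nan,
                    "speed_accel_r2": r2,
                    "distance_to_reward_cm":
                        float(session.maze.distance_to_reward(f.center_u)),
                })
            all_fields.extend(fields)
        fields_table = pd.DataFrame(field_rows)
        if len(fields_table):
            fields_table = fields_table.sort_values(
                ["unit_id", "field_id"]).reset_index(drop=True)
        log.info("fields: %d direction-split fields in %d place cells",
                 len(fields_table), len(passing))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "field locations"
    try:
        loc_rows, hist_rows = [], []
        for region in ("HPC", "LS"):
            reg_fields = [f for f in all_fields
                          if session.unit(f.unit_id).region == region]
            rows = assign_field_locations(reg_fields, session.maze,
                                          config.junction_halfwidth)
            for r in rows:
                r["region"] = region
            loc_rows.extend(rows)
            if reg_fields:
                h = field_probability_by_distance(reg_fields, session.maze,
                                                  bin_width=10.0,
                                                  track_bin=config.field_bin)
                for d, fr, tb in zip(h["distance_bin_cm"],
                                     h["field_fraction"], h["track_bins"]):
                    hist_rows.append({"region": region,
                                      "distance_bin_cm": float(d),
                                      "field_fraction": float(fr),
                                      "track_bins": float(tb)})
        locations = pd.DataFrame(loc_rows)
        distance_histograms = pd.DataFrame(hist_rows)
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "hpc-ls coupling"
    try:
        hpc_f = [f for u, fl in both_fields.items() for f in fl
                 if session.unit(u).region == "HPC"]
        ls_f = [f for u, fl in both_fields.items() for f in fl
                if session.unit(u).region == "LS"]
        pairs = match_pairs(hpc_f, ls_f, session.maze, config)
        ccg_seed = np.random.SeedSequence(seed).spawn(3)
        ccgs = pair_ccgs(session, pairs, ccg_seed[1], config)
        groups = summarize_pairs(pairs, ccgs)
        thirds = session_thirds(session, pairs, ccg_seed[2], config)
        pairs_df = pd.DataFrame([{
            "hpc_unit": p.hpc_unit, "ls_unit": p.ls_unit,
            "hpc_field_id": p.hpc_field_id, "ls_field_id": p.ls_field_id,
            "center_distance_cm": p.center_distance,
            "rate_difference_hz": p.rate_difference, "arm_group": p.arm_group,
            "mean_corrected": c.mean_corrected, "peak_lag_ms": c.peak_lag_ms,
        } for p, c in zip(pairs, ccgs)])
        group_summary = pd.DataFrame([{
            "arm_group": g, "n": d["n"], "mean_corrected": d["mean_corrected"],
            "se": d["se"], "mean_peak_lag_ms": d["mean_peak_lag_ms"],
        } for g, d in groups.items()])
        thirds_summary = pd.DataFrame([{
            "third": t["third"], "arm_group": g, "n": d["n"],
            "mean_corrected": d["mean_corrected"], "se": d["se"],
        } for t in thirds for g, d in t["groups"].items()])
        log.info("coupling: %d matched pairs", len(pairs))
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    stage = "statistics"
    try:
        rows = []
        scored = unit_info[unit_info.excluded_reason == ""]
        hpc = scored[scored.region == "HPC"]
        ls = scored[scored.region == "LS"]
        _safe_test(rows, "bits_per_spike_hpc_vs_ls",
                   hpc.bits_per_spike, ls.bits_per_spike, test="t")
        _safe_test(rows, "bits_per_second_hpc_vs_ls",
                   hpc.bits_per_second, ls.bits_per_second, test="t")
        sur_ok = surrogate_info[surrogate_info.excluded_reason == ""]
        if len(ls) and len(sur_ok):
            _safe_test(rows, "bits_per_spike_ls_vs_surrogate_ks",
                       ls.bits_per_spike, sur_ok.bits_per_spike, test="ks")
            _safe_test(rows, "bits_per_spike_ls_vs_surrogate_t",
                       ls.bits_per_spike, sur_ok.bits_per_spike, test="t")
        if len(hpc) and len(ls):
            _safe_test(rows, "place_cell_prevalence_hpc_vs_ls",
                       hpc.passes_cutoff.astype(float),
                       ls.passes_cutoff.astype(float), test="t")
            z = two_proportion_z(int(hpc.passes_cutoff.sum()), len(hpc),
                                 int(ls.passes_cutoff.sum()), len(ls))
            rows.append({"name": "place_cell_prevalence_two_prop_z",
                         "test": z.test, "statistic": z.statistic,
                         "df": np.nan, "p": z.p, "n1": z.n1, "n2": z.n2})
        ft = fields_table
        if len(ft):
            fh = ft[ft.region == "HPC"]
            fl = ft[ft.region == "LS"]
            _safe_test(rows, "field_length_hpc_vs_ls",
                       fh.length_cm, fl.length_cm, test="t")
            for region, sub in (("hpc", fh), ("ls", fl)):
                tw = sub.loc[sub.direction == "toward_reward", "skew"].dropna()
                aw = sub.loc[sub.direction == "away_from_reward", "skew"].dropna()
                _safe_test(rows, f"skew_toward_vs_away_{region}", tw, aw,
                           test="t")
            counts = []
            for sub in (fh, fl):
                counts.append([int((sub.zone == z).sum())
                               for z in ("forced_side", "stem", "choice_side")])
            tab = np.array(counts)
            if tab.size and (tab.sum(axis=1) > 0).all() and \
                    (tab.sum(axis=0) > 0).all():
                _safe_test(rows, "field_location_distribution_chi2", tab,
                           test="chi2")
        for g1, g2 in (("forced", "choice"), ("middle", "choice")):
            if g1 in groups and g2 in groups:
                _safe_test(rows, f"coupling_{g1}_vs_{g2}",
                           groups[g1]["values"], groups[g2]["values"],
                           test="t")
        stats_table = pd.DataFrame(
            rows, columns=["name", "test", "statistic", "df", "p", "n1", "n2"])
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    summary = {
        "n_units": int(len(unit_info)),
        "n_excluded": int((unit_info.excluded_reason != "").sum()),
        "n_pass_cutoff": int(unit_info.passes_cutoff.sum()),
        "frac_pass_hpc": float(hpc.passes_cutoff.mean()) if len(hpc) else np.nan,
        "frac_pass_ls": float(ls.passes_cutoff.mean()) if len(ls) else np.nan,
        "frac_surrogate_above_cutoff":
            float(sur_ok.passes_cutoff.mean()) if len(sur_ok) else np.nan,
        "n_fields": int(len(fields_table)),
        "mean_field_length_cm":
            float(fields_table.length_cm.mean()) if len(fields_table) else np.nan,
        "n_pairs": int(len(pairs_df)),
        "coverage": bool(ctx.coverage),
    }
    bundle = ReportBundle(config=config, seed=seed, unit_info=unit_info,
                          surrogate_info=surrogate_info,
                          fields_table=fields_table, locations=locations,
                          distance_histograms=distance_histograms,
                          pairs=pairs_df, group_summary=group_summary,
                          thirds_summary=thirds_summary,
                          stats_table=stats_table, summary=summary)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
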