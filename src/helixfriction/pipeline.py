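"""End-to-end analysis orchestration.

Runs the full stack per peptide x condition x trajectory (synthetic
generation, kinetics, dwell analysis, landscape, friction), averages the
paired e/h trajectories with half their difference as the error, and emits
result tables (kinetics, dwell/local friction, viscosity fits, global
friction, internal friction) plus a JSON manifest.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dwell import ensemble_dwell_time, extract_dwells, fit_exponential_mixture, log_histogram
from .friction import PhysicalConstants, global_friction, local_friction, round_sig
from .kinetics import autocorrelation, fit_relaxation, rates_from_relaxation
from .landscape import build_surface, histogram_centers
from .synthgen import GeometrySpec, KineticsSpec, hb_to_end_to_end, simulate_hb_states
from .viscosity import fit_friction_vs_viscosity

__all__ = ["AveragedResult", "average_eh", "run_pipeline", "PipelineResult"]

PS_PER_US = 1.0e6


@dataclass
class AveragedResult:
    """Mean of the paired e/h values with error = |e - h| / 2."""

    mean: float
    error: float
    n_values: int = 2


def average_eh(value_e: float, value_h: float, units_e: str | None = None,
               units_h: str | None = None) -> AveragedResult:
    """Average the extended- and helix-start values of one quantity.

    The error is half the absolute difference; argument order is
    irrelevant.  Units, when given, must match.
    """
    if units_e is not None and units_h is not None and units_e != units_h:
        raise ValueError(f"unit mismatch: {units_e!r} vs {units_h!r}")
    return AveragedResult(
        mean=0.5 * (value_e + value_h),
        error=0.5 * abs(value_e - value_h),
    )


@dataclass
class PipelineResult:
    tables: dict  # name -> DataFrame
    manifest: dict


def _cell_seed(base_seed: int, peptide: str, condition: str, tag: str) -> int:
    """Stable per-cell seed keyed by labels (not config order), so removing
    one peptide never perturbs another's stream."""
    crc = zlib.crc32(f"{peptide}/{condition}/{tag}".encode())
    return int(np.random.SeedSequence([int(base_seed), crc]).generate_state(1)[0])


def _analyze_trajectory(pep: dict, cond: dict, tag: str, settings: dict) -> dict:
    """All stage outputs for one synthetic trajectory."""
    dt = float(cond.get("dt_ps", settings["dt_ps"]))
    seed = _cell_seed(settings["seed"], pep["label"], cond["label"], tag)
    spec = KineticsSpec(
        n_bonds=int(pep.get("n_bonds", 1)),
        k_form=float(cond["k_form_per_us"]),
        k_break=float(cond["k_break_per_us"]),
        cooperativity=float(cond.get("cooperativity", 1.0)),
        dt=dt,
        n_frames=int(cond.get("n_frames", 100_000)),
        seed=seed,
    )
    states = simulate_hb_states(spec)
    h = states.h_series

    # kinetics
    f = float(h.mean() / states.h_max)
    max_lag = int(cond.get("max_lag", min(spec.n_frames // 4, 200_000)))
    acf = autocorrelation(h, max_lag)
    relax = fit_relaxation(acf, dt)
    tau_f_us = relax.tau / PS_PER_US
    rates = rates_from_relaxation(tau_f_us, f)

    # dwell analysis -> local friction
    dwells = extract_dwells(states, mode=settings["dwell_mode"])
    hist = log_histogram(dwells, bins_per_decade=settings["bins_per_decade"])
    mix = fit_exponential_mixture(hist, n_components=settings["dwell_components"])
    tau_ps = ensemble_dwell_time(mix, rule=settings["dwell_rule"])
    consts = PhysicalConstants(T=settings["temperature"], delta=settings["delta_nm"])
    g_local = local_friction(tau_ps, consts)

    # landscape -> global friction
    geo_cfg = dict(cond.get("geometry", {}))
    geo_cfg.setdefault("rise_per_residue", settings["delta_nm"])
    geom = GeometrySpec(seed=seed + 1, **geo_cfg)
    e2e = hb_to_end_to_end(states, geom)
    surface = build_surface(
        h, e2e,
        bin_width=settings["bin_width_nm"],
        temperature=settings["temperature"],
        h_max=states.h_max,
    )
    dxr = histogram_centers(surface, min_count=settings["level_floor"])
    g_global = global_friction(rates.k_fold, dxr.delta_x_sq_total, consts)

    return {
        "seed": seed,
        "f": f,
        "tau_f_us": tau_f_us,
        "k_fold_per_us": rates.k_fold,
        "k_unfold_per_us": rates.k_unfold,
        "K": rates.K,
        "dwell_tau_ps": tau_ps,
        "dwell_censored": dwells.censored_count,
        "dwell_fallback": mix.fallback,
        "local_friction_ng_s": g_local.ng_per_s,
        "delta_x_nm": dxr.delta_x_reported,
        "delta_x_sq_nm2": dxr.delta_x_sq_total,
        "global_friction_ug_s": g_global.ug_per_s,
    }


def _combine(cell_results: dict, key: str):
    """e/h average for one scalar, or the single value flagged as such."""
    tags = sorted(cell_results)
    if len(tags) >= 2:
        avg = average_eh(cell_results[tags[0]][key], cell_results[tags[1]][key])
        return avg.mean, avg.error, False
    only = cell_results[tags[0]][key]
    return only, np.nan, True


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir=None) -> PipelineResult:
    """Run the full analysis described by a declarative config.

    The config carries global defaults (seed, temperature, dt, delta, HB
    cutoff) and a list of peptides, each with conditions (rates,
    cooperativity, frame count, relative viscosity, trajectory tags).
    A stage failure aborts only that peptide x condition cell and is
    recorded in the manifest diagnostics.
    """
    cfg = load_config(config)
    settings = {
        "seed": int(cfg.get("seed", 0)),
        "temperature": float(cfg.get("temperature", 300.0)),
        "dt_ps": float(cfg.get("dt_ps", 2.0)),
        "delta_nm": float(cfg.get("delta_nm", 0.15)),
        "hb_cutoff_nm": float(cfg.get("hb_cutoff_nm", 0.36)),
        "dwell_mode": cfg.get("dwell_mode", "per_bond_formed"),
        "dwell_components": int(cfg.get("dwell_components", 2)),
        "dwell_rule": cfg.get("dwell_rule", "amplitude_weighted"),
        "bins_per_decade": int(cfg.get("bins_per_decade", 10)),
        "bin_width_nm": float(cfg.get("bin_width_nm", 0.05)),
        "level_floor": int(cfg.get("level_floor", 50)),
    }
    rows_kin, rows_dwell, rows_global = [], [], []
    rows_visc, rows_internal = [], []
    diagnostics = []
    cell_records = {}

    for pep in cfg.get("peptides", []):
        local_points, global_points = [], []
        for cond in pep.get("conditions", []):
            tags = cond.get("trajectories", ["e", "h"])
            cell = {}
            for tag in tags:
                try:
                    cell[tag] = _analyze_trajectory(pep, cond, tag, settings)
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    diagnostics.append(
                        {
                            "peptide": pep["label"],
                            "condition": cond["label"],
                            "trajectory": tag,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
            if not cell:
                continue
            cell_records[(pep["label"], cond["label"])] = cell
            ku, ku_err, single = _combine(cell, "k_unfold_per_us")
            kf, kf_err, _ = _combine(cell, "k_fold_per_us")
            K, K_err, _ = _combine(cell, "K")
            rows_kin.append(
                {
                    "peptide": pep["label"],
                    "condition": cond["label"],
                    "k_unfold_per_us": round_sig(ku),
                    "k_unfold_err": round_sig(ku_err),
                    "k_fold_per_us": round_sig(kf),
                    "k_fold_err": round_sig(kf_err),
                    "K": round_sig(K),
                    "K_err": round_sig(K_err),
                    "single_trajectory": single,
                }
            )
            tau, tau_err, _ = _combine(cell, "dwell_tau_ps")
            gl, gl_err, _ = _combine(cell, "local_friction_ng_s")
            rows_dwell.append(
                {
                    "peptide": pep["label"],
                    "condition": cond["label"],
                    "dwell_time_ps": round_sig(tau),
                    "dwell_time_err": round_sig(tau_err),
                    "local_friction_ng_s": round_sig(gl),
                    "local_friction_err": round_sig(gl_err),
                    "single_trajectory": single,
                }
            )
            gg, gg_err, _ = _combine(cell, "global_friction_ug_s")
            dx, dx_err, _ = _combine(cell, "delta_x_nm")
            rows_global.append(
                {
                    "peptide": pep["label"],
                    "condition": cond["label"],
                    "global_friction_ug_s": round_sig(gg),
                    "global_friction_err": round_sig(gg_err),
                    "delta_x_A": round_sig(dx * 10.0),
                    "delta_x_err_A": round_sig(dx_err * 10.0),
                    "single_trajectory": single,
                }
            )
            if "rel_viscosity" in cond:
                local_points.append((float(cond["rel_viscosity"]), gl))
                global_points.append((float(cond["rel_viscosity"]), gg))
        if len(local_points) >= 2:
            lin = fit_friction_vs_viscosity(local_points, model="linear")
            row = {
                "peptide": pep["label"],
                "a_ng_s": round_sig(lin.a),
                "gamma0_ng_s": round_sig(lin.gamma0),
                "gamma_w_ng_s": np.nan,
                "beta": np.nan,
            }
            try:
                pw = fit_friction_vs_viscosity(local_points, model="power")
                row["gamma_w_ng_s"] = round_sig(pw.gamma_w)
                row["beta"] = round_sig(pw.beta)
            except ValueError:
                pass
            rows_visc.append(row)
        if len(global_points) >= 2:
            ling = fit_friction_vs_viscosity(global_points, model="linear")
            rows_internal.append(
                {
                    "peptide": pep["label"],
                    "global_internal_friction_ug_s": round_sig(ling.gamma0),
                }
            )

    tables = {
        "kinetics": pd.DataFrame(rows_kin),
        "dwell_local_friction": pd.DataFrame(rows_dwell),
        "viscosity_fits": pd.DataFrame(rows_visc),
        "global_friction": pd.DataFrame(rows_global),
        "internal_friction": pd.DataFrame(rows_internal),
    }
    manifest = {
        "software_version": __version__,
        "settings": settings,
        "cells": {
            f"{p}/{c}": {tag: {"seed": r["seed"]} for tag, r in cell.items()}
            for (p, c), cell in cell_records.items()
        },
        "diagnostics": diagnostics,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"table_{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(tables=tables, manifest=manifest)
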