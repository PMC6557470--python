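"""End-to-end analysis pipeline: rates -> MIDs -> fit -> report.

Consumes a study bundle (from the synthetic generator or CSV tables in the
same dialect), computes extracellular rates with Monte-Carlo SDs, corrects and
pools MIDs with the minimum-error floor, fits fluxes per scenario, and emits a
JSON-serializable report with per-condition flux tables, fit diagnostics,
glycolytic efficiencies, percent-labeling tables, the M5-citrate
reductive-carboxylation diagnostic, and cross-condition comparisons of the key
pathway fluxes (oxidative PPP, PDH, CS, PC, GDH, malic enzyme, IDH exchange).

The report is a pure function of (inputs, options, seed): two runs with the
same seed produce byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exflux as xf
from .estimation import (
    FitResult,
    MeasurementSet,
    confidence_intervals,
    estimate_fluxes,
)
from .mid import (
    DEFAULT_ERROR_FLOOR,
    MIDVector,
    apply_error_floor,
    correct_natural_abundance,
    percent_labeling,
    pool_replicates,
)
from .network import NetworkModel, default_breast_network
from .synth import TRACER_PANELS, load_default_fragments

__all__ = [
    "PipelineOptions",
    "compute_extracellular_fluxes",
    "build_measurement_set",
    "run_pipeline",
    "compare_conditions",
    "KEY_FLUXES",
]

# the cross-condition comparison panel: oxidative PPP, PDH, CS, PC, GDH/AT,
# malic enzyme, and the reductive-carboxylation (IDH) exchange
KEY_FLUXES: tuple[tuple[str, str], ...] = (
    ("net", "v11"),
    ("net", "v15"),
    ("net", "v16"),
    ("net", "v22"),
    ("net", "v26"),
    ("net", "v23"),
    ("exchange", "v17"),
)

KEY_FLUX_LABELS = {
    ("net", "v11"): "PPP",
    ("net", "v15"): "PDH",
    ("net", "v16"): "CS",
    ("net", "v22"): "PC",
    ("net", "v26"): "GDH/AT",
    ("net", "v23"): "ME",
    ("exchange", "v17"): "IDH exchange",
}


@dataclass
class PipelineOptions:
    seed: int = 0
    n_restarts: int = 20
    mc_iters: int = 1_000_000
    alpha: float = 0.05
    error_floor_molpct: float = DEFAULT_ERROR_FLOOR
    gln_kdeg: float = xf.GLN_DEGRADATION_RATE
    compute_ci: bool = True
    ci_quantities: tuple[tuple[str, str], ...] = KEY_FLUXES
    lactate_mids_in_fit: bool = False


def _pooled_cv(df: pd.DataFrame, group_cols: list[str], value_col: str, min_mean: float = 0.5) -> float:
    """Study-wide coefficient of variation pooled over replicate groups.

    Measurement noise on concentrations and counts is proportional, so one CV
    estimated over every (metabolite, time) replicate group carries far more
    degrees of freedom than any single group's SD; groups with tiny means are
    excluded (their error is dominated by an absolute detection floor).
    """
    ratios = []
    for _, grp in df.groupby(group_cols, sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        m = vals.mean()
        if len(vals) > 1 and m > min_mean:
            ratios.append((vals.std(ddof=1) / m) ** 2)
    return float(np.sqrt(np.mean(ratios))) if ratios else 0.0


def compute_extracellular_fluxes(
    cells: pd.DataFrame,
    conc: pd.DataFrame,
    mc_iters: int = 1_000_000,
    seed: int = 0,
    gln_kdeg: float = xf.GLN_DEGRADATION_RATE,
    conc_sd_floor_mM: float = 0.02,
) -> tuple[dict[str, tuple[float, float]], dict]:
    """Specific rates with Monte-Carlo SDs from count and concentration tables.

    Growth rate from log-linear regression over all replicates; each
    metabolite's rate from the 24/48 h concentration means, with glutamine
    corrected for spontaneous degradation.  Concentration and count errors use
    a study-wide pooled CV (proportional-noise model) with an absolute floor
    for near-zero concentrations, which keeps the error estimates stable at
    triplicate sample sizes.  Returns ``(rates, growth_info)``.
    """
    growth = xf.fit_growth_rate(cells["time_h"].to_numpy(), cells["density"].to_numpy())
    at24 = cells[cells.time_h == 24.0]["density"]
    x24 = float(at24.mean())
    cv_cells = _pooled_cv(cells, ["time_h"], "density", min_mean=0.0)
    x24_sd = cv_cells * x24 / np.sqrt(len(at24))
    cv_conc = _pooled_cv(conc, ["metabolite", "time_h"], "conc_mM")
    rng = np.random.default_rng(seed)
    rates = {}
    for met, grp in conc.groupby("metabolite", sort=True):
        c24 = grp[grp.time_h == 24.0]["conc_mM"]
        c48 = grp[grp.time_h == 48.0]["conc_mM"]
        m24, m48 = float(c24.mean()), float(c48.mean())
        se24 = max(cv_conc * abs(m24), conc_sd_floor_mM) / np.sqrt(len(c24))
        se48 = max(cv_conc * abs(m48), conc_sd_floor_mM) / np.sqrt(len(c48))
        dc_sd = float(np.hypot(se24, se48))
        if met == "GLN":
            val = xf.correct_glutamine_flux(growth.mu, m24, m48, x24, k_deg=gln_kdeg)
        else:
            val = xf.compute_flux(growth.mu, m24, m48, x24)
        sd = xf.monte_carlo_flux_sd(
            growth.mu, growth.mu_sd, m48 - m24, dc_sd, x24, x24_sd,
            n_iter=mc_iters, seed=rng,
        )
        rates[met] = (val, max(sd, 1e-9))
    info = {
        "mu": growth.mu, "mu_sd": growth.mu_sd, "x24": x24, "x24_sd": x24_sd,
        "cv_conc": cv_conc, "cv_cells": cv_cells,
    }
    return rates, info


def build_measurement_set(
    data: dict,
    options: PipelineOptions,
    fragments=None,
    raw_scale: bool | None = None,
) -> tuple[MeasurementSet, dict]:
    """MeasurementSet for one scenario bundle entry (cells/concentrations/mids).

    ``raw_scale`` states whether the MID tables are raw ion distributions that
    need natural-abundance correction; when None it is taken from the bundled
    scenario config (falling back to True).  Replicates are corrected (if
    needed) and pooled; the measurement error per mass is the fragment-pooled
    standard error — rms replicate SD over the fragment's masses divided by
    sqrt(n), reflecting homoscedastic ion-counting noise within one fragment —
    floored at the minimum error (0.6 mol% by default).
    """
    fragments = fragments or load_default_fragments()
    if raw_scale is None:
        cfg = data.get("config")
        raw_scale = cfg.convolve_natural_abundance if cfg is not None else True
    rates, info = compute_extracellular_fluxes(
        data["cells"], data["concentrations"],
        mc_iters=options.mc_iters, seed=options.seed, gln_kdeg=options.gln_kdeg,
    )
    mids: dict[str, dict[str, MIDVector]] = {}
    tracers: dict[str, dict] = {}
    for tracer, df in data["mids"].items():
        tracers[tracer] = TRACER_PANELS[tracer]["specs"]
        pooled_by_fid = {}
        for fid, grp in df.groupby("fragment_id", sort=True):
            mcols = [c for c in grp.columns if c.startswith("m") and c[1:].isdigit()]
            mcols = sorted(mcols, key=lambda c: int(c[1:]))
            reps = []
            for _, row in grp.iterrows():
                vals = row[mcols].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                if raw_scale:
                    raw = MIDVector(fragment_id=fid, values=vals, state="raw", tracer=tracer)
                    reps.append(correct_natural_abundance(raw, fragments[fid]))
                else:
                    n_back = fragments[fid].n_carbons
                    reps.append(
                        MIDVector(fragment_id=fid, values=vals[: n_back + 1],
                                  state="corrected", tracer=tracer)
                    )
            pooled_by_fid[fid] = pool_replicates(reps)
        # experiment-wide pooled replicate SD: MID noise is homoscedastic
        # across masses and fragments of one labeling experiment, so pooling
        # stabilizes the error estimate at triplicate sample sizes
        all_vars = np.concatenate(
            [np.square(p.sds) for p in pooled_by_fid.values() if p.n_replicates > 1]
        ) if any(p.n_replicates > 1 for p in pooled_by_fid.values()) else np.array([np.nan])
        exp_sd = float(np.sqrt(np.nanmean(all_vars)))
        frag_mids = {}
        for fid, pooled in pooled_by_fid.items():
            se = np.full_like(
                pooled.values, exp_sd / np.sqrt(max(pooled.n_replicates, 1))
            )
            floored = apply_error_floor(se, floor=options.error_floor_molpct)
            frag_mids[fid] = MIDVector(
                fragment_id=fid, values=pooled.values, sds=floored,
                state="corrected", tracer=tracer, n_replicates=pooled.n_replicates,
            )
        mids[tracer] = frag_mids
    mset = MeasurementSet(
        exflux=rates, mids=mids, tracers=tracers, fragments=fragments, mu=info["mu"]
    )
    return mset, info


def run_pipeline(
    bundle: dict,
    options: PipelineOptions | None = None,
    model: NetworkModel | None = None,
    fragments=None,
) -> dict:
    """Run the full analysis over a study bundle and build the report."""
    options = options or PipelineOptions()
    model = model or default_breast_network()
    fragments = fragments or load_default_fragments()
    report = {
        "settings": {
            "seed": options.seed,
            "n_restarts": options.n_restarts,
            "mc_iters": options.mc_iters,
            "alpha": options.alpha,
            "error_floor_molpct": options.error_floor_molpct,
            "gln_kdeg": options.gln_kdeg,
            "lactate_mids_in_fit": options.lactate_mids_in_fit,
        },
        "scenarios": {},
        "comparisons": {},
    }
    fits: dict[str, FitResult] = {}
    for name in sorted(bundle["scenarios"]):
        data = bundle["scenarios"][name]
        mset, info = build_measurement_set(data, options, fragments)
        fit = estimate_fluxes(
            model, mset,
            n_restarts=options.n_restarts,
            seed=options.seed,
            lactate_mids_in_fit=options.lactate_mids_in_fit,
            alpha=options.alpha,
        )
        ci = {}
        if options.compute_ci:
            ci = confidence_intervals(fit, list(options.ci_quantities), alpha=options.alpha)
        fits[name] = fit
        glc, lac = mset.exflux.get("GLC"), mset.exflux.get("LAC")
        efficiency = (
            xf.glycolytic_efficiency(max(lac[0], 0.0), glc[0])
            if glc and lac and glc[0] < 0
            else None
        )
        labeling = {
            tracer: {fid: round(percent_labeling(m), 3) for fid, m in sorted(frags.items())}
            for tracer, frags in mset.mids.items()
        }
        m5 = None
        if "gln" in mset.mids and "CIT_123456" in mset.mids["gln"]:
            m5 = float(mset.mids["gln"]["CIT_123456"].values[5])
        report["scenarios"][name] = {
            "growth": info,
            "exflux": {m: [v, s] for m, (v, s) in sorted(mset.exflux.items())},
            "fit": {
                "net": {k: round(v, 6) for k, v in sorted(fit.fluxes.net.items())},
                "exchange": {k: round(v, 6) for k, v in sorted(fit.fluxes.exchange.items())},
                "ssres": fit.ssres,
                "dof": fit.dof,
                "chi2_bounds": list(fit.chi2_bounds),
                "verdict": fit.verdict,
                "n_restarts_used": fit.n_restarts_used,
                "ci": {f"{k}:{r}": list(v) for (k, r), v in sorted(ci.items())},
            },
            "glycolytic_efficiency": None if efficiency is None else round(efficiency, 1),
            "percent_labeling": labeling,
            "m5_citrate": m5,
            "provenance": {
                "stages": ["exflux", "mid_processing", "flux_estimation"],
                "scenario": name,
                "seed": options.seed,
            },
        }
    # pair control/high_lactate fits per cell line
    by_line: dict[str, dict[str, str]] = {}
    for name in fits:
        data = bundle["scenarios"][name]
        cfg = data.get("config")
        line = cfg.cell_line if cfg is not None else name.rsplit("_", 1)[0]
        cond = cfg.condition if cfg is not None else name.rsplit("_", 1)[1]
        by_line.setdefault(line, {})[cond] = name
    for line, conds in sorted(by_line.items()):
        if {"control", "high_lactate"} <= set(conds):
            report["comparisons"][line] = compare_conditions(
                fits[conds["control"]], fits[conds["high_lactate"]],
                alpha=options.alpha,
            )
    return report


def compare_conditions(
    fit_a: FitResult,
    fit_b: FitResult,
    quantities: tuple[tuple[str, str], ...] = KEY_FLUXES,
    alpha: float = 0.05,
) -> dict:
    """Per-flux differences between two fitted conditions with significance flags.

    The difference is flagged when the two profile-likelihood confidence
    intervals do not overlap — a conservative proxy for a p <= alpha test.
    Symmetric: compare(a, b) flags = compare(b, a) flags.
    """
    if set(fit_a.fluxes.net) != set(fit_b.fluxes.net):
        raise ValueError("fits come from different networks")
    out = {}
    for q in quantities:
        kind, rid = q
        va = fit_a.fluxes.net[rid] if kind == "net" else fit_a.fluxes.exchange.get(rid, 0.0)
        vb = fit_b.fluxes.net[rid] if kind == "net" else fit_b.fluxes.exchange.get(rid, 0.0)
        ci_a = fit_a.ci.get(q)
        ci_b = fit_b.ci.get(q)
        significant = None
        if ci_a is not None and ci_b is not None:
            significant = bool(ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0])
        label = KEY_FLUX_LABELS.get(q, f"{kind}:{rid}")
        a_r, b_r = round(va, 6), round(vb, 6)
        out[label] = {
            "quantity": f"{kind}:{rid}",
            "a": a_r,
            "b": b_r,
            "difference": round(b_r - a_r, 6),
            "ci_a": None if ci_a is None else list(ci_a),
            "ci_b": None if ci_b is None else list(ci_b),
            "significant": significant,
        }
    return out


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True, default=float)
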