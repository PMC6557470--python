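"""Variance-weighted flux estimation against parallel-labeling data.

Net fluxes are parameterized by an orthonormal basis of the affine space
defined by steady state (S v = 0 over balanced metabolites), zero net flux for
dilution-exchange reactions, and fixed biomass drain fluxes derived from the
growth rate.  Exchange fluxes of selected reversible reactions are fitted on a
bounded [0, 1) scale u with e = s*u/(1-u) for conditioning.  The objective is
the variance-weighted sum of squared residuals (SSRes) over (i) measured
extracellular rates and (ii) corrected MIDs from every parallel tracer
experiment, each simulated with its own tracer specification but a single
shared flux vector.  Irreversibility is enforced through hinge penalty
residuals, which are inactive at any feasible optimum and asserted small
after the fit.

Goodness of fit compares SSRes to a two-sided chi-square interval; confidence
intervals profile the objective, re-optimizing all remaining parameters, until
SSRes crosses SSRes_min + chi2(1 - alpha, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize, stats

from .emu import TracerSpec, decompose_emus, simulate_mids
from .mid import FragmentSpec, MIDVector
from .network import NetworkModel, stoichiometric_matrix

__all__ = [
    "FluxVector",
    "MeasurementSet",
    "FitResult",
    "biomass_flux_from_growth",
    "estimate_fluxes",
    "goodness_of_fit",
    "confidence_intervals",
    "profile_covers",
    "sensitivity_rerun",
    "max_secretion_yield",
    "DEFAULT_EXFLUX_MAP",
    "DEFAULT_FIT_EXCHANGES",
]

DEFAULT_DRY_MASS_PG = 470.0  # pg dry weight per cell (hybridoma literature value)

# measured extracellular metabolite -> (reaction carrying it, sign such that
# measured rate = sign * net flux); for the default breast network
DEFAULT_EXFLUX_MAP: dict[str, tuple[str, int]] = {
    "GLC": ("v1", -1),
    "LAC": ("v10", +1),
    "GLN": ("v24", -1),
    "GLU": ("v27", +1),
    "ALA": ("v30", +1),
    "ASP": ("v31", +1),
    "EAA": ("v35", -1),
}

# reversible reactions whose exchange flux is a fitted parameter by default:
# LDH, IDH, GDH, and the lactate dilution exchange
DEFAULT_FIT_EXCHANGES = ("v9", "v17", "v26", "v38")

EXCHANGE_SCALE = 50.0
_HINGE_WEIGHT = 10.0


@dataclass(frozen=True)
class FluxVector:
    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def as_arrays(self, model: NetworkModel) -> np.ndarray:
        return np.array([self.net.get(r.id, 0.0) for r in model.reactions])


@dataclass
class MeasurementSet:
    """Everything the fit consumes for one cell line x condition."""

    exflux: dict[str, tuple[float, float]]  # metabolite -> (rate, sd)
    mids: dict[str, dict[str, MIDVector]]  # tracer experiment -> fragment -> corrected MID
    tracers: dict[str, dict[str, list[TracerSpec]]]  # experiment -> substrate -> specs
    fragments: dict[str, FragmentSpec]
    mu: float
    dry_mass: float = DEFAULT_DRY_MASS_PG
    exflux_map: dict[str, tuple[str, int]] = field(default_factory=lambda: dict(DEFAULT_EXFLUX_MAP))

    def validate(self, model: NetworkModel) -> None:
        for met, (rid, _sign) in ((m, self.exflux_map[m]) for m in self.exflux):
            model.reaction(rid)
        for exp, frags in self.mids.items():
            if exp not in self.tracers:
                raise ValueError(f"tracer experiment {exp!r} has MIDs but no tracer spec")
            for fid, mid in frags.items():
                spec = self.fragments[fid]
                if spec.metabolite not in model.metabolites:
                    raise ValueError(f"fragment {fid}: metabolite {spec.metabolite} not in model")
                if mid.sds is None or np.any(np.asarray(mid.sds) <= 0):
                    raise ValueError(f"fragment {fid} in {exp}: SDs must be positive")


@dataclass
class FitResult:
    fluxes: FluxVector
    ssres: float
    n_measurements: int
    n_parameters: int
    dof: int
    chi2_bounds: tuple[float, float]
    verdict: str  # accept | overfit | underfit
    ci: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    n_restarts_used: int = 0
    seed: int | None = None
    converged: bool = True
    # internal state enabling profiling without refitting from scratch
    _problem: "_Problem | None" = field(default=None, repr=False)
    _x: np.ndarray | None = field(default=None, repr=False)


def biomass_flux_from_growth(
    mu: float, model: NetworkModel, dry_mass: float = DEFAULT_DRY_MASS_PG
) -> dict[str, float]:
    """Biomass drain fluxes implied by the growth rate.

    Each sink drain carries ``mu * dry_mass`` (ug dry weight per 1e6 cells per
    h, numerically equal to pg/cell/h); with drain coefficients in mmol per g
    dry weight, precursor consumption comes out in nmol/1e6 cells/h.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return {rid: mu * dry_mass for rid in model.sink_reactions}


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------


class _Parameterization:
    """Affine basis of net-flux space: v = v0 + N beta."""

    def __init__(self, model: NetworkModel, fixed: dict[str, float], extra: list[tuple[str, float]] = ()):
        S, _mets = stoichiometric_matrix(model)
        rids = model.reaction_ids
        idx = {r: i for i, r in enumerate(rids)}
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        for r in model.reactions:
            if r.kind == "dilution-exchange":
                e = np.zeros(len(rids))
                e[idx[r.id]] = 1.0
                rows.append(e[None, :])
                rhs.append(np.array([0.0]))
        for rid, val in fixed.items():
            e = np.zeros(len(rids))
            e[idx[rid]] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([val]))
        for rid, val in extra:
            e = np.zeros(len(rids))
            e[idx[rid]] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([val]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        v0, res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
        if np.linalg.norm(A @ v0 - b) > 1e-6 * max(1.0, np.linalg.norm(b)):
            raise ValueError("infeasible flux constraints")
        self.model = model
        self.rids = rids
        self.idx = idx
        self.v0 = v0
        self.N = linalg.null_space(A)
        self.irreversible = np.array(
            [not r.reversible and r.kind == "net" for r in model.reactions]
        )

    @property
    def n_free(self) -> int:
        return self.N.shape[1]

    def v(self, beta: np.ndarray) -> np.ndarray:
        return self.v0 + self.N @ beta

    def project(self, v: np.ndarray) -> np.ndarray:
        return self.N.T @ (v - self.v0)


def _exchange_from_u(u: np.ndarray) -> np.ndarray:
    return EXCHANGE_SCALE * u / (1.0 - u)


def _u_from_exchange(e: np.ndarray) -> np.ndarray:
    e = np.asarray(e, dtype=float)
    return e / (EXCHANGE_SCALE + e)


class _Problem:
    """Precompiled residual machinery for one measurement set."""

    def __init__(
        self,
        model: NetworkModel,
        measurements: MeasurementSet,
        fit_exchanges: tuple[str, ...],
        excluded_tracers: tuple[str, ...],
        extra_constraints: list[tuple[str, float]] = (),
        fixed_exchange: dict[str, float] | None = None,
    ):
        measurements.validate(model)
        self.model = model
        self.m = measurements
        self.excluded = tuple(excluded_tracers)
        fixed = biomass_flux_from_growth(measurements.mu, model, measurements.dry_mass)
        self.param = _Parameterization(model, fixed, list(extra_constraints))
        self.fixed_exchange = dict(fixed_exchange or {})
        self.fit_exchanges = tuple(r for r in fit_exchanges if r not in self.fixed_exchange)

        self.experiments = []
        for exp in sorted(measurements.mids):
            if exp in self.excluded:
                continue
            frags = measurements.mids[exp]
            targets = {
                fid: (measurements.fragments[fid].metabolite, measurements.fragments[fid].carbon_atoms)
                for fid in sorted(frags)
            }
            system = decompose_emus(model, targets)
            meas = np.concatenate([np.asarray(frags[fid].values) for fid in sorted(frags)])
            sds = np.concatenate([np.asarray(frags[fid].sds) for fid in sorted(frags)])
            self.experiments.append((exp, sorted(frags), targets, system, meas, sds))

        self.ex_rows = []
        for met in sorted(measurements.exflux):
            rid, sign = measurements.exflux_map[met]
            val, sd = measurements.exflux[met]
            if sd <= 0:
                raise ValueError(f"extracellular flux SD for {met} must be positive")
            self.ex_rows.append((self.param.idx[rid], sign, val, sd))

        # every fitted mass fraction counts as one measurement (Metran-style),
        # plus one per extracellular rate
        self.n_meas = len(self.ex_rows) + sum(
            len(measurements.mids[exp][fid].values)
            for exp, fids, _t, _s, _mv, _sd in self.experiments
            for fid in fids
        )
        self.n_params = self.param.n_free + len(self.fit_exchanges)

    def split(self, x: np.ndarray):
        nb = self.param.n_free
        return x[:nb], x[nb:]

    def flux_dicts(self, x: np.ndarray):
        beta, u = self.split(x)
        v = self.param.v(beta)
        net = {rid: float(v[i]) for rid, i in self.param.idx.items()}
        exch = dict(self.fixed_exchange)
        for rid, ui in zip(self.fit_exchanges, u):
            exch[rid] = float(_exchange_from_u(np.clip(ui, 0.0, 0.999999)))
        return net, exch, v

    def residuals(self, x: np.ndarray, with_penalty: bool = True) -> np.ndarray:
        net, exch, v = self.flux_dicts(x)
        out = []
        for i, sign, val, sd in self.ex_rows:
            out.append((sign * v[i] - val) / sd)
        for _exp, fids, targets, system, meas, sds in self.experiments:
            tracers = self.m.tracers[_exp]
            try:
                sims = simulate_mids(
                    self.model, net, exch, tracers, targets,
                    system=system, check_steady_state=False,
                )
            except Exception:
                out.extend([1e3] * len(meas))
                continue
            sim = np.concatenate([sims[fid] for fid in fids])
            out.extend((sim - meas) / sds)
        res = np.array(out)
        if with_penalty:
            neg = np.minimum(v[self.param.irreversible], 0.0)
            res = np.concatenate([res, _HINGE_WEIGHT * neg])
        return res

    def ssres(self, x: np.ndarray) -> float:
        r = self.residuals(x, with_penalty=False)
        return float(r @ r)

    def optimize(self, x0: np.ndarray, ftol: float = 1e-10, max_nfev: int | None = None):
        nb = self.param.n_free
        lo = np.concatenate([np.full(nb, -np.inf), np.zeros(len(self.fit_exchanges))])
        hi = np.concatenate([np.full(nb, np.inf), np.full(len(self.fit_exchanges), 0.995)])
        x0 = np.clip(x0, lo, hi)
        x_scale = np.concatenate([np.full(nb, 50.0), np.full(len(self.fit_exchanges), 0.1)])
        return optimize.least_squares(
            self.residuals, x0, bounds=(lo, hi), x_scale=x_scale,
            ftol=ftol, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev, method="trf",
        )

    def start_points(self, n: int, rng: np.random.Generator) -> list[np.ndarray]:
        """Random feasible-ish starts anchored on the measured extracellular rates."""
        # weighted linear fit of beta to the extracellular measurements
        rows, vals = [], []
        for i, sign, val, sd in self.ex_rows:
            rows.append(sign * self.param.N[i] / sd)
            vals.append((val - sign * self.param.v0[i]) / sd)
        beta0 = np.zeros(self.param.n_free)
        if rows:
            A = np.vstack(rows)
            A = np.vstack([A, 1e-3 * np.eye(self.param.n_free)])
            b = np.concatenate([vals, np.zeros(self.param.n_free)])
            beta0, *_ = np.linalg.lstsq(A, b, rcond=None)
        starts = []
        for k in range(n):
            beta = beta0 if k == 0 else beta0 + rng.normal(0.0, 30.0, self.param.n_free)
            u = (
                np.full(len(self.fit_exchanges), 0.3)
                if k == 0
                else rng.uniform(0.05, 0.8, len(self.fit_exchanges))
            )
            starts.append(np.concatenate([beta, u]))
        return starts


def estimate_fluxes(
    model: NetworkModel,
    measurements: MeasurementSet,
    n_restarts: int = 20,
    seed: int = 0,
    lactate_mids_in_fit: bool = False,
    fit_exchanges: tuple[str, ...] = DEFAULT_FIT_EXCHANGES,
    excluded_tracers: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    ftol: float = 1e-10,
) -> FitResult:
    """Fit net and exchange fluxes to parallel-labeling MIDs and extracellular rates.

    Multi-start variance-weighted least squares from random initial fluxes; the
    best SSRes solution is returned, deterministically for a given seed.  MIDs
    from the lactate tracer experiment (experiment name ``"lac"``) are excluded
    from the objective unless ``lactate_mids_in_fit`` is set; they remain
    available for posterior qualitative comparison.
    """
    if excluded_tracers is None:
        excluded_tracers = () if lactate_mids_in_fit else ("lac",)
    prob = _Problem(model, measurements, tuple(fit_exchanges), tuple(excluded_tracers))
    if prob.n_meas <= prob.n_params:
        raise ValueError(
            f"underdetermined fit: {prob.n_meas} measurements, {prob.n_params} parameters"
        )
    rng = np.random.default_rng(seed)
    best = None
    best_feasible = None
    n_used = 0
    for x0 in prob.start_points(max(1, n_restarts), rng):
        try:
            res = prob.optimize(x0, ftol=ftol)
        except Exception:
            continue
        n_used += 1
        _net, _exch, v = prob.flux_dicts(res.x)
        feasible = not np.any(
            v[prob.param.irreversible] < -1e-3 * max(1.0, float(np.max(np.abs(v))))
        )
        if best is None or res.cost < best.cost:
            best = res
        if feasible and (best_feasible is None or res.cost < best_feasible.cost):
            best_feasible = res
    if best is None:
        raise RuntimeError("no optimization start converged; check measurement scaling")
    if best_feasible is None:
        _net, _exch, v = prob.flux_dicts(best.x)
        worst = float(np.min(v[prob.param.irreversible]))
        raise RuntimeError(
            f"no feasible solution found over {n_used} starts "
            f"(best has irreversible flux {worst:.3g}); increase n_restarts"
        )

    x = best_feasible.x
    net, exch, v = prob.flux_dicts(x)
    net = {r: (0.0 if prob.param.irreversible[prob.param.idx[r]] and val < 0 else val)
           for r, val in net.items()}
    ssres = prob.ssres(x)
    verdict, bounds, dof = goodness_of_fit(ssres, prob.n_meas, prob.n_params, alpha)
    return FitResult(
        fluxes=FluxVector(net=net, exchange=exch),
        ssres=ssres,
        n_measurements=prob.n_meas,
        n_parameters=prob.n_params,
        dof=dof,
        chi2_bounds=bounds,
        verdict=verdict,
        n_restarts_used=n_used,
        seed=seed,
        converged=True,
        _problem=prob,
        _x=x,
    )


def goodness_of_fit(
    ssres: float, n_measurements: int, n_free_params: int, alpha: float = 0.05
) -> tuple[str, tuple[float, float], int]:
    """Chi-square goodness-of-fit verdict.

    ``n_measurements`` counts every fitted value (each mass fraction of every
    MID, each extracellular rate).  Returns (verdict, (lower, upper), dof)
    with verdict "accept" iff lower <= SSRes <= upper at the two-sided alpha
    level; below = "overfit", above = "underfit".
    """
    dof = n_measurements - n_free_params
    if dof <= 0:
        raise ValueError("degrees of freedom must be positive")
    lo = float(stats.chi2.ppf(alpha / 2, dof))
    hi = float(stats.chi2.ppf(1 - alpha / 2, dof))
    if ssres < lo:
        verdict = "overfit"
    elif ssres > hi:
        verdict = "underfit"
    else:
        verdict = "accept"
    return verdict, (lo, hi), dof


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


def _constrained_refit(
    fit: FitResult, quantity: tuple[str, str], value: float, ftol: float = 1e-8
) -> float:
    """SSRes re-optimized with one flux held at ``value`` (inf if infeasible)."""
    prob = fit._problem
    kind, rid = quantity
    if kind == "net":
        try:
            sub = _Problem(
                prob.model, prob.m, prob.fit_exchanges, prob.excluded,
                extra_constraints=[(rid, value)], fixed_exchange=prob.fixed_exchange,
            )
        except ValueError:
            return np.inf
        if np.any(sub.param.v0[sub.param.irreversible] < -1e-6) and sub.param.n_free == 0:
            return np.inf
        v_prev = prob.param.v(prob.split(fit._x)[0])
        beta0 = sub.param.project(v_prev)
        x0 = np.concatenate([beta0, prob.split(fit._x)[1]])
    elif kind == "exchange":
        if value < 0:
            return np.inf
        if rid not in prob.fit_exchanges:
            raise KeyError(f"{rid} is not a fitted exchange flux")
        fixed = dict(prob.fixed_exchange)
        fixed[rid] = value
        sub = _Problem(
            prob.model, prob.m, prob.fit_exchanges, prob.excluded, fixed_exchange=fixed
        )
        beta_prev, u_prev = prob.split(fit._x)
        keep = [i for i, r in enumerate(prob.fit_exchanges) if r != rid]
        x0 = np.concatenate([beta_prev, u_prev[keep]])
    else:
        raise ValueError(f"unknown quantity kind {kind!r}")
    try:
        res = sub.optimize(x0, ftol=ftol, max_nfev=60 * (sub.n_params + 1))
    except Exception:
        return np.inf
    return sub.ssres(res.x)


def profile_covers(fit: FitResult, quantity: tuple[str, str], value: float, alpha: float = 0.05) -> bool:
    """Whether ``value`` lies inside the profile-likelihood CI of one flux."""
    threshold = fit.ssres + stats.chi2.ppf(1 - alpha, 1)
    return _constrained_refit(fit, quantity, value) <= threshold


def confidence_intervals(
    fit: FitResult,
    quantities: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    rel_tol: float = 0.02,
    max_flux: float = 3000.0,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Profile-likelihood confidence intervals for the requested fluxes.

    For each flux the objective is profiled (all other parameters
    re-optimized) until SSRes exceeds SSRes_min + chi2(1-alpha, 1); the
    crossing is located by bisection.  A direction that never crosses within
    ``max_flux`` is reported as open (+-inf).
    """
    if fit._problem is None or fit._x is None:
        raise ValueError("fit does not carry profiling state (not a converged fit)")
    prob = fit._problem
    if quantities is None:
        quantities = [("net", rid) for rid in prob.param.rids] + [
            ("exchange", rid) for rid in prob.fit_exchanges
        ]
    threshold = fit.ssres + float(stats.chi2.ppf(1 - alpha, 1))
    out = {}
    for q in quantities:
        kind, rid = q
        if kind == "net":
            center = fit.fluxes.net[rid]
            lower_limit = 0.0 if fit._problem.param.irreversible[prob.param.idx[rid]] else -max_flux
        else:
            center = fit.fluxes.exchange[rid]
            lower_limit = 0.0
        scale = max(abs(center) * 0.1, 2.0)
        lo = _profile_direction(fit, q, center, -scale, threshold, lower_limit, rel_tol)
        hi = _profile_direction(fit, q, center, +scale, threshold, max_flux, rel_tol)
        out[q] = (lo, hi)
    fit.ci.update(out)
    return out


def _profile_direction(fit, quantity, center, step, threshold, limit, rel_tol) -> float:
    """March then bisect one profile direction; returns the CI endpoint."""
    inside = center
    q = center
    for _ in range(40):
        q = q + step
        if (step < 0 and q <= limit) or (step > 0 and q >= limit):
            q = limit
        ss = _constrained_refit(fit, quantity, q)
        if ss > threshold:
            break
        inside = q
        if q == limit:
            return float(limit) if limit in (0.0,) else (-np.inf if step < 0 else np.inf)
        step *= 1.7
    else:
        return -np.inf if step < 0 else np.inf
    outside = q
    # bisect between inside and outside
    for _ in range(30):
        if abs(outside - inside) <= rel_tol * max(abs(center), 1.0):
            break
        mid = 0.5 * (inside + outside)
        if _constrained_refit(fit, quantity, mid) > threshold:
            outside = mid
        else:
            inside = mid
    return float(0.5 * (inside + outside))


def sensitivity_rerun(
    model: NetworkModel,
    measurements: MeasurementSet,
    fragment_id: str,
    replacement_sd_molpct: float = 0.6,
    **fit_kwargs,
) -> tuple[FitResult, FitResult, dict[str, float]]:
    """Refit with one fragment's MID SDs replaced (e.g. by the 0.6 mol% floor).

    Returns (baseline fit, rerun fit, per-reaction net flux differences).
    """
    found = False
    new_mids = {}
    for exp, frags in measurements.mids.items():
        new_frags = dict(frags)
        if fragment_id in new_frags:
            found = True
            old = new_frags[fragment_id]
            new_frags[fragment_id] = replace(
                old, sds=np.full_like(np.asarray(old.values), replacement_sd_molpct / 100.0)
            )
        new_mids[exp] = new_frags
    if not found:
        raise KeyError(f"fragment {fragment_id!r} not present in measurements")
    baseline = estimate_fluxes(model, measurements, **fit_kwargs)
    modified = replace_measurements(measurements, new_mids)
    rerun = estimate_fluxes(model, modified, **fit_kwargs)
    diffs = {
        rid: rerun.fluxes.net[rid] - baseline.fluxes.net[rid] for rid in baseline.fluxes.net
    }
    return baseline, rerun, diffs


def replace_measurements(m: MeasurementSet, mids) -> MeasurementSet:
    return MeasurementSet(
        exflux=dict(m.exflux), mids=mids, tracers=m.tracers, fragments=m.fragments,
        mu=m.mu, dry_mass=m.dry_mass, exflux_map=dict(m.exflux_map),
    )


# ---------------------------------------------------------------------------
# stoichiometric yield ceiling
# ---------------------------------------------------------------------------


def max_secretion_yield(
    model: NetworkModel, uptake: str = "v1", secretion: str = "v10"
) -> float:
    """Maximum feasible secretion:uptake flux ratio with all other exchanges closed.

    Fixes the uptake reaction at 1, constrains every other reaction touching an
    extracellular metabolite or a biomass sink to zero net flux (internal
    decarboxylations stay open: CO2 is an unbalanced byproduct, not a carbon
    exchange with the environment), and maximizes the secretion flux subject to
    steady state.  On the default network with glucose in and lactate out this
    is the theoretical glycolytic ceiling of 2 mol lactate per mol glucose.
    """
    S, _mets = stoichiometric_matrix(model)
    rids = model.reaction_ids
    idx = {r: i for i, r in enumerate(rids)}
    n = len(rids)
    A_rows = [S]
    b = [np.zeros(S.shape[0])]
    closed = {
        r.id
        for r in model.reactions
        for t in r.terms()
        if model.metabolites[t.met].compartment == "extracellular"
        or model.metabolites[t.met].is_sink
    } - {uptake, secretion}
    bounds = []
    for r in model.reactions:
        i = idx[r.id]
        if r.id == uptake:
            bounds.append((1.0, 1.0))
        elif r.id in closed or r.kind == "dilution-exchange":
            bounds.append((0.0, 0.0))
        elif r.reversible:
            bounds.append((-1e6, 1e6))
        else:
            bounds.append((0.0, 1e6))
    c = np.zeros(n)
    c[idx[secretion]] = -1.0
    res = optimize.linprog(c, A_eq=np.vstack(A_rows), b_eq=np.concatenate(b), bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"yield LP failed: {res.message}")
    return float(res.x[idx[secretion]])
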