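"""Flux fitting: self-consistency, chi-square calibration, profile CIs."""

import numpy as np
import pytest
from scipy import stats

from lactoflux.emu import TracerSpec, simulate_mids
from lactoflux.estimation import (
    MeasurementSet,
    biomass_flux_from_growth,
    confidence_intervals,
    estimate_fluxes,
    goodness_of_fit,
    max_secretion_yield,
    sensitivity_rerun,
)
from lactoflux.mid import FragmentSpec, MIDVector
from lactoflux.network import default_breast_network


class TestBiomassFlux:
    def test_zero_growth_gives_zero_drains(self):
        model = default_breast_network()
        drains = biomass_flux_from_growth(0.0, model)
        assert set(drains) == {"v36", "v37"}
        assert all(v == 0.0 for v in drains.values())

    def test_linear_in_growth_rate(self):
        model = default_breast_network()
        a = biomass_flux_from_growth(0.021, model)
        b = biomass_flux_from_growth(0.042, model)
        for rid in a:
            assert b[rid] == pytest.approx(2 * a[rid])

    def test_hand_unit_conversion(self):
        """mu = 0.02 1/h x 470 pg/cell = 9.4 ug DW/1e6 cells/h; the glutamine
        drain at 0.35 mmol/g DW is then 0.35 nmol/ug x 9.4 = 3.29 nmol/1e6/h."""
        model = default_breast_network()
        drains = biomass_flux_from_growth(0.02, model)
        assert drains["v36"] == pytest.approx(9.4)
        gln_coeff = model.biomass_coefficients["v36"]["GLN"]
        assert gln_coeff * drains["v36"] == pytest.approx(3.29)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            biomass_flux_from_growth(-0.01, default_breast_network())


class TestGoodnessOfFit:
    def test_ssres_at_dof_mean_accepts(self):
        verdict, (lo, hi), dof = goodness_of_fit(10.0, 12, 2)
        assert dof == 10 and verdict == "accept"

    def test_tiny_ssres_is_overfit(self):
        # chi2 2.5th percentile at dof 10 is ~3.25 > 1
        verdict, (lo, _), _ = goodness_of_fit(1.0, 12, 2)
        assert lo == pytest.approx(stats.chi2.ppf(0.025, 10))
        assert verdict == "overfit"

    def test_huge_ssres_is_underfit(self):
        verdict, _, _ = goodness_of_fit(100.0, 12, 2)
        assert verdict == "underfit"

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(1.0, 2, 2)


# ---------------------------------------------------------------------------
# toy-model fitting helpers
# ---------------------------------------------------------------------------

TOY_TRUTH = {"t1": 10.0, "t2": 10.0, "t3": 10.0, "t4": 5.0, "t5": 5.0}
TOY_EXCH = {"t2": 4.0}
TOY_TRACERS = {"glc": {"A.x": [TracerSpec("A.x", (1, 2), 0.95)]}}
TOY_FRAGMENTS = {
    "P_full": FragmentSpec("P_full", "P", (1, 2, 3, 4), "C8H10O2"),
    "C_full": FragmentSpec("C_full", "C", (1, 2, 3), "C6H8O2"),
}
TOY_EXFLUX_MAP = {"A": ("t1", -1), "P": ("t5", +1)}


def toy_measurements(model, rng=None, mid_sd=0.006, ex_sd=0.5, exact=False):
    """Measurement set for the condensation toy at the known ground truth."""
    targets = {f: (s.metabolite, s.carbon_atoms) for f, s in TOY_FRAGMENTS.items()}
    sims = simulate_mids(model, TOY_TRUTH, TOY_EXCH, TOY_TRACERS["glc"], targets)
    mids = {}
    for fid, sim in sims.items():
        vals = sim if exact else sim + rng.normal(0.0, mid_sd, len(sim))
        mids[fid] = MIDVector(fid, vals, sds=np.full(len(sim), mid_sd), state="corrected")
    ex = {
        "A": (-TOY_TRUTH["t1"] + (0.0 if exact else rng.normal(0, ex_sd)), ex_sd),
        "P": (TOY_TRUTH["t5"] + (0.0 if exact else rng.normal(0, ex_sd)), ex_sd),
    }
    return MeasurementSet(
        exflux=ex, mids={"glc": mids}, tracers=TOY_TRACERS,
        fragments=TOY_FRAGMENTS, mu=0.0, exflux_map=TOY_EXFLUX_MAP,
    )


class TestToyFitting:
    def test_noise_free_self_consistency(self, condensation_toy):
        """Exact synthetic measurements are recovered with near-zero SSRes."""
        mset = toy_measurements(condensation_toy, exact=True)
        fit = estimate_fluxes(
            condensation_toy, mset, n_restarts=3, seed=1, fit_exchanges=("t2",)
        )
        assert fit.ssres < 1e-6
        for rid, truth in TOY_TRUTH.items():
            assert fit.fluxes.net[rid] == pytest.approx(truth, rel=1e-3)
        # the B<->C exchange is structurally unidentifiable in a linear chain
        # (both pools carry identical labeling), so only net fluxes are checked

    def test_multistart_deterministic_given_seed(self, condensation_toy, rng):
        mset = toy_measurements(condensation_toy, rng)
        fits = [
            estimate_fluxes(condensation_toy, mset, n_restarts=3, seed=9, fit_exchanges=("t2",))
            for _ in range(2)
        ]
        assert fits[0].fluxes.net == fits[1].fluxes.net
        assert fits[0].ssres == fits[1].ssres

    def test_objective_invariant_to_measurement_ordering(self, condensation_toy, rng):
        mset = toy_measurements(condensation_toy, rng)
        flipped = MeasurementSet(
            exflux=dict(reversed(list(mset.exflux.items()))),
            mids={"glc": dict(reversed(list(mset.mids["glc"].items())))},
            tracers=mset.tracers, fragments=mset.fragments, mu=0.0,
            exflux_map=TOY_EXFLUX_MAP,
        )
        a = estimate_fluxes(condensation_toy, mset, n_restarts=2, seed=3, fit_exchanges=("t2",))
        b = estimate_fluxes(condensation_toy, flipped, n_restarts=2, seed=3, fit_exchanges=("t2",))
        assert a.ssres == pytest.approx(b.ssres, rel=1e-9)

    def test_ssres_calibrated_at_stated_sds(self, condensation_toy):
        """With noise generated at the stated SDs and those SDs used as
        weights, the SSRes distribution mean sits at the residual dof."""
        rng = np.random.default_rng(77)
        ssres = []
        for _ in range(60):
            mset = toy_measurements(condensation_toy, rng)
            fit = estimate_fluxes(
                condensation_toy, mset, n_restarts=2, seed=5, fit_exchanges=("t2",)
            )
            ssres.append(fit.ssres)
        dof = fit.dof
        assert np.mean(ssres) == pytest.approx(dof, rel=0.15)

    def test_fitted_fluxes_satisfy_steady_state_and_signs(self, condensation_toy, rng):
        from lactoflux.network import stoichiometric_matrix

        mset = toy_measurements(condensation_toy, rng)
        fit = estimate_fluxes(condensation_toy, mset, n_restarts=2, seed=2, fit_exchanges=("t2",))
        S, _ = stoichiometric_matrix(condensation_toy)
        v = np.array([fit.fluxes.net[r.id] for r in condensation_toy.reactions])
        assert np.max(np.abs(S @ v)) < 1e-6 * max(1.0, np.max(np.abs(v)))
        for r in condensation_toy.reactions:
            if not r.reversible:
                assert fit.fluxes.net[r.id] >= -1e-9
        assert all(e >= 0 for e in fit.fluxes.exchange.values())


class TestConfidenceIntervals:
    def test_profile_matches_analytic_gaussian_linear_case(self, linear_toy):
        """Two direct rate measurements of one free flux: the profile CI must
        match the closed-form weighted least-squares interval."""
        mset = MeasurementSet(
            exflux={"A": (-10.0, 1.0), "B": (9.0, 1.0)},
            mids={}, tracers={}, fragments={}, mu=0.0,
            exflux_map={"A": ("r1", -1), "B": ("r4", +1)},
        )
        fit = estimate_fluxes(linear_toy, mset, n_restarts=2, seed=1, fit_exchanges=())
        vhat = fit.fluxes.net["r1"]
        assert vhat == pytest.approx(9.5, abs=1e-6)
        ci = confidence_intervals(fit, [("net", "r1")], rel_tol=5e-4)
        lo, hi = ci[("net", "r1")]
        se = 1.0 / np.sqrt(2.0)
        half = np.sqrt(stats.chi2.ppf(0.95, 1)) * se
        assert lo == pytest.approx(vhat - half, rel=0.01)
        assert hi == pytest.approx(vhat + half, rel=0.01)

    def test_noise_free_intervals_collapse(self, condensation_toy):
        """With vanishing measurement SDs the profile CI collapses onto the
        point estimate."""
        mset = toy_measurements(condensation_toy, mid_sd=1e-5, ex_sd=1e-4, exact=True)
        fit = estimate_fluxes(condensation_toy, mset, n_restarts=2, seed=1, fit_exchanges=("t2",))
        ci = confidence_intervals(fit, [("net", "t1")], rel_tol=1e-4)
        lo, hi = ci[("net", "t1")]
        assert hi - lo < 1e-2 * TOY_TRUTH["t1"]

    def test_point_estimate_inside_intervals(self, condensation_toy, rng):
        mset = toy_measurements(condensation_toy, rng)
        fit = estimate_fluxes(condensation_toy, mset, n_restarts=2, seed=4, fit_exchanges=("t2",))
        ci = confidence_intervals(fit, [("net", "t1"), ("exchange", "t2")])
        for (kind, rid), (lo, hi) in ci.items():
            val = fit.fluxes.net[rid] if kind == "net" else fit.fluxes.exchange[rid]
            assert lo <= val <= hi


class TestSensitivityRerun:
    def test_noop_when_sds_already_at_replacement(self, condensation_toy, rng):
        mset = toy_measurements(condensation_toy, rng, mid_sd=0.006)
        base, rerun, diffs = sensitivity_rerun(
            condensation_toy, mset, "P_full", replacement_sd_molpct=0.6,
            n_restarts=2, seed=6, fit_exchanges=("t2",),
        )
        assert base.ssres == pytest.approx(rerun.ssres, rel=1e-6)
        assert max(abs(d) for d in diffs.values()) < 1e-6

    def test_verdict_flips_when_oversized_sd_floored(self, condensation_toy):
        """Inflated MID errors make a correct fit look overfit; restoring one
        fragment's SDs to the floor recovers an accepted chi-square verdict."""
        rng = np.random.default_rng(123)
        mset = toy_measurements(condensation_toy, rng, mid_sd=0.006)
        for fid in mset.mids["glc"]:
            m = mset.mids["glc"][fid]
            mset.mids["glc"][fid] = MIDVector(
                fid, m.values, sds=np.asarray(m.sds) * 10, state="corrected"
            )
        base, rerun, _ = sensitivity_rerun(
            condensation_toy, mset, "P_full", replacement_sd_molpct=0.6,
            n_restarts=2, seed=6, fit_exchanges=("t2",),
        )
        assert base.verdict == "overfit"
        assert rerun.ssres > base.ssres
        assert rerun.verdict == "accept"

    def test_unknown_fragment_rejected(self, condensation_toy, rng):
        mset = toy_measurements(condensation_toy, rng)
        with pytest.raises(KeyError):
            sensitivity_rerun(condensation_toy, mset, "nope")


class TestYieldCeiling:
    def test_default_network_lactate_glucose_ceiling_is_two(self):
        assert max_secretion_yield(default_breast_network()) == pytest.approx(2.0, abs=1e-9)

    def test_ceiling_unaffected_by_reversible_loops(self, linear_toy):
        # A(3C) -> ... -> D(2C): one carbon is lost as CO2, yield 1
        y = max_secretion_yield(linear_toy, uptake="r1", secretion="r4")
        assert y == pytest.approx(1.0, abs=1e-9)
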