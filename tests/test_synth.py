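"""Synthetic study generator: round trips, determinism, study design."""

import numpy as np
import pytest

from lactoflux.emu import simulate_mids
from lactoflux.exflux import compute_flux, correct_glutamine_flux
from lactoflux.mid import MIDVector, correct_natural_abundance
from lactoflux.network import default_breast_network, stoichiometric_matrix
from lactoflux.synth import (
    ScenarioConfig,
    TRACER_PANELS,
    concentration_trajectory,
    default_scenarios,
    generate_mids,
    generate_scenario,
    generate_study,
    generate_timecourse,
    load_default_fragments,
    sample_ground_truth_fluxes,
)

MDA_CONTROL_ANCHORS = {"GLC": -337, "LAC": 603, "GLN": -44, "ALA": 10, "ASP": 3.5, "GLU": 8.5}


@pytest.fixture(scope="module")
def model():
    return default_breast_network()


class TestGroundTruthSampling:
    def test_table_anchors_feasible_with_tiny_steady_state_residual(self, model):
        truth = sample_ground_truth_fluxes(model, MDA_CONTROL_ANCHORS, mu=0.021, seed=0)
        S, _ = stoichiometric_matrix(model)
        v = np.array([truth.net[r.id] for r in model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-8
        assert truth.net["v1"] == pytest.approx(337.0)
        assert truth.net["v10"] == pytest.approx(603.0)

    def test_zero_anchor_set_still_valid(self, model):
        truth = sample_ground_truth_fluxes(model, {}, mu=0.02, seed=3)
        S, _ = stoichiometric_matrix(model)
        v = np.array([truth.net[r.id] for r in model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-8

    def test_seed_reproducibility(self, model):
        a = sample_ground_truth_fluxes(model, MDA_CONTROL_ANCHORS, mu=0.021, seed=11)
        b = sample_ground_truth_fluxes(model, MDA_CONTROL_ANCHORS, mu=0.021, seed=11)
        assert a.net == b.net

    def test_irreversibility_respected(self, model):
        truth = sample_ground_truth_fluxes(model, MDA_CONTROL_ANCHORS, mu=0.021, seed=7)
        for r in model.reactions:
            if not r.reversible:
                assert truth.net[r.id] >= -1e-9

    def test_infeasible_anchors_rejected(self, model):
        bad = dict(MDA_CONTROL_ANCHORS, GLC=-10.0, LAC=900.0)  # > 2:1 ceiling
        with pytest.raises(ValueError, match="infeasible"):
            sample_ground_truth_fluxes(model, bad, mu=0.021, seed=0)


class TestTimecourse:
    def test_noise_free_roundtrip_recovers_flux(self, model):
        """Inverting the rate equation on noise-free trajectories returns the
        ground-truth rate to numerical precision."""
        sc = ScenarioConfig(
            name="t", cell_line="X", condition="control", mu=0.02, seed=1,
            anchor_fluxes=MDA_CONTROL_ANCHORS, conc_cv=0.0,
        )
        truth = sample_ground_truth_fluxes(model, sc.anchor_fluxes, sc.mu, seed=1)
        cells, conc = generate_timecourse(sc, truth, model)
        x24 = cells[cells.time_h == 24.0].density.iloc[0]
        for met, rid, sign in (("GLC", "v1", -1), ("LAC", "v10", 1), ("ALA", "v30", 1)):
            grp = conc[conc.metabolite == met]
            c24 = grp[grp.time_h == 24.0].conc_mM.iloc[0]
            c48 = grp[grp.time_h == 48.0].conc_mM.iloc[0]
            q = compute_flux(sc.mu, c24, c48, x24)
            assert q == pytest.approx(sign * truth.net[rid], rel=1e-6)

    def test_glutamine_decay_plus_uptake_roundtrip(self, model):
        sc = ScenarioConfig(
            name="t", cell_line="X", condition="control", mu=0.02, seed=2,
            anchor_fluxes=MDA_CONTROL_ANCHORS, conc_cv=0.0,
        )
        truth = sample_ground_truth_fluxes(model, sc.anchor_fluxes, sc.mu, seed=2)
        cells, conc = generate_timecourse(sc, truth, model)
        x24 = cells[cells.time_h == 24.0].density.iloc[0]
        grp = conc[conc.metabolite == "GLN"]
        c24 = grp[grp.time_h == 24.0].conc_mM.iloc[0]
        c48 = grp[grp.time_h == 48.0].conc_mM.iloc[0]
        q = correct_glutamine_flux(sc.mu, c24, c48, x24, k_deg=sc.k_deg)
        assert q == pytest.approx(-truth.net["v24"], rel=1e-6)

    def test_zero_flux_metabolite_stays_flat(self):
        traj = concentration_trajectory(3.0, 0.0, 0.02, 1e5, np.array([0.0, 24.0, 48.0]))
        assert np.allclose(traj, 3.0)

    def test_pure_degradation_closed_form(self):
        t = np.array([0.0, 24.0, 48.0])
        traj = concentration_trajectory(3.0, 0.0, 0.02, 1e5, t, k_deg=0.0019)
        assert np.allclose(traj, 3.0 * np.exp(-0.0019 * t))


class TestGeneratedMIDs:
    def test_zero_noise_no_convolution_identity_path(self, model):
        sc = ScenarioConfig(
            name="t", cell_line="X", condition="control", mu=0.021, seed=5,
            anchor_fluxes=MDA_CONTROL_ANCHORS, mid_rep_sd_molpct=0.0,
            convolve_natural_abundance=False, n_rep_mids=1,
        )
        truth = sample_ground_truth_fluxes(
            model, sc.anchor_fluxes, sc.mu, seed=5, exchange=sc.exchange_truth
        )
        tables = generate_mids(sc, truth, model)
        frs = load_default_fragments()
        targets = {f: (frs[f].metabolite, frs[f].carbon_atoms) for f in TRACER_PANELS["glc"]["fragments"]}
        sims = simulate_mids(model, truth.net, truth.exchange, TRACER_PANELS["glc"]["specs"], targets, ss_tol=1e-5)
        df = tables["glc"]
        for fid, sim in sims.items():
            row = df[df.fragment_id == fid].iloc[0]
            vals = row[[f"m{i}" for i in range(len(sim))]].to_numpy(dtype=float)
            assert np.allclose(vals, sim, atol=1e-12)

    def test_convolved_zero_noise_roundtrips_through_correction(self, model):
        sc = ScenarioConfig(
            name="t", cell_line="X", condition="control", mu=0.021, seed=5,
            anchor_fluxes=MDA_CONTROL_ANCHORS, mid_rep_sd_molpct=0.0,
            convolve_natural_abundance=True, n_rep_mids=1,
        )
        truth = sample_ground_truth_fluxes(
            model, sc.anchor_fluxes, sc.mu, seed=5, exchange=sc.exchange_truth
        )
        tables = generate_mids(sc, truth, model)
        frs = load_default_fragments()
        targets = {f: (frs[f].metabolite, frs[f].carbon_atoms) for f in TRACER_PANELS["gln"]["fragments"]}
        sims = simulate_mids(model, truth.net, truth.exchange, TRACER_PANELS["gln"]["specs"], targets, ss_tol=1e-5)
        df = tables["gln"]
        for fid, sim in sims.items():
            row = df[df.fragment_id == fid].iloc[0]
            mcols = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]
            vals = row[sorted(mcols, key=lambda c: int(c[1:]))].to_numpy(dtype=float)
            raw = MIDVector(fid, vals[~np.isnan(vals)], state="raw")
            corrected = correct_natural_abundance(raw, frs[fid])
            assert np.max(np.abs(corrected.values - sim)) < 1e-8


@pytest.fixture(scope="module")
def study(model):
    # trimmed scenario list keeps the full-bundle test fast
    scenarios = [s for s in default_scenarios(3) if s.cell_line == "MCF7"]
    return generate_study(seed=3, scenarios=scenarios, model=model)


class TestStudyBundle:
    def test_control_scenarios_have_no_lactate_tracer(self, study):
        assert set(study["scenarios"]["MCF7_control"]["mids"]) == {"glc", "gln"}
        assert set(study["scenarios"]["MCF7_high_lactate"]["mids"]) == {"glc", "gln", "lac"}

    def test_manifest_matches_regeneration(self, study, model):
        scenarios = [s for s in default_scenarios(3) if s.cell_line == "MCF7"]
        again = generate_study(seed=3, scenarios=scenarios, model=model)
        assert again["manifest"] == study["manifest"]
        for name in study["scenarios"]:
            a = study["scenarios"][name]["mids"]["gln"]
            b = again["scenarios"][name]["mids"]["gln"]
            assert a.equals(b)

    def test_high_lactate_has_more_m5_citrate_in_gln_tracer(self, study, model):
        """Elevated IDH exchange in the high-lactate scenario shows up as
        higher M5 citrate under [U-13C] glutamine."""
        frs = load_default_fragments()
        m5 = {}
        for name, data in study["scenarios"].items():
            truth = data["truth"]
            targets = {"CIT_123456": (frs["CIT_123456"].metabolite, frs["CIT_123456"].carbon_atoms)}
            out = simulate_mids(
                model, truth.net, truth.exchange, TRACER_PANELS["gln"]["specs"],
                targets, check_steady_state=False,
            )
            m5[name] = out["CIT_123456"][5]
        assert m5["MCF7_high_lactate"] > m5["MCF7_control"]

    def test_write_study_roundtrip(self, study, tmp_path):
        from lactoflux.synth import write_study
        import json

        write_study(study, tmp_path / "out")
        assert (tmp_path / "out" / "ground_truth.json").exists()
        manifest = json.loads((tmp_path / "out" / "ground_truth.json").read_text())
        assert set(manifest["ground_truth"]) == set(study["scenarios"])
        for name in study["scenarios"]:
            d = tmp_path / "out" / name
            assert (d / "cells.csv").exists() and (d / "concentrations.csv").exists()

    def test_written_study_reloads_with_scenario_metadata(self, study, tmp_path):
        """A written scenario directory carries enough metadata for the
        analysis stages to know the MID scale and condition labels."""
        from lactoflux.cli import _read_scenario_dir
        from lactoflux.synth import write_study

        write_study(study, tmp_path / "out")
        data = _read_scenario_dir(tmp_path / "out" / "MCF7_high_lactate")
        assert data["config"].condition == "high_lactate"
        assert data["config"].cell_line == "MCF7"
        assert data["config"].convolve_natural_abundance is False
        assert set(data["mids"]) == {"glc", "gln", "lac"}


class TestScenarioValidation:
    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(name="x", cell_line="X", condition="control", mu=0.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(name="x", cell_line="X", condition="control", mu=0.02, conc_cv=-1)
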