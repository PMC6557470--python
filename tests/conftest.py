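"""Shared fixtures: toy carbon-mapped networks for oracle cross-checks."""

import numpy as np
import pytest

from lactoflux.emu import TracerSpec
from lactoflux.network import parse_network, stoichiometric_matrix


def random_feasible_fluxes(model, rng, scale=10.0):
    """Random strictly positive flux vector satisfying S v = 0."""
    from scipy.linalg import null_space

    S, _ = stoichiometric_matrix(model)
    rids = [r.id for r in model.reactions]
    dil = [i for i, r in enumerate(model.reactions) if r.kind == "dilution-exchange"]
    rows = [S]
    for i in dil:
        e = np.zeros(len(rids))
        e[i] = 1.0
        rows.append(e[None, :])
    N = null_space(np.vstack(rows))
    for _ in range(200):
        v = N @ rng.normal(0, scale, N.shape[1])
        irrev = np.array([not r.reversible for r in model.reactions])
        if np.all(v[irrev] > 0.5):
            exch = {
                r.id: float(rng.uniform(0.0, scale))
                for r in model.reactions
                if r.reversible
            }
            return {rid: float(val) for rid, val in zip(rids, v)}, exch
    raise RuntimeError("no feasible flux vector found")


# (fixture name, nominal net fluxes, tracers, target fragments) for the
# EMU-vs-brute-force oracle equivalence checks
TOY_CASES = [
    ("linear_toy", {"r1": 8.0, "r2": 8.0, "r3": 8.0, "r4": 8.0},
     {"A.x": [TracerSpec("A.x", (1, 2), 0.95)]},
     {"D": ("D", (1, 2)), "C13": ("C", (1, 3))}),
    ("condensation_toy", {"t1": 10.0, "t2": 10.0, "t3": 10.0, "t4": 5.0, "t5": 5.0},
     {"A.x": [TracerSpec("A.x", (2, 3), 0.8)]},
     {"P": ("P", (1, 2, 3, 4)), "D": ("D", (1, 2))}),
    ("symmetric_toy", {"s1": 6.0, "s2": 6.0, "s3": 6.0},
     {"A.x": [TracerSpec("A.x", (1,), 0.9)]},
     {"M": ("M", (1, 2, 3, 4)), "M14": ("M", (1, 4))}),
    ("cycle_toy", {"c1": 10.0, "c2": 5.0, "c3": 10.0, "c4": 10.0, "c5": 10.0, "c6": 5.0},
     {"Ac.x": [TracerSpec("Ac.x", "U", 0.99)]},
     {"CI": ("CI", (1, 2, 3, 4, 5)), "OX": ("OX", (1, 2, 3))}),
    ("dilution_toy", {"d1": 7.0, "d2": 7.0, "d3": 0.0},
     {"A.x": [TracerSpec("A.x", "U", 0.9)], "L.x": [TracerSpec("L.x", "U", 0.5)]},
     {"L": ("L", (1, 2, 3))}),
]


@pytest.fixture(scope="session")
def linear_toy():
    """Linear chain with one reversible step and a decarboxylation."""
    return parse_network(
        "@unbalanced A.x B.x CO2\n"
        "r1\tA.x (abc) -> B (abc)\n"
        "r2\tB (abc) <-> C (abc)\n"
        "r3\tC (abc) -> D (bc) + CO2 (a)\n"
        "r4\tD (ab) -> B.x (ab)\n"
    )


@pytest.fixture(scope="session")
def condensation_toy():
    """Cleavage plus condensation: P(4) built from two D(2) units."""
    return parse_network(
        "@unbalanced A.x P.x CO2\n"
        "t1\tA.x (abc) -> B (abc)\n"
        "t2\tB (abc) <-> C (abc)\n"
        "t3\tC (abc) -> D (bc) + CO2 (a)\n"
        "t4\tD (ab) + D (cd) -> P (acbd)\n"
        "t5\tP (abcd) -> P.x (abcd)\n"
    )


@pytest.fixture(scope="session")
def symmetric_toy():
    """Rotationally symmetric intermediate (equal-weight atom-map variants)."""
    return parse_network(
        "@unbalanced A.x Q.x\n"
        "s1\tA.x (abcd) -> F (abcd|dcba)\n"
        "s2\tF (abcd) <-> M (abcd)\n"
        "s3\tM (abcd) -> Q.x (abcd)\n"
    )


@pytest.fixture(scope="session")
def cycle_toy():
    """TCA-like cycle: condensation, CO2 release, anaplerotic input.

    14 total backbone carbons, within the brute-force oracle's limit.
    """
    return parse_network(
        "@unbalanced Ac.x An.x CO2 Out.x\n"
        "c1\tAc.x (ab) -> AC (ab)\n"
        "c2\tAn.x (abc) -> OX (abc)\n"
        "c3\tOX (abc) + AC (de) -> CI (cbeda)\n"
        "c4\tCI (abcde) <-> AK (abcd) + CO2 (e)\n"
        "c5\tAK (abcd) -> OX (bcd) + CO2 (a)\n"
        "c6\tOX (abc) -> Out.x (abc)\n"
    )


@pytest.fixture(scope="session")
def dilution_toy():
    """Intracellular pool diluted by an extracellular exchange (no net flux)."""
    return parse_network(
        "@unbalanced A.x L.x\n"
        "@dilution d3\n"
        "d1\tA.x (abc) -> L (abc)\n"
        "d2\tL (abc) -> L.x (abc)\n"
        "d3\tL.x (abc) <-> L (abc)\n"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def breast_setup():
    """Default breast network with a realistic ground-truth flux vector."""
    from lactoflux.network import default_breast_network
    from lactoflux.synth import load_default_fragments, sample_ground_truth_fluxes

    model = default_breast_network()
    anchors = {"GLC": -337, "LAC": 603, "GLN": -44, "ALA": 10, "ASP": 3.5, "GLU": 8.5}
    truth = sample_ground_truth_fluxes(
        model, anchors, mu=0.021, seed=4,
        exchange={"v9": 50.0, "v17": 5.0, "v26": 20.0, "v38": 5.0},
    )
    frs = load_default_fragments()
    return model, truth, frs
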