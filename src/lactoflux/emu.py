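"""Steady-state isotopomer simulation via the EMU framework.

An elementary metabolite unit (EMU) is a specific subset of a metabolite's
backbone carbons.  Backward tracing from the measured fragments through the
reaction atom maps yields the minimal EMU set; EMUs are grouped by size and
each size block is one linear system A X = B whose right-hand side collects
tracer-substrate EMUs and convolutions of smaller EMUs (condensation
reactions).  Reversible reactions contribute forward flux net + exchange and
backward flux exchange; dilution-exchange reactions carry equal flux in both
directions.  Symmetric molecules are handled by equally weighted atom-map
variants, which split the reaction flux across the variants.

A brute-force full-isotopomer solver (`brute_force_isotopomer`) provides an
independent correctness oracle for small networks (<= 16 total backbone
carbons).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .network import NetworkModel, Reaction

__all__ = [
    "TracerSpec",
    "EMU",
    "EMUSystem",
    "decompose_emus",
    "substrate_mid",
    "simulate_mids",
    "brute_force_isotopomer",
    "SingularBlockError",
]

C13_NATURAL = 0.0107


class SingularBlockError(RuntimeError):
    """An EMU block is singular at the supplied flux vector."""


@dataclass(frozen=True)
class TracerSpec:
    """Labeling pattern and molar enrichment of one substrate species.

    ``pattern`` lists the 1-based labeled carbon positions ("U" = all carbons);
    ``enrichment`` is the molar fraction of the labeled species; the remainder
    is strictly unlabeled by default, or carries natural 13C abundance when
    ``natural_remainder`` is set.
    """

    substrate: str
    pattern: tuple[int, ...] | str
    enrichment: float
    natural_remainder: bool = False

    def __post_init__(self):
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")

    def positions(self, n_carbons: int) -> frozenset[int]:
        if self.pattern == "U":
            return frozenset(range(1, n_carbons + 1))
        pos = frozenset(self.pattern)
        if pos and (min(pos) < 1 or max(pos) > n_carbons):
            raise ValueError(f"pattern positions outside 1..{n_carbons}")
        return pos


# An EMU is identified by (metabolite, sorted tuple of 1-based atom positions).
EMU = tuple[str, tuple[int, ...]]


@dataclass(frozen=True)
class _Uni:
    """One unidirectional atom-map variant of a reaction."""

    rxn_index: int
    forward: bool
    weight: float  # 1/n_variants
    substrates: tuple[tuple[str, str, float], ...]  # (met, map or "", coeff)
    products: tuple[tuple[str, str], ...]  # mapped products only


def _expand_unidirectional(model: NetworkModel) -> list[_Uni]:
    unis: list[_Uni] = []
    for j, r in enumerate(model.reactions):
        combos = _variant_combos(r)
        w = 1.0 / len(combos)
        for sub_maps, prod_maps in combos:
            subs = tuple(
                (t.met, sub_maps.get(i, ""), t.coeff) for i, t in enumerate(r.substrates)
            )
            prods = tuple(
                (t.met, prod_maps[i]) for i, t in enumerate(r.products) if i in prod_maps
            )
            unis.append(_Uni(j, True, w, subs, prods))
            if r.reversible:
                rsubs = tuple(
                    (t.met, prod_maps.get(i, ""), t.coeff) for i, t in enumerate(r.products)
                )
                rprods = tuple(
                    (t.met, sub_maps[i]) for i, t in enumerate(r.substrates) if i in sub_maps
                )
                unis.append(_Uni(j, False, w, rsubs, rprods))
    return unis


def _variant_combos(r: Reaction):
    """Cartesian product of atom-map variants over all mapped terms."""
    sub_opts = [t.maps if t.mapped else ("",) for t in r.substrates]
    prod_opts = [t.maps if t.mapped else ("",) for t in r.products]
    combos = []
    for svar in itertools.product(*sub_opts):
        for pvar in itertools.product(*prod_opts):
            smap = {i: m for i, m in enumerate(svar) if m}
            pmap = {i: m for i, m in enumerate(pvar) if m}
            combos.append((smap, pmap))
    return combos


def _uni_flux_values(model: NetworkModel, unis: list[_Uni], net, exchange) -> np.ndarray:
    """Flux carried by each unidirectional variant reaction."""
    vals = np.empty(len(unis))
    for k, u in enumerate(unis):
        r = model.reactions[u.rxn_index]
        v = net.get(r.id, 0.0)
        e = exchange.get(r.id, 0.0)
        if r.kind == "dilution-exchange":
            f = b = e
        elif r.reversible:
            f = max(v, 0.0) + e
            b = max(-v, 0.0) + e
        else:
            f, b = v, 0.0
        vals[k] = u.weight * (f if u.forward else b)
    return vals


@dataclass
class EMUSystem:
    """Precompiled EMU decomposition for one set of target fragments.

    ``blocks`` maps EMU size -> (emu list, balance structure); every block
    depends only on smaller blocks and on input-substrate EMUs.
    """

    model: NetworkModel
    unis: list[_Uni]
    targets: dict[str, EMU]  # fragment_id -> EMU
    sizes: list[int]
    internal: dict[int, list[EMU]]  # size -> ordered internal EMUs
    # per size: list of (row, uni_index, [source refs]); a source ref is
    # ("emu", EMU) or ("input", met, atoms)
    productions: dict[int, list[tuple[int, int, list[tuple]]]]
    consumption: dict[str, list[tuple[int, float]]]  # met -> [(uni_index, coeff)]

    @property
    def n_emus(self) -> int:
        return sum(len(v) for v in self.internal.values())


def decompose_emus(model: NetworkModel, targets: dict[str, tuple[str, tuple[int, ...]]]) -> EMUSystem:
    """Minimal EMU system generated by backward trace from target fragments.

    ``targets`` maps fragment_id -> (metabolite, carbon positions).  Ordering
    is deterministic (lexicographic by metabolite then atom set within each
    size block).
    """
    unis = _expand_unidirectional(model)

    target_emus: dict[str, EMU] = {}
    for fid, (met, atoms) in targets.items():
        if met not in model.metabolites:
            raise KeyError(f"target metabolite {met!r} not in model")
        nc = model.metabolites[met].n_carbons
        atoms = tuple(sorted(atoms))
        if not atoms or min(atoms) < 1 or max(atoms) > nc:
            raise ValueError(f"{fid}: atoms {atoms} outside 1..{nc} of {met}")
        target_emus[fid] = (met, atoms)

    def is_input(met: str) -> bool:
        m = model.metabolites[met]
        return not m.balanced and not m.is_sink

    # consumption bookkeeping (whole-molecule, includes drains)
    consumption: dict[str, list[tuple[int, float]]] = {}
    for k, u in enumerate(unis):
        for met, _amap, coeff in u.substrates:
            consumption.setdefault(met, []).append((k, coeff))

    contribs: dict[EMU, list[tuple[int, list[tuple]]]] = {}
    queue = [e for e in target_emus.values() if not is_input(e[0])]
    seen: set[EMU] = set(queue)
    while queue:
        emu = queue.pop()
        met, atoms = emu
        entries: list[tuple[int, list[tuple]]] = []
        for k, u in enumerate(unis):
            for pmet, pmap in u.products:
                if pmet != met:
                    continue
                letters = [pmap[i - 1] for i in atoms]
                sources: list[tuple] = []
                remaining = set(letters)
                for smet, smap, _coeff in u.substrates:
                    if not smap:
                        continue
                    pos = tuple(
                        sorted(i + 1 for i, ch in enumerate(smap) if ch in remaining)
                    )
                    if not pos:
                        continue
                    remaining -= {smap[i - 1] for i in pos}
                    if is_input(smet):
                        sources.append(("input", smet, pos))
                    else:
                        src = (smet, pos)
                        sources.append(("emu", src))
                        if src not in seen:
                            seen.add(src)
                            queue.append(src)
                if remaining:
                    raise ValueError(
                        f"reaction {model.reactions[u.rxn_index].id}: product atoms "
                        f"{sorted(remaining)} of {met} have no substrate origin"
                    )
                entries.append((k, sources))
        if not entries:
            raise ValueError(f"EMU {emu} has no producing reactions")
        contribs[emu] = entries

    internal: dict[int, list[EMU]] = {}
    for emu in sorted(contribs, key=lambda e: (len(e[1]), e[0], e[1])):
        internal.setdefault(len(emu[1]), []).append(emu)
    sizes = sorted(internal)

    productions: dict[int, list[tuple[int, int, list[tuple]]]] = {}
    for size in sizes:
        rows = []
        for row, emu in enumerate(internal[size]):
            for k, sources in contribs[emu]:
                rows.append((row, k, sources))
        productions[size] = rows

    return EMUSystem(
        model=model,
        unis=unis,
        targets=target_emus,
        sizes=sizes,
        internal=internal,
        productions=productions,
        consumption=consumption,
    )


def substrate_mid(
    specs: list[TracerSpec], atoms: tuple[int, ...], n_carbons: int
) -> np.ndarray:
    """Mixture MID of a substrate EMU given the tracer species feeding it.

    Enrichments of the listed species must sum to <= 1; the remainder is the
    unlabeled (or natural-abundance) species.
    """
    total = sum(s.enrichment for s in specs)
    if total > 1.0 + 1e-12:
        raise ValueError("tracer enrichments for one substrate exceed 1")
    n = len(atoms)
    mid = np.zeros(n + 1)
    natural = any(s.natural_remainder for s in specs)
    for s in specs:
        k = len(s.positions(n_carbons) & set(atoms))
        mid[k] += s.enrichment
    remainder = 1.0 - total
    if remainder > 0:
        if natural:
            base = np.array([1.0])
            for _ in range(n):
                base = np.convolve(base, [1 - C13_NATURAL, C13_NATURAL])
            mid += remainder * base
        else:
            mid[0] += remainder
    return mid


def _input_mid(
    model: NetworkModel, tracers: dict[str, list[TracerSpec]], met: str, atoms: tuple[int, ...]
) -> np.ndarray:
    specs = tracers.get(met, [])
    return substrate_mid(specs, atoms, model.metabolites[met].n_carbons)


def simulate_mids(
    model: NetworkModel,
    net: dict[str, float],
    exchange: dict[str, float],
    tracers: dict[str, list[TracerSpec]],
    targets: dict[str, tuple[str, tuple[int, ...]]],
    system: EMUSystem | None = None,
    check_steady_state: bool = True,
    ss_tol: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Steady-state MIDs of the target fragments at the given flux vector.

    ``tracers`` maps extracellular substrate name -> list of TracerSpec; any
    input metabolite not listed (including CO2) is strictly unlabeled.
    Returns fragment_id -> probability vector of length ``len(atoms) + 1``.
    """
    if system is None:
        system = decompose_emus(model, targets)
    if check_steady_state:
        _check_steady_state(model, net, ss_tol)
    fluxes = _uni_flux_values(model, system.unis, net, exchange)
    solved: dict[EMU, np.ndarray] = {}

    def source_vec(sources: list[tuple]) -> np.ndarray:
        vec = None
        for s in sources:
            v = (
                _input_mid(model, tracers, s[1], s[2])
                if s[0] == "input"
                else solved[s[1]]
            )
            vec = v if vec is None else np.convolve(vec, v)
        return vec

    for size in system.sizes:
        emus = system.internal[size]
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        index = {e: i for i, e in enumerate(emus)}
        dead = np.zeros(n, dtype=bool)
        for i, emu in enumerate(emus):
            denom = sum(c * fluxes[k] for k, c in system.consumption.get(emu[0], []))
            A[i, i] = -denom
            dead[i] = denom == 0.0
        for row, k, sources in system.productions[size]:
            f = fluxes[k]
            if f == 0.0:
                continue
            if len(sources) == 1 and sources[0][0] == "emu" and len(sources[0][1][1]) == size:
                A[row, index[sources[0][1]]] += f
            else:
                B[row] -= f * source_vec(sources)
        # pools untouched by the flux vector (zero production and consumption,
        # e.g. a closed pathway branch) are pinned to unlabeled: they feed
        # nothing, but the block must stay nonsingular
        for i in np.where(dead)[0]:
            A[i, :] = 0.0
            A[i, i] = -1.0
            B[i, :] = 0.0
            B[i, 0] = -1.0
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as err:
            raise SingularBlockError(
                f"EMU block of size {size} is singular at the given fluxes"
            ) from err
        if not np.all(np.isfinite(X)):
            raise SingularBlockError(f"EMU block of size {size} produced non-finite MIDs")
        for i, emu in enumerate(emus):
            solved[emu] = X[i]

    out = {}
    for fid, emu in system.targets.items():
        met, atoms = emu
        if not model.metabolites[met].balanced:
            out[fid] = _input_mid(model, tracers, met, atoms)
        else:
            out[fid] = solved[emu]
    return out


def _check_steady_state(model: NetworkModel, net: dict[str, float], tol: float) -> None:
    from .network import stoichiometric_matrix

    S, _mets = stoichiometric_matrix(model)
    v = np.array([net.get(r.id, 0.0) for r in model.reactions])
    resid = S @ v
    scale = max(1.0, float(np.max(np.abs(v))))
    if np.max(np.abs(resid)) > tol * scale:
        raise ValueError(
            f"flux vector violates steady state (max residual {np.max(np.abs(resid)):.3g})"
        )


# ---------------------------------------------------------------------------
# brute-force full isotopomer oracle
# ---------------------------------------------------------------------------


def brute_force_isotopomer(
    model: NetworkModel,
    net: dict[str, float],
    exchange: dict[str, float],
    tracers: dict[str, list[TracerSpec]],
    targets: dict[str, tuple[str, tuple[int, ...]]],
    max_carbons: int = 16,
    tol: float = 1e-14,
    max_iter: int = 200_000,
) -> dict[str, np.ndarray]:
    """Exact full-isotopomer reference solution for small networks.

    Solves the complete 2^n isotopomer balance for every balanced metabolite by
    fixed-point iteration (condensation reactions make the system bilinear).
    Intended as a verification oracle for :func:`simulate_mids`; refuses
    networks with more than ``max_carbons`` total backbone carbons.
    """
    balanced = [
        m for m in model.metabolites.values() if m.balanced and m.n_carbons > 0
    ]
    total_c = sum(m.n_carbons for m in balanced)
    if total_c > max_carbons:
        raise ValueError(
            f"network has {total_c} balanced backbone carbons; brute force limited to {max_carbons}"
        )
    unis = _expand_unidirectional(model)
    fluxes = _uni_flux_values(model, unis, net, exchange)

    def is_input(met: str) -> bool:
        mm = model.metabolites[met]
        return not mm.balanced and not mm.is_sink

    def input_iso(met: str) -> np.ndarray:
        nc = model.metabolites[met].n_carbons
        specs = tracers.get(met, [])
        dist = np.zeros(2**nc)
        total = sum(s.enrichment for s in specs)
        natural = any(s.natural_remainder for s in specs)
        for s in specs:
            idx = 0
            for p in s.positions(nc):
                idx |= 1 << (p - 1)
            dist[idx] += s.enrichment
        rem = 1.0 - total
        if rem > 0:
            if natural:
                base = np.zeros(2**nc)
                for state in range(2**nc):
                    k = bin(state).count("1")
                    base[state] = (C13_NATURAL**k) * ((1 - C13_NATURAL) ** (nc - k))
                dist += rem * base
            else:
                dist[0] += rem
        return dist

    # consumption denominators
    denom = {m.name: 0.0 for m in balanced}
    for k, u in enumerate(unis):
        for met, _amap, coeff in u.substrates:
            if met in denom:
                denom[met] += coeff * fluxes[k]

    # production machinery: for each uni and mapped balanced product,
    # precompute joint-state -> product-state index map over mapped substrates
    prods: dict[str, list[tuple[float, int, list, np.ndarray]]] = {m.name: [] for m in balanced}
    for k, u in enumerate(unis):
        if fluxes[k] == 0.0:
            continue
        mapped_subs = [(met, amap) for met, amap, _c in u.substrates if amap]
        sub_bits = [len(amap) for _m, amap in mapped_subs]
        # letter -> (substrate index, bit position)
        origin = {}
        offset = 0
        for si, (_met, amap) in enumerate(mapped_subs):
            for bi, ch in enumerate(amap):
                origin[ch] = offset + bi
            offset += len(amap)
        joint_n = offset
        for pmet, pmap in u.products:
            if pmet not in denom:
                continue
            idx_map = np.zeros(2**joint_n, dtype=np.int64)
            for state in range(2**joint_n):
                out_state = 0
                for bi, ch in enumerate(pmap):
                    if (state >> origin[ch]) & 1:
                        out_state |= 1 << bi
                idx_map[state] = out_state
            prods[pmet].append((fluxes[k], 2 ** len(pmap), mapped_subs, idx_map))

    # fixed-point iteration from unlabeled pools
    iso = {m.name: np.zeros(2**m.n_carbons) for m in balanced}
    for m in balanced:
        iso[m.name][0] = 1.0
    input_cache = {}

    def pool_dist(met: str) -> np.ndarray:
        if met in iso:
            return iso[met]
        if met not in input_cache:
            input_cache[met] = input_iso(met)
        return input_cache[met]

    for _ in range(max_iter):
        delta = 0.0
        for m in balanced:
            if denom[m.name] == 0.0:
                continue  # untouched pool, stays unlabeled
            acc = np.zeros_like(iso[m.name])
            for f, nstates, mapped_subs, idx_map in prods[m.name]:
                joint = _joint_distribution([pool_dist(smet) for smet, _a in mapped_subs])
                acc += f * np.bincount(idx_map, weights=joint, minlength=nstates)
            new = acc / denom[m.name]
            delta = max(delta, float(np.max(np.abs(new - iso[m.name]))))
            iso[m.name] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("brute-force fixed point did not converge")

    out = {}
    for fid, (met, atoms) in targets.items():
        atoms = tuple(sorted(atoms))
        if is_input(met):
            out[fid] = substrate_mid(
                tracers.get(met, []), atoms, model.metabolites[met].n_carbons
            )
            continue
        dist = iso[met]
        nc = model.metabolites[met].n_carbons
        mid = np.zeros(len(atoms) + 1)
        for state in range(2**nc):
            k = sum(1 for p in atoms if (state >> (p - 1)) & 1)
            mid[k] += dist[state]
        out[fid] = mid
    return out


def _joint_distribution(dists: list[np.ndarray]) -> np.ndarray:
    """Joint independent distribution; substrate 0 occupies the low-order bits."""
    joint = np.array([1.0])
    for d in dists:
        joint = (joint[None, :] * d[:, None]).ravel()
    return joint
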