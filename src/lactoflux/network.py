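"""Carbon-mapped metabolic network model.

A :class:`NetworkModel` is the object every other analysis stage consumes: an
ordered list of reactions whose substrates and products carry per-carbon atom
maps, plus metabolite metadata (carbon count, compartment, whether the species
is balanced at steady state, whether it is a biomass sink).

The network file dialect is a tab-separated, Metran/13CFLUX-style text format:

    # comment
    @unbalanced GLC.x LAC.x CO2
    @sink Biomass
    @dilution v38
    v1\tGLC.x (abcdef) -> G6P (abcdef)
    v9\tPYR (abc) <-> LAC (abc)
    v19\tSUC (abcd) <-> FUM (abcd|dcba)

``<->`` marks reversible reactions, ``coeff*name`` gives a stoichiometric
coefficient (default 1), atom maps are lowercase letters locally scoped to the
reaction, and ``|`` separates equally weighted atom-map variants used for
rotationally symmetric molecules.  Terms may omit the atom map, in which case
the metabolite is treated as a lumped, carbon-free bookkeeping pool.
Compartments are derived from name suffixes: ``.m`` mitochondria, ``.c``
cytosol, ``.x`` extracellular, otherwise a lumped single pool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

__all__ = [
    "Metabolite",
    "Term",
    "Reaction",
    "NetworkModel",
    "NetworkError",
    "parse_network",
    "serialize_network",
    "stoichiometric_matrix",
    "validate_atom_balance",
    "find_orphans",
    "default_breast_network",
]


class NetworkError(ValueError):
    """Raised for malformed network files or invariant violations."""


@dataclass(frozen=True)
class Metabolite:
    name: str
    n_carbons: int
    compartment: str  # cytosol | mitochondria | extracellular | lumped
    balanced: bool
    is_sink: bool = False


@dataclass(frozen=True)
class Term:
    """One substrate or product entry of a reaction."""

    met: str
    coeff: float = 1.0
    maps: tuple[str, ...] = ()  # empty = unmapped; >1 = symmetric variants

    @property
    def mapped(self) -> bool:
        return bool(self.maps)

    @property
    def n_carbons(self) -> int:
        return len(self.maps[0]) if self.maps else 0


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[Term, ...]
    products: tuple[Term, ...]
    reversible: bool = False
    kind: str = "net"  # "net" | "dilution-exchange"

    def terms(self):
        yield from self.substrates
        yield from self.products


def _compartment(name: str) -> str:
    if name.endswith(".m"):
        return "mitochondria"
    if name.endswith(".c"):
        return "cytosol"
    if name.endswith(".x"):
        return "extracellular"
    return "lumped"


@dataclass
class NetworkModel:
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m.name for m in self.metabolites.values() if m.balanced]

    @property
    def sink_reactions(self) -> list[str]:
        """Reactions draining into biomass sink pools."""
        return [
            r.id
            for r in self.reactions
            for t in r.products
            if self.metabolites[t.met].is_sink
        ]

    @property
    def biomass_coefficients(self) -> dict[str, dict[str, float]]:
        """Precursor stoichiometry (mmol per g dry weight) of each sink drain."""
        out: dict[str, dict[str, float]] = {}
        for rid in self.sink_reactions:
            r = self.reaction(rid)
            out[rid] = {t.met: t.coeff for t in r.substrates}
        return out

    @property
    def exchange_reactions(self) -> list[str]:
        """Reactions that touch an unbalanced or sink metabolite."""
        out = []
        for r in self.reactions:
            for t in r.terms():
                m = self.metabolites[t.met]
                if not m.balanced or m.is_sink:
                    out.append(r.id)
                    break
        return out


_TERM_RE = re.compile(
    r"^\s*(?:(\d+(?:\.\d+)?)\s*\*\s*)?([A-Za-z][A-Za-z0-9_.]*)\s*(?:\(\s*([a-z]+(?:\|[a-z]+)*)\s*\))?\s*$"
)


def _parse_term(text: str, lineno: int) -> Term:
    m = _TERM_RE.match(text)
    if not m:
        raise NetworkError(f"line {lineno}: malformed term {text!r}")
    coeff = float(m.group(1)) if m.group(1) else 1.0
    maps: tuple[str, ...] = ()
    if m.group(3):
        maps = tuple(m.group(3).split("|"))
        if len({len(v) for v in maps}) != 1:
            raise NetworkError(f"line {lineno}: atom-map variants of unequal length in {text!r}")
        if coeff != 1.0:
            raise NetworkError(
                f"line {lineno}: atom-mapped term {text!r} must have unit coefficient; "
                "repeat the term instead"
            )
    return Term(m.group(2), coeff, maps)


def parse_network(text: str) -> NetworkModel:
    """Parse a network file and return a validated :class:`NetworkModel`."""
    unbalanced: set[str] = set()
    sinks: set[str] = set()
    dilution: set[str] = set()
    reactions: list[Reaction] = []
    seen_ids: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            parts = line.split()
            directive, args = parts[0], parts[1:]
            if directive == "@unbalanced":
                unbalanced.update(args)
            elif directive == "@sink":
                sinks.update(args)
            elif directive == "@dilution":
                dilution.update(args)
            else:
                raise NetworkError(f"line {lineno}: unknown directive {directive!r}")
            continue
        m = re.match(r"^(\S+)\s+(.*?)\s*(<->|->)\s*(.*)$", line)
        if not m:
            raise NetworkError(f"line {lineno}: malformed reaction line {line!r}")
        rid, lhs, arrow, rhs = m.groups()
        if rid in seen_ids:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        seen_ids.add(rid)
        subs = tuple(_parse_term(t, lineno) for t in lhs.split("+"))
        prods = tuple(_parse_term(t, lineno) for t in rhs.split("+"))
        reactions.append(
            Reaction(rid, subs, prods, reversible=(arrow == "<->"), kind="net")
        )

    reactions = [
        replace(r, kind="dilution-exchange", reversible=True) if r.id in dilution else r
        for r in reactions
    ]
    missing = dilution - seen_ids
    if missing:
        raise NetworkError(f"@dilution names unknown reactions: {sorted(missing)}")

    # metabolite table: carbon counts must agree across reactions
    n_carbons: dict[str, int] = {}
    for r in reactions:
        for t in r.terms():
            if t.mapped:
                prev = n_carbons.get(t.met)
                if prev is not None and prev != t.n_carbons:
                    raise NetworkError(
                        f"reaction {r.id}: {t.met} has {t.n_carbons} carbons here "
                        f"but {prev} elsewhere"
                    )
                n_carbons[t.met] = t.n_carbons
            else:
                n_carbons.setdefault(t.met, 0)

    metabolites = {
        name: Metabolite(
            name=name,
            n_carbons=nc,
            compartment=_compartment(name),
            balanced=(name not in unbalanced and name not in sinks),
            is_sink=(name in sinks),
        )
        for name, nc in n_carbons.items()
    }
    model = NetworkModel(metabolites=metabolites, reactions=reactions)

    violations = validate_atom_balance(model)
    if violations:
        raise NetworkError("atom balance violations: " + "; ".join(violations))
    return model


def serialize_network(model: NetworkModel) -> str:
    """Serialize a model to the network-file dialect (parse/serialize round-trips)."""
    lines = []
    unbalanced = [m.name for m in model.metabolites.values() if not m.balanced and not m.is_sink]
    sinks = [m.name for m in model.metabolites.values() if m.is_sink]
    dilution = [r.id for r in model.reactions if r.kind == "dilution-exchange"]
    if unbalanced:
        lines.append("@unbalanced " + " ".join(unbalanced))
    if sinks:
        lines.append("@sink " + " ".join(sinks))
    if dilution:
        lines.append("@dilution " + " ".join(dilution))

    def fmt_term(t: Term) -> str:
        coeff = "" if t.coeff == 1.0 else f"{t.coeff:g}*"
        amap = f" ({'|'.join(t.maps)})" if t.maps else ""
        return f"{coeff}{t.met}{amap}"

    for r in model.reactions:
        arrow = "<->" if r.reversible else "->"
        lhs = " + ".join(fmt_term(t) for t in r.substrates)
        rhs = " + ".join(fmt_term(t) for t in r.products)
        lines.append(f"{r.id}\t{lhs} {arrow} {rhs}")
    return "\n".join(lines) + "\n"


def validate_atom_balance(model: NetworkModel) -> list[str]:
    """Report carbon-conservation violations (empty list = all balanced).

    A reaction is checked when every carbon-bearing term on both sides carries
    an atom map; lumped/drain reactions with unmapped carbon terms are exempt.
    Every atom-map variant combination must conserve the multiset of letters.
    """
    violations = []
    for r in model.reactions:
        terms = list(r.terms())
        if any(not t.mapped and model.metabolites[t.met].n_carbons > 0 for t in terms):
            continue  # lumped/drain reaction
        if not any(t.mapped for t in terms):
            continue  # pure bookkeeping reaction
        sub_letters = _letter_multisets(r.substrates)
        prod_letters = _letter_multisets(r.products)
        if sub_letters != prod_letters:
            viol = False
            # each substrate variant multiset must appear among product multisets
            if len(sub_letters) == 1 and len(prod_letters) == 1:
                viol = True
            else:
                viol = sub_letters != prod_letters
            if viol:
                violations.append(
                    f"{r.id}: substrate atoms {sorted(sub_letters)} != product atoms "
                    f"{sorted(prod_letters)}"
                )
    return violations


def _letter_multisets(terms: tuple[Term, ...]) -> set[tuple[str, ...]]:
    """Set of sorted letter multisets over all variant combinations of one side."""
    combos = [()]
    for t in terms:
        if not t.mapped:
            continue
        combos = [c + (v,) for c in combos for v in t.maps]
    return {tuple(sorted("".join(c))) for c in combos}


def find_orphans(model: NetworkModel) -> list[str]:
    """Balanced metabolites that are produced but never consumed (dead ends)."""
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        for t in r.substrates:
            consumed.add(t.met)
            if r.reversible:
                produced.add(t.met)
        for t in r.products:
            produced.add(t.met)
            if r.reversible:
                consumed.add(t.met)
    return [
        m.name
        for m in model.metabolites.values()
        if m.balanced and not m.is_sink and m.name in produced and m.name not in consumed
    ]


def stoichiometric_matrix(model: NetworkModel) -> tuple[np.ndarray, list[str]]:
    """Stoichiometric matrix over balanced metabolites.

    Returns ``(S, metabolite_order)`` with ``S[i, j]`` the net coefficient of
    balanced metabolite i in reaction j.  Dilution-exchange reactions carry no
    net material and contribute zero columns.
    """
    mets = model.balanced_metabolites
    idx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        if r.kind == "dilution-exchange":
            continue
        for t in r.substrates:
            if t.met in idx:
                S[idx[t.met], j] -= t.coeff
        for t in r.products:
            if t.met in idx:
                S[idx[t.met], j] += t.coeff
    return S, mets


def default_breast_network() -> NetworkModel:
    """The default 38-reaction breast cell central-carbon model."""
    text = resources.files("lactoflux.data").joinpath("breast_network.txt").read_text()
    return parse_network(text)
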