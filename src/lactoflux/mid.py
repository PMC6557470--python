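"""GC-MS mass isotopomer distribution (MID) processing.

Raw single-ion MIDs are corrected for the natural isotope abundance of every
atom in the detected ion *except* the backbone carbons whose labeling is being
estimated; tracer-derived labeling of those carbons is what remains.  The
correction solves a non-negatively constrained least-squares inversion of the
banded convolution matrix, which is robust to noisy, truncated raw vectors
(a plain matrix inverse can return negative fractions).

Replicate MIDs are pooled to a mean vector with per-mass sample SDs; SDs below
a minimum error floor (default 0.6 mol%) are raised to the floor, which also
covers single-replicate measurements with undefined SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .isotopes import mass_shift_distribution, parse_formula

__all__ = [
    "FragmentSpec",
    "MIDVector",
    "correction_matrix",
    "correct_natural_abundance",
    "pool_replicates",
    "apply_error_floor",
    "percent_labeling",
]

DEFAULT_ERROR_FLOOR = 0.6  # mol%


@dataclass(frozen=True)
class FragmentSpec:
    fragment_id: str
    metabolite: str
    carbon_atoms: tuple[int, ...]  # 1-based backbone positions covered
    formula: str  # elemental composition of the detected ion

    def __post_init__(self):
        if not self.carbon_atoms:
            raise ValueError("carbon_atoms must be non-empty")
        counts = parse_formula(self.formula)
        if counts.get("C", 0) < len(self.carbon_atoms):
            raise ValueError(
                f"{self.fragment_id}: ion formula has fewer carbons than the backbone range"
            )

    @property
    def n_carbons(self) -> int:
        return len(self.carbon_atoms)


@dataclass(frozen=True)
class MIDVector:
    fragment_id: str
    values: np.ndarray  # mass fractions M0..Mn
    sds: np.ndarray | None = None  # per-mass SD, mol% units when stated
    state: str = "raw"  # "raw" | "corrected"
    tracer: str = ""
    n_replicates: int = 1

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sds is not None:
            object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))


def correction_matrix(formula: str, backbone_carbons: int, max_extra: int = 8) -> np.ndarray:
    """Natural-abundance convolution matrix for one fragment ion.

    Maps a backbone-carbon MID (length ``backbone_carbons + 1``) to the
    observed mass distribution.  Built from the natural isotope abundances of
    every formula atom except the ``backbone_carbons`` backbone carbons; each
    column is the same mass-shift distribution shifted by the backbone mass.
    Columns sum to <= 1 (mass beyond the retained window is truncated).
    """
    counts = parse_formula(formula)
    if counts.get("C", 0) < backbone_carbons:
        raise ValueError("formula carbon count below backbone carbon count")
    counts = dict(counts)
    counts["C"] = counts.get("C", 0) - backbone_carbons
    shift = mass_shift_distribution(counts, max_shift=max_extra)
    n_rows = backbone_carbons + 1 + max_extra
    M = np.zeros((n_rows, backbone_carbons + 1))
    for j in range(backbone_carbons + 1):
        M[j : j + len(shift), j] = shift
    return M


def correct_natural_abundance(raw: MIDVector, spec: FragmentSpec) -> MIDVector:
    """Correct a raw MID for natural isotope abundance.

    Solves ``min ||M x - raw||`` subject to ``x >= 0`` and renormalizes to unit
    sum; SDs are propagated through the unconstrained linear solution map.
    """
    if raw.state == "corrected":
        return raw
    y = np.asarray(raw.values, dtype=float)
    if np.all(y == 0):
        raise ValueError(f"{raw.fragment_id}: all-zero raw MID")
    n = spec.n_carbons
    if len(y) < n + 1:
        raise ValueError(f"{raw.fragment_id}: raw vector shorter than backbone carbons + 1")
    M = correction_matrix(spec.formula, n)
    rows = min(len(y), M.shape[0])
    Mt, yt = M[:rows], y[:rows]
    x, _ = nnls(Mt, yt)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{raw.fragment_id}: degenerate correction (zero mass)")
    sds = None
    if raw.sds is not None:
        P = np.linalg.pinv(Mt)
        var = (P**2) @ (np.asarray(raw.sds[:rows], dtype=float) ** 2)
        sds = np.sqrt(var) / total
    return MIDVector(
        fragment_id=raw.fragment_id,
        values=x / total,
        sds=sds,
        state="corrected",
        tracer=raw.tracer,
        n_replicates=raw.n_replicates,
    )


def pool_replicates(replicates: list[MIDVector]) -> MIDVector:
    """Mean MID over biological replicates with per-mass sample SDs (n-1).

    A single replicate yields undefined SDs (NaN), flagged for the error floor.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    lengths = {len(r.values) for r in replicates}
    if len(lengths) != 1:
        raise ValueError("replicate MIDs have mismatched lengths")
    states = {r.state for r in replicates}
    if len(states) != 1:
        raise ValueError("cannot pool raw with corrected replicates")
    vals = np.stack([r.values for r in replicates])
    mean = vals.mean(axis=0)
    n = len(replicates)
    sds = vals.std(axis=0, ddof=1) if n > 1 else np.full(vals.shape[1], np.nan)
    first = replicates[0]
    return MIDVector(
        fragment_id=first.fragment_id,
        values=mean,
        sds=sds,
        state=first.state,
        tracer=first.tracer,
        n_replicates=n,
    )


def apply_error_floor(sds, floor: float = DEFAULT_ERROR_FLOOR, scale: float = 100.0):
    """Raise per-mass SDs to at least ``floor`` (mol%); NaN SDs become the floor.

    ``scale`` converts the SD units to mol% (100 when SDs are mass fractions).
    Idempotent and monotone.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    s = np.asarray(sds, dtype=float) * scale
    s = np.where(np.isnan(s), floor, np.maximum(s, floor))
    return s / scale


def percent_labeling(mid: MIDVector) -> float:
    """Percent isotopomer labeling, 100 * (1 - M0), of a corrected MID."""
    if mid.state != "corrected":
        raise ValueError("percent labeling requires a corrected MID")
    return 100.0 * (1.0 - float(mid.values[0]))
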