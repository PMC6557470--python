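"""Natural isotope abundances and elemental formula handling.

Abundances are IUPAC 2021 representative values.  Each entry lists the
fractional abundance of the M+0, M+1, ... mass isotopes of the element
(mass shifts relative to the lightest stable isotope).
"""

from __future__ import annotations

import re

import numpy as np

NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0001),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula such as ``C11H25O3Si2`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        if not m.group(0):
            break
        el = m.group(1)
        if el not in NATURAL_ABUNDANCE:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def mass_shift_distribution(counts: dict[str, int], max_shift: int | None = None) -> np.ndarray:
    """Probability distribution of the total isotopic mass shift of a set of atoms.

    Convolves the per-atom natural-abundance distributions of every atom in
    ``counts``.  Truncated to ``max_shift`` + 1 entries when given.
    """
    dist = np.array([1.0])
    for el, n in counts.items():
        if n < 0:
            raise ValueError(f"negative atom count for {el}")
        base = np.asarray(NATURAL_ABUNDANCE[el])
        for _ in range(n):
            dist = np.convolve(dist, base)
            if max_shift is not None and len(dist) > max_shift + 1:
                dist = dist[: max_shift + 1]
    if max_shift is not None and len(dist) < max_shift + 1:
        dist = np.pad(dist, (0, max_shift + 1 - len(dist)))
    return dist
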