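"""Elemental-formula arithmetic for negative-mode LC-MS annotation.

Monoisotopic masses, anion m/z under the ``[M-H]-`` / ``[M+Cl]-`` adduct
conventions, ppm errors, ring-double-bond equivalents, and bounded
enumeration of CHO(NS) formulas within a mass tolerance.

The anion m/z convention used throughout is *electron-inclusive*: a singly
charged anion carries one extra electron, so

    m/z([M-H]-)  = M - m(H) + m(e-)       = M - 1.00727646
    m/z([M+Cl]-) = M + m(35Cl) + m(e-)    = M + 34.96940126

This bookkeeping matters at the fourth decimal and is what reproduces
reference theoretical values such as geniposide [M+Cl]- = 423.1063.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "ElementalFormula",
    "AdductSpec",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "anion_mz",
    "ppm_error",
    "rdbe",
    "enumerate_formulas",
]

# Monoisotopic atomic masses, Da (CODATA/IUPAC). Fixed constants: annotation
# must not depend on whichever periodic-table library happens to be around.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "Cl": 34.96885268,
}
ELECTRON_MASS = 0.00054858
PROTON_MASS = 1.00727646

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count map with monoisotopic-mass semantics.

    Supports element-wise addition and subtraction; subtraction that would
    drive any count negative raises ``ValueError`` (a fragment cannot contain
    atoms its precursor lacks).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                clean[el] = int(n)
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(clean))

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count: {self} - {other}"
                )
        return ElementalFormula(merged)

    def contains(self, other: "ElementalFormula") -> bool:
        """True if ``other`` fits element-wise inside this formula."""
        return all(self[el] >= n for el, n in other.counts.items())

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:
        # Hill-ish order: C, H, then remaining alphabetically.
        order = ["C", "H"] + sorted(set(self.counts) - {"C", "H"})
        parts = []
        for el in order:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


@dataclass(frozen=True)
class AdductSpec:
    """Negative-mode adduct: name, mass offset from the neutral, charge -1."""

    name: str
    mass_delta: float
    charge: int = -1


ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS),
    "[M+Cl]-": AdductSpec("[M+Cl]-", MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS),
}


def _resolve_adduct(adduct: str | AdductSpec) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; expected one of {sorted(ADDUCTS)}"
        ) from None


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``"C17H24O10"`` or the underscore dialect ``"C_17_H_24_O_10_"``.

    An omitted count means 1 (``"CH4"`` -> C1 H4).
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    s = text.strip().replace("_", "")
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(s):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(s):
        raise ValueError(f"cannot parse formula {text!r} at {s[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | str) -> float:
    """Sum of count x monoisotopic atomic mass over the formula, in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts.items())


def adduct_mz(f: ElementalFormula | str, adduct: str | AdductSpec) -> float:
    """Theoretical m/z of the neutral ``f`` observed as the given anion."""
    spec = _resolve_adduct(adduct)
    return monoisotopic_mass(f) + spec.mass_delta


def anion_mz(f: ElementalFormula | str) -> float:
    """m/z of an anion whose elemental composition is given *explicitly*.

    ``f`` here is the ion's own atom count (e.g. C16H23O11 for the shanzhiside
    [M-H]- ion); the charge-carrying electron's mass is added.
    """
    return monoisotopic_mass(f) + ELECTRON_MASS


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative error, (measured - theoretical)/theoretical x 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (measured - theoretical) / theoretical * 1e6


def rdbe(f: ElementalFormula | str) -> float:
    """Ring-and-double-bond equivalents, C - H/2 + N/2 + 1 (halogens count as H)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f["C"] - (f["H"] + f["Cl"]) / 2.0 + f["N"] / 2.0 + 1.0


# Default enumeration bounds: all 28 fingerprint constituents are CHO.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 100),
    "O": (0, 30),
}


def enumerate_formulas(
    target_mz: float,
    adduct: str | AdductSpec = "[M-H]-",
    tol_ppm: float = 5.0,
    bounds: Mapping[str, tuple[int, int]] | None = None,
) -> list[ElementalFormula]:
    """All CHO(NS) neutral formulas whose adduct m/z falls within ``tol_ppm``.

    Candidates must have RDBE >= 0 and integer-valued RDBE (even-electron
    species). Ranked by |ppm error|, ties broken by |RDBE - 7| (the typical
    RDBE of the compound classes handled here) and then by formula string —
    an arbitrary but deterministic order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    spec = _resolve_adduct(adduct)
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    elements = [el for el in ("C", "H", "N", "O", "S") if el in bounds]
    target_neutral = target_mz - spec.mass_delta
    tol_da = tol_ppm * 1e-6 * target_mz
    if target_neutral <= 0:
        return []

    # Vectorized grid over the (small) bounded element ranges.
    axes = [np.arange(bounds[el][0], bounds[el][1] + 1) for el in elements]
    grids = np.meshgrid(*axes, indexing="ij")
    mass = np.zeros_like(grids[0], dtype=float)
    for el, g in zip(elements, grids):
        mass = mass + MONOISOTOPIC_MASS[el] * g
    hit = np.abs(mass - target_neutral) <= tol_da
    idx = np.argwhere(hit)
    out: list[tuple[float, float, str, ElementalFormula]] = []
    for ix in idx:
        counts = {el: int(axes[j][ix[j]]) for j, el in enumerate(elements)}
        if sum(counts.values()) == 0:
            continue
        try:
            f = ElementalFormula(counts)
        except ValueError:
            continue
        r = rdbe(f)
        if r < 0 or abs(r - round(r)) > 1e-9:
            continue
        out.append((abs(ppm_error(adduct_mz(f, spec), target_mz)), abs(r - 7.0), str(f), f))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return [t[3] for t in out]
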