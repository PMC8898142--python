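"""Product-ion (MS/MS) annotation by sub-formula and neutral-loss inference.

Given a precursor whose elemental formula is known or hypothesised, fragment
ions are explained two ways:

* **sub-formula assignment** — every elemental composition that fits inside
  the precursor anion and matches the fragment m/z within tolerance;
* **loss-cascade annotation** — a breadth-first search over sequences of
  neutral losses (water, CO2, anhydroglucose, acyl residues, ...) whose
  cumulative mass connects the precursor anion to the fragment. The cascade
  a fragment receives is the shortest one that matches.

A compound library lookup combines retention time, precursor m/z and
diagnostic-fragment agreement into an identification with a confidence
level (``reference-confirmed`` > ``literature`` > ``putative``). When no
library record passes outright, the loss cascade itself is searched for a
known skeleton: a fragment whose loss path *ends* with a library compound's
reference cascade identifies that compound as the core of an acylated or
glycosylated derivative.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

from .chem_mass import (
    ADDUCTS,
    ElementalFormula,
    adduct_mz,
    anion_mz,
    enumerate_formulas,
    parse_formula,
    ppm_error,
)
from .datasets import CompoundRecord

__all__ = [
    "NeutralLoss",
    "FragmentIon",
    "ProductSpectrum",
    "AnnotationResult",
    "default_loss_library",
    "precursor_anion",
    "assign_fragment_formula",
    "annotate_cascade",
    "match_to_library",
    "DEFAULT_FRAGMENT_TOL_PPM",
    "DEFAULT_PRECURSOR_TOL_PPM",
    "DEFAULT_RT_TOL_MIN",
]

# Fragment m/z in product scans scatters more than precursor m/z does
# (observed fragment deviations reach ~10 ppm where precursors stay <=5 ppm),
# hence the asymmetric defaults.
DEFAULT_FRAGMENT_TOL_PPM = 15.0
DEFAULT_PRECURSOR_TOL_PPM = 5.0
DEFAULT_RT_TOL_MIN = 0.5
MAX_CASCADE_DEPTH = 5


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral fragment; its mass derives from its formula."""

    name: str
    formula: ElementalFormula

    @property
    def mass(self) -> float:
        return self.formula.mass


def default_loss_library() -> list[NeutralLoss]:
    """Neutral losses seen in iridoid/crocin/acylglycoside fragmentation.

    Order is fixed and acts as the deterministic tiebreak between equal-mass
    cascades. ``HCl`` covers the [M+Cl]- -> [M-H]- normalization transition.
    """
    defs = [
        ("H2O", "H2O"),
        ("CO2", "CO2"),
        ("HCl", "HCl"),
        ("glucose", "C6H10O5"),        # anhydroglucose unit, 162.0528
        ("sinapoyl", "C11H10O4"),      # 206.0579
        ("caffeoyl", "C9H6O3"),
        ("coumaroyl", "C9H6O2"),
        ("gentiobiose", "C12H20O10"),  # anhydrogentiobiose, 324.1056
        ("rutinosyl", "C12H20O9"),     # anhydrorutinose, 308.1107
    ]
    return [NeutralLoss(name, parse_formula(f)) for name, f in defs]


@dataclass
class FragmentIon:
    """One product ion; annotation fills ``assigned_formula``/``loss_path``."""

    mz: float
    intensity: float = 0.0
    assigned_formula: ElementalFormula | None = None
    loss_path: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class ProductSpectrum:
    """A product-ion spectrum: precursor (m/z, adduct) plus fragments.

    Fragments are kept sorted by descending intensity, matching the
    abundance-ordered fragment listings of reference spectra.
    """

    precursor_mz: float
    adduct: str
    fragments: list[FragmentIon] = field(default_factory=list)
    retention_time: float = 0.0
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.adduct not in ADDUCTS:
            raise ValueError(f"unsupported adduct {self.adduct!r}")
        self.fragments = sorted(self.fragments, key=lambda f: -f.intensity)


@dataclass(frozen=True)
class AnnotationResult:
    """Outcome of a library match for one spectrum."""

    spectrum_id: str
    name: str | None
    candidate_formula: ElementalFormula | None
    ppm_precursor: float | None
    matched_fragments: int
    matched_cascade: bool
    identity_level: str  # "reference-confirmed" | "literature" | "putative"
    record: CompoundRecord | None = None


def precursor_anion(formula: ElementalFormula, adduct: str) -> ElementalFormula:
    """Elemental composition of the observed precursor anion.

    [M-H]- removes one hydrogen; [M+Cl]- appends one chlorine.
    """
    if adduct == "[M-H]-":
        return formula - parse_formula("H")
    if adduct == "[M+Cl]-":
        return formula + parse_formula("Cl")
    raise ValueError(f"unsupported adduct {adduct!r}")


def assign_fragment_formula(
    frag: FragmentIon | float,
    precursor: ElementalFormula,
    adduct: str = "[M-H]-",
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> list[ElementalFormula]:
    """Rank anion compositions that fit inside the precursor for a fragment m/z.

    Candidates are element-wise sub-formulas of the precursor anion (for
    [M+Cl]- the chlorine is treated as losable, i.e. Cl count 0 or 1), with
    electron-inclusive m/z within ``tol_ppm``; ranked by absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz = frag.mz if isinstance(frag, FragmentIon) else float(frag)
    anion = precursor_anion(precursor, adduct)
    tol_da = tol_ppm * 1e-6 * mz
    hits: list[tuple[float, str, ElementalFormula]] = []
    elements = sorted(anion.counts)
    ranges = [range(anion[el] + 1) for el in elements]
    for combo in itertools.product(*ranges):
        if sum(combo) == 0:
            continue
        counts = {el: n for el, n in zip(elements, combo) if n}
        f = ElementalFormula(counts)
        theo = anion_mz(f)
        if abs(theo - mz) <= tol_da:
            hits.append((abs(ppm_error(mz, theo)), str(f), f))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [t[2] for t in hits]


def _cascade_states(
    start: ElementalFormula,
    adduct: str,
    library: Sequence[NeutralLoss],
    max_depth: int,
) -> list[tuple[tuple[str, ...], ElementalFormula]]:
    """All reachable (loss path, remaining anion formula) states, by depth.

    The cumulative composition is order-invariant, so the search runs over
    loss *multisets*; the reported path is canonically ordered with the HCl
    normalization first (only available to [M+Cl]- precursors, at most once),
    then remaining losses by descending mass — the order cascades are
    conventionally written in.
    """
    by_name = {l.name: l for l in library}
    general = [l for l in library if l.name != "HCl"]
    heads: list[tuple[tuple[str, ...], ElementalFormula]] = [((), start)]
    if adduct == "[M+Cl]-" and "HCl" in by_name:
        try:
            heads.append((("HCl",), start - by_name["HCl"].formula))
        except ValueError:
            pass
    states: list[tuple[int, int, tuple[str, ...], ElementalFormula]] = []
    order = {l.name: i for i, l in enumerate(library)}
    for head_path, head_formula in heads:
        for depth in range(max_depth - len(head_path) + 1):
            for combo in itertools.combinations_with_replacement(general, depth):
                f = head_formula
                try:
                    for loss in combo:
                        f = f - loss.formula
                except ValueError:
                    continue
                tail = sorted(combo, key=lambda l: (-l.mass, order[l.name]))
                path = head_path + tuple(l.name for l in tail)
                states.append((len(path), min((order[l.name] for l in combo), default=-1), path, f))
    states.sort(key=lambda s: (s[0], s[1], s[2]))
    return [(path, f) for _, _, path, f in states]


def annotate_cascade(
    spectrum: ProductSpectrum,
    precursor: ElementalFormula,
    library: Sequence[NeutralLoss] | None = None,
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    max_depth: int = MAX_CASCADE_DEPTH,
) -> list[FragmentIon]:
    """Explain each fragment as the precursor anion minus a loss sequence.

    Every fragment receives the *shortest* loss path whose remaining
    composition matches its m/z within ``tol_ppm``; equal-depth ties resolve
    by library order. Unexplained fragments keep ``loss_path=()`` unset
    (``None``). The zero-loss (precursor-survival) fragment is additionally
    matched against the spectrum's own measured precursor m/z, since the
    surviving precursor in the product scan is the same measured species and
    can sit further from theory than the fragment tolerance allows.
    """
    if library is None:
        library = default_loss_library()
    if not library:
        raise ValueError("loss library must be non-empty")
    start = precursor_anion(precursor, spectrum.adduct)
    states = _cascade_states(start, spectrum.adduct, library, max_depth)
    annotated: list[FragmentIon] = []
    for frag in spectrum.fragments:
        tol_da = tol_ppm * 1e-6 * frag.mz
        match: tuple[tuple[str, ...], ElementalFormula] | None = None
        for path, f in states:
            theo = anion_mz(f)
            ok = abs(theo - frag.mz) <= tol_da
            if not ok and not path:
                ok = abs(spectrum.precursor_mz - frag.mz) <= tol_da
            if ok:
                match = (path, f)
                break
        if match is None:
            annotated.append(replace(frag, loss_path=None, assigned_formula=None))
        else:
            annotated.append(replace(frag, loss_path=match[0], assigned_formula=match[1]))
    return annotated


def _diagnostic_mz(record: CompoundRecord, library: Sequence[NeutralLoss]) -> list[float]:
    """Theoretical m/z of the precursor anion and each cascade intermediate."""
    by_name = {l.name: l for l in library}
    f = precursor_anion(record.formula, record.adduct)
    out = [anion_mz(f)]
    for name in record.reference_cascade:
        f = f - by_name[name].formula
        out.append(anion_mz(f))
    return out


def match_to_library(
    spectrum: ProductSpectrum,
    records: Sequence[CompoundRecord],
    rt_tol: float = DEFAULT_RT_TOL_MIN,
    prec_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    min_fragment_hits: int = 2,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    library: Sequence[NeutralLoss] | None = None,
) -> AnnotationResult:
    """Identify a spectrum against a compound library.

    A record matches when its theoretical precursor m/z is within
    ``prec_tol_ppm``, its reference retention time within ``rt_tol`` minutes,
    and at least ``min_fragment_hits`` of its diagnostic fragments appear in
    the spectrum within ``frag_tol_ppm``. The best passing record (smallest
    precursor ppm) wins; its provenance sets the identity level. With no
    passing record, skeleton inference is attempted: the precursor formula is
    enumerated from the measured m/z, the loss cascade annotated, and any
    library cascade appearing as the tail of a fragment's loss path marks a
    putative derivative of that library compound.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if library is None:
        library = default_loss_library()

    best: tuple[float, CompoundRecord, int] | None = None
    for rec in records:
        theo = adduct_mz(rec.formula, spectrum.adduct)
        ppm = ppm_error(spectrum.precursor_mz, theo)
        if abs(ppm) > prec_tol_ppm:
            continue
        if abs(spectrum.retention_time - rec.reference_rt) > rt_tol:
            continue
        diag = _diagnostic_mz(rec, library) if rec.reference_cascade else [
            anion_mz(precursor_anion(rec.formula, rec.adduct))
        ]
        hits = 0
        for frag in spectrum.fragments:
            if any(abs(frag.mz - d) <= frag_tol_ppm * 1e-6 * d for d in diag):
                hits += 1
        if hits < min_fragment_hits:
            continue
        if best is None or abs(ppm) < abs(best[0]):
            best = (ppm, rec, hits)

    if best is not None:
        ppm, rec, hits = best
        level = "reference-confirmed" if rec.is_reference_substance else "literature"
        return AnnotationResult(
            spectrum_id=spectrum.spectrum_id,
            name=rec.name,
            candidate_formula=rec.formula,
            ppm_precursor=ppm,
            matched_fragments=hits,
            matched_cascade=bool(rec.reference_cascade),
            identity_level=level,
            record=rec,
        )

    # Skeleton inference: does some library cascade terminate a loss path?
    candidates = enumerate_formulas(
        spectrum.precursor_mz, spectrum.adduct, tol_ppm=max(2 * prec_tol_ppm, 10.0)
    )
    for cand in candidates[:3]:
        annotated = annotate_cascade(spectrum, cand, library, frag_tol_ppm)
        paths = [f.loss_path for f in annotated if f.loss_path]
        for rec in records:
            cas = rec.reference_cascade
            if not cas:
                continue
            core = cas[1:] if cas and cas[0] == "HCl" else cas
            if not core:
                continue
            for path in paths:
                if len(path) >= len(core) and tuple(path[-len(core):]) == tuple(core):
                    return AnnotationResult(
                        spectrum_id=spectrum.spectrum_id,
                        name=f"{rec.name} skeleton",
                        candidate_formula=cand,
                        ppm_precursor=ppm_error(
                            spectrum.precursor_mz, adduct_mz(cand, spectrum.adduct)
                        ),
                        matched_fragments=len(paths),
                        matched_cascade=True,
                        identity_level="putative",
                        record=rec,
                    )
    return AnnotationResult(
        spectrum_id=spectrum.spectrum_id,
        name=None,
        candidate_formula=candidates[0] if candidates else None,
        ppm_precursor=None,
        matched_fragments=0,
        matched_cascade=False,
        identity_level="putative",
    )
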