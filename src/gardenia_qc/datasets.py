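"""Packaged reference datasets.

Three small tables ship with the package:

* ``common_peaks_msms.csv`` — the 28 fingerprint constituents of Gardeniae
  Fructus with retention times, elemental formulas, compound classes,
  quasimolecular-ion records ([M-H]- and/or [M+Cl]-, measured and theoretical
  m/z, printed ppm error), abundance-ordered MS/MS fragment lists, and — for
  the reference-substance compounds — a neutral-loss cascade.
* ``calibration_lines.csv`` — the 12 external-standard regression lines
  (area = slope x ng + intercept), linear ranges, LOD/LOQ and detection
  channel per analyte.
* ``batch_contents.csv`` — measured contents (mg/g) of the 12 quantified
  components across 40 commercial decoction-piece batches, with the
  published 7-iridoid total column.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .chem_mass import ElementalFormula, parse_formula

__all__ = [
    "IRIDOID_GROUP",
    "QUANTIFIED_ANALYTES",
    "table_common_peaks",
    "table_calibration",
    "table_contents",
    "compound_library",
    "calibration_curves",
    "CompoundRecord",
]

#: The seven iridoids whose row-sum is reported as "Total of iridoids".
IRIDOID_GROUP = [
    "Geniposide",
    "Genipin gentiobioside",
    "Gardenoside",
    "Shanzhiside",
    "DAAME",
    "SME",
    "Geniposidic acid",
]

#: All 12 analytes with calibration lines, in calibration-table order.
QUANTIFIED_ANALYTES = [
    "Shanzhiside",
    "Geniposidic acid",
    "DAAME",
    "Gardenoside",
    "SME",
    "Jasminoside B",
    "Chlorogenic acid",
    "Genipin gentiobioside",
    "Geniposide",
    "Rutin",
    "Crocin I",
    "Crocin II",
]

COMPOUND_CLASSES = frozenset(
    {"iridoid", "crocin", "monocyclic monoterpenoid", "organic acid", "flavonoid"}
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("gardenia_qc.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def table_common_peaks() -> pd.DataFrame:
    """Per-adduct ion records of the 28 common peaks (33 rows)."""
    df = _read("common_peaks_msms.csv")
    df["reference_substance"] = df["reference_substance"].astype(bool)
    df["ppm_consistent"] = df["ppm_consistent"].astype(bool)
    return df


@lru_cache(maxsize=None)
def table_calibration() -> pd.DataFrame:
    return _read("calibration_lines.csv")


@lru_cache(maxsize=None)
def table_contents() -> pd.DataFrame:
    """40 batches x 12 analytes (mg/g) plus the published iridoid-total column."""
    return _read("batch_contents.csv").set_index("sample_id")


@dataclass(frozen=True)
class CompoundRecord:
    """A library compound: identity, formula, class, RT and fragmentation."""

    name: str
    formula: ElementalFormula
    compound_class: str
    reference_rt: float
    adduct: str
    reference_cascade: tuple[str, ...]
    diagnostic_mz: tuple[float, ...]
    is_reference_substance: bool
    peak_id: int
    name_collision: bool = False

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")


@lru_cache(maxsize=None)
def compound_library() -> list[CompoundRecord]:
    """One :class:`CompoundRecord` per common peak (28 records).

    For peaks observed under both adducts the record uses the adduct that
    carries the reference fragmentation cascade (falling back to the first
    listed row). Two library names are duplicated as published (peaks 1/5
    "Gardenoside", peaks 25/28 "Crocin II"); those records are flagged with
    ``name_collision`` rather than silently renamed.
    """
    df = table_common_peaks()
    records: list[CompoundRecord] = []
    dup_names = {n for n, c in df.groupby("name")["peak"].nunique().items() if c > 1}
    for peak, grp in df.groupby("peak", sort=True):
        with_cascade = grp[grp["cascade"].notna()]
        row = with_cascade.iloc[0] if len(with_cascade) else grp.iloc[0]
        cascade = tuple(str(row["cascade"]).split(";")) if pd.notna(row["cascade"]) else ()
        frags = tuple(float(x) for x in str(row["msms"]).split(";"))
        records.append(
            CompoundRecord(
                name=row["name"],
                formula=parse_formula(row["formula"]),
                compound_class=row["compound_class"],
                reference_rt=float(row["rt_min"]),
                adduct=row["adduct"],
                reference_cascade=cascade,
                diagnostic_mz=frags,
                is_reference_substance=bool(row["reference_substance"]),
                peak_id=int(peak),
                name_collision=row["name"] in dup_names,
            )
        )
    return records


def calibration_curves() -> dict[str, "CalibrationCurve"]:
    """The 12 published regression lines as CalibrationCurve objects."""
    from .quantitation import CalibrationCurve

    out = {}
    for _, r in table_calibration().iterrows():
        out[r["analyte"]] = CalibrationCurve(
            analyte=r["analyte"],
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            r_squared=float(r["r_squared"]),
            linear_range=(float(r["range_min_ng"]), float(r["range_max_ng"])),
            lod_ng=float(r["lod_ng"]),
            loq_ng=float(r["loq_ng"]),
            channel=int(r["channel_nm"]),
        )
    return out
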