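"""Readers and writers for the pipeline's plain-text exchange formats.

CSV carries peak tables, templates, calibration points and content reports
(comma-separated, mandatory header, UTF-8, '.' decimal); TSV carries the
similarity report; MGF carries product-ion spectra (PEPMASS = precursor m/z,
charge 1-). Display precisions follow reporting convention — m/z to 4
decimals, contents and similarities to 3 — while every reader returns full
parsed precision.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .fingerprint import ChromPeak, Chromatogram, CommonPeakTemplate
from .msms_annotation import FragmentIon, ProductSpectrum

__all__ = [
    "read_peak_tables",
    "write_peak_tables",
    "read_template",
    "write_template",
    "read_calibration_points",
    "write_contents",
    "read_contents",
    "write_similarity_report",
    "read_spectra_mgf",
    "write_spectra_mgf",
]

PEAK_COLUMNS = ["sample_id", "rt_min", "area", "channel_nm"]


def read_peak_tables(path: str | os.PathLike) -> list[Chromatogram]:
    """Read per-sample peak tables from one CSV (sample_id, rt_min, area, channel_nm)."""
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        peaks = [
            ChromPeak(rt=float(r.rt_min), area=float(r.area), channel=int(r.channel_nm))
            for r in grp.itertuples()
        ]
        out.append(Chromatogram(sample_id=str(sid), peaks=peaks))
    return out


def write_peak_tables(samples: Sequence[Chromatogram], path: str | os.PathLike) -> None:
    rows = [
        {"sample_id": s.sample_id, "rt_min": p.rt, "area": p.area, "channel_nm": p.channel}
        for s in samples
        for p in s.peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


def read_template(path: str | os.PathLike) -> CommonPeakTemplate:
    """Template CSV: peak_id, rt_min, is_anchor (exactly one anchor row)."""
    df = pd.read_csv(path).sort_values("rt_min")
    anchors = df[df["is_anchor"].astype(bool)]
    if len(anchors) != 1:
        raise ValueError(f"{path}: template must designate exactly one anchor peak")
    return CommonPeakTemplate(
        peak_ids=tuple(int(p) for p in df["peak_id"]),
        rts=tuple(float(r) for r in df["rt_min"]),
        reference_peak_id=int(anchors["peak_id"].iloc[0]),
    )


def write_template(template: CommonPeakTemplate, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "peak_id": template.peak_ids,
            "rt_min": template.rts,
            "is_anchor": [int(k == template.reference_peak_id) for k in template.peak_ids],
        }
    ).to_csv(path, index=False)


def read_calibration_points(path: str | os.PathLike) -> pd.DataFrame:
    """Calibration CSV: analyte, ng_on_column, area, channel_nm."""
    df = pd.read_csv(path)
    need = ["analyte", "ng_on_column", "area", "channel_nm"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_contents(table: pd.DataFrame, path: str | os.PathLike, decimals: int = 3) -> None:
    """Content report: samples as rows, analytes as columns, mg/g to 3 decimals."""
    table.round(decimals).to_csv(path, index_label="sample_id")


def read_contents(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path).set_index("sample_id")


def write_similarity_report(report: pd.DataFrame, path: str | os.PathLike) -> None:
    out = report.copy()
    out["similarity"] = out["similarity"].round(3)
    out.to_csv(path, sep="\t", index=False)


def write_spectra_mgf(spectra: Sequence[ProductSpectrum], path: str | os.PathLike) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": [f.mz for f in s.fragments],
                "intensity array": [f.intensity for f in s.fragments],
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": round(s.precursor_mz, 4),
                    "charge": "1-",
                    "rtinseconds": s.retention_time * 60.0,
                    "adduct": s.adduct,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_spectra_mgf(path: str | os.PathLike) -> list[ProductSpectrum]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params["pepmass"]
            precursor = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            frags = [
                FragmentIon(mz=float(m), intensity=float(i))
                for m, i in zip(entry["m/z array"], entry["intensity array"])
            ]
            out.append(
                ProductSpectrum(
                    precursor_mz=precursor,
                    adduct=str(params.get("adduct", "[M-H]-")),
                    fragments=frags,
                    retention_time=float(params.get("rtinseconds", 0.0)) / 60.0,
                    spectrum_id=str(params.get("title", "")),
                )
            )
    return out
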