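"""HPLC fingerprint analysis across batches.

A fingerprint is the table of common chromatographic peaks shared by every
batch of a herbal material, recorded at a fixed wavelength (254 nm here).
All statistics are expressed relative to a designated anchor peak: relative
retention time RRT = rt / rt(anchor) and relative peak area
RPA = area / area(anchor), which cancel run-to-run drifts in flow and
injection. Batch similarity is the congruence (cosine) coefficient between
common-peak area vectors; method validation summarises the relative standard
deviations of RPA and RRT over replicate injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromPeak",
    "Chromatogram",
    "CommonPeakTemplate",
    "FingerprintMatrix",
    "AnchorNotFoundError",
    "assign_common_peaks",
    "relative_stats",
    "build_reference",
    "similarity",
    "similarity_report",
    "validation_suite",
    "DEFAULT_RRT_WINDOW",
    "FINGERPRINT_CHANNEL_NM",
]

FINGERPRINT_CHANNEL_NM = 254
# RRT scatter across replicate injections stays around 0.2%, so a 0.5%
# relative window cleanly separates true common peaks from neighbours.
DEFAULT_RRT_WINDOW = 0.005


class AnchorNotFoundError(ValueError):
    """The anchor (reference) peak could not be located in a sample."""


def _align(
    n_t: int,
    n_s: int,
    dev: Mapping[tuple[int, int], float],
    window: float,
) -> list[tuple[int, int]]:
    """Order-preserving one-to-one alignment of template to sample peaks.

    Dynamic programme over the two RT-sorted sequences: maximise the number
    of matched pairs with deviation <= ``window``, then minimise the total
    deviation. Returns (template index, sample index) pairs.
    """
    NEG = (-1, 0.0)
    # score[i][j] = (matches, -total_dev) using first i template, j sample peaks
    score = [[(0, 0.0)] * (n_s + 1) for _ in range(n_t + 1)]
    move = [[0] * (n_s + 1) for _ in range(n_t + 1)]  # 1=skip t, 2=skip s, 3=match
    for i in range(n_t + 1):
        for j in range(n_s + 1):
            if i == 0 and j == 0:
                continue
            best, mv = NEG, 0
            if i > 0 and (score[i - 1][j][0], score[i - 1][j][1]) > best:
                best, mv = score[i - 1][j], 1
            if j > 0 and (score[i][j - 1][0], score[i][j - 1][1]) > best:
                best, mv = score[i][j - 1], 2
            if i > 0 and j > 0:
                d = dev[(i - 1, j - 1)]
                if d <= window:
                    cand = (score[i - 1][j - 1][0] + 1, score[i - 1][j - 1][1] - d)
                    if cand > best:
                        best, mv = cand, 3
            score[i][j], move[i][j] = best, mv
    pairs: list[tuple[int, int]] = []
    i, j = n_t, n_s
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 3:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


@dataclass(frozen=True)
class ChromPeak:
    rt: float
    area: float
    channel: int = FINGERPRINT_CHANNEL_NM

    def __post_init__(self) -> None:
        if self.rt < 0 or self.area < 0:
            raise ValueError("rt and area must be >= 0")


@dataclass
class Chromatogram:
    """One sample's peak table at one detection channel."""

    sample_id: str
    peaks: list[ChromPeak]
    channel: int = FINGERPRINT_CHANNEL_NM

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.rt)


@dataclass(frozen=True)
class CommonPeakTemplate:
    """Numbered common peaks with reference RTs and the RRT/RPA anchor."""

    peak_ids: tuple[int, ...]
    rts: tuple[float, ...]
    reference_peak_id: int

    def __post_init__(self) -> None:
        if len(self.peak_ids) != len(self.rts):
            raise ValueError("peak_ids and rts must have equal length")
        if self.reference_peak_id not in self.peak_ids:
            raise ValueError("reference peak must be part of the template")
        if any(b <= a for a, b in zip(self.rts, self.rts[1:])):
            raise ValueError("template rts must be strictly increasing")

    @property
    def anchor_rt(self) -> float:
        return self.rts[self.peak_ids.index(self.reference_peak_id)]

    @property
    def rrt(self) -> dict[int, float]:
        return {k: rt / self.anchor_rt for k, rt in zip(self.peak_ids, self.rts)}


def default_template() -> CommonPeakTemplate:
    """The 28-peak template with peak 11 (genipin gentiobioside) as anchor."""
    from .datasets import table_common_peaks

    df = table_common_peaks().drop_duplicates("peak").sort_values("rt_min")
    return CommonPeakTemplate(
        peak_ids=tuple(int(p) for p in df["peak"]),
        rts=tuple(float(r) for r in df["rt_min"]),
        reference_peak_id=11,
    )


@dataclass
class FingerprintMatrix:
    """samples x common-peaks area and RT matrices (NaN = peak absent)."""

    areas: pd.DataFrame
    rts: pd.DataFrame
    template: CommonPeakTemplate
    invalid_samples: list[str] = field(default_factory=list)

    @property
    def rrt(self) -> pd.DataFrame:
        anchor = self.rts[self.template.reference_peak_id]
        return self.rts.div(anchor, axis=0)

    @property
    def rpa(self) -> pd.DataFrame:
        anchor = self.areas[self.template.reference_peak_id]
        if (anchor == 0).any():
            raise ValueError("anchor peak area is zero in some sample")
        return self.areas.div(anchor, axis=0)


def assign_common_peaks(
    samples: Sequence[Chromatogram],
    template: CommonPeakTemplate,
    rrt_window: float = DEFAULT_RRT_WINDOW,
) -> FingerprintMatrix:
    """Match each template peak to at most one peak per sample by RRT.

    The anchor is located first as the absolute-RT nearest neighbour. The
    remaining template peaks are then aligned to sample peaks one-to-one by
    relative deviation |RRT_sample/RRT_template - 1| <= ``rrt_window``,
    using an elution-order-preserving alignment that maximises the number of
    matches and, among those, minimises the total deviation — peaks cannot
    swap identities across a close-eluting pair, which plain closest-first
    greedy matching allows. A sample whose anchor cannot be matched is
    flagged invalid (all NaN).
    """
    if not samples:
        raise ValueError("need at least one sample")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique")
    areas = pd.DataFrame(np.nan, index=ids, columns=list(template.peak_ids))
    rts = pd.DataFrame(np.nan, index=ids, columns=list(template.peak_ids))
    invalid: list[str] = []
    t_rrt = template.rrt
    for s in samples:
        if not s.peaks:
            invalid.append(s.sample_id)
            continue
        peak_rts = np.array([p.rt for p in s.peaks])
        i_anchor = int(np.argmin(np.abs(peak_rts - template.anchor_rt)))
        anchor = s.peaks[i_anchor]
        if anchor.rt == 0 or abs(anchor.rt / template.anchor_rt - 1) > rrt_window:
            invalid.append(s.sample_id)
            continue
        areas.loc[s.sample_id, template.reference_peak_id] = anchor.area
        rts.loc[s.sample_id, template.reference_peak_id] = anchor.rt
        ks = [k for k in template.peak_ids if k != template.reference_peak_id]
        js = [j for j in range(len(s.peaks)) if j != i_anchor]
        dev = {
            (ki, jj): abs((s.peaks[js[jj]].rt / anchor.rt) / t_rrt[ks[ki]] - 1.0)
            for ki in range(len(ks))
            for jj in range(len(js))
        }
        for ki, jj in _align(len(ks), len(js), dev, rrt_window):
            areas.loc[s.sample_id, ks[ki]] = s.peaks[js[jj]].area
            rts.loc[s.sample_id, ks[ki]] = s.peaks[js[jj]].rt
    valid = [i for i in ids if i not in invalid]
    return FingerprintMatrix(
        areas=areas.loc[valid], rts=rts.loc[valid], template=template,
        invalid_samples=invalid,
    )


def _rsd(x: pd.Series | np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return np.nan
    m = x.mean()
    if m == 0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * x.std(ddof=1) / m


def relative_stats(matrix: FingerprintMatrix) -> pd.DataFrame:
    """Per-peak mean and RSD (%) of RRT and RPA across samples."""
    rrt, rpa = matrix.rrt, matrix.rpa
    return pd.DataFrame(
        {
            "rrt_mean": rrt.mean(axis=0),
            "rrt_rsd_pct": rrt.apply(_rsd, axis=0),
            "rpa_mean": rpa.mean(axis=0),
            "rpa_rsd_pct": rpa.apply(_rsd, axis=0),
        }
    )


def build_reference(
    samples: Sequence[Chromatogram],
    mode: Literal["designated", "median"] = "designated",
    designated_id: str | None = None,
    template: CommonPeakTemplate | None = None,
    rrt_window: float = DEFAULT_RRT_WINDOW,
) -> Chromatogram:
    """Reference chromatogram: a designated sample, or per-peak medians."""
    if mode == "designated":
        if designated_id is None:
            designated_id = samples[0].sample_id
        for s in samples:
            if s.sample_id == designated_id:
                return Chromatogram(sample_id="reference", peaks=list(s.peaks), channel=s.channel)
        raise ValueError(f"unknown designated_id {designated_id!r}")
    if mode == "median":
        if template is None:
            raise ValueError("median mode requires a template")
        m = assign_common_peaks(samples, template, rrt_window)
        peaks = [
            ChromPeak(rt=float(m.rts[k].median()), area=float(m.areas[k].median()))
            for k in template.peak_ids
            if m.rts[k].notna().any()
        ]
        return Chromatogram(sample_id="reference", peaks=peaks)
    raise ValueError(f"unknown mode {mode!r}")


def similarity(
    sample_vec: Iterable[float],
    reference_vec: Iterable[float],
    method: Literal["cosine", "pearson"] = "cosine",
) -> float:
    """Congruence (cosine) or Pearson similarity between area vectors."""
    x = np.asarray(list(sample_vec), dtype=float)
    y = np.asarray(list(reference_vec), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share a length >= 2")
    if not np.linalg.norm(y):
        raise ValueError("reference vector has zero norm")
    if not np.linalg.norm(x):
        raise ValueError("sample vector has zero norm")
    if method == "cosine":
        return float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown method {method!r}")


def similarity_report(
    samples: Sequence[Chromatogram],
    reference: Chromatogram,
    template: CommonPeakTemplate,
    method: Literal["cosine", "pearson"] = "cosine",
    rrt_window: float = DEFAULT_RRT_WINDOW,
) -> pd.DataFrame:
    """Per-sample matched-peak count and similarity to the reference.

    Unmatched common peaks enter the vectors as zero area; the matched count
    is reported alongside so absences stay auditable.
    """
    m = assign_common_peaks(list(samples) + [reference], template, rrt_window)
    if "reference" in m.invalid_samples or reference.sample_id in m.invalid_samples:
        raise AnchorNotFoundError("anchor not found in the reference chromatogram")
    ref_vec = m.areas.loc[reference.sample_id].fillna(0.0).to_numpy()
    rows = []
    for s in samples:
        if s.sample_id in m.invalid_samples:
            rows.append({"sample_id": s.sample_id, "n_matched": 0, "similarity": np.nan})
            continue
        vec = m.areas.loc[s.sample_id]
        rows.append(
            {
                "sample_id": s.sample_id,
                "n_matched": int(vec.notna().sum()),
                "similarity": similarity(vec.fillna(0.0).to_numpy(), ref_vec, method),
            }
        )
    return pd.DataFrame(rows)


def validation_suite(
    replicate_sets: Mapping[str, Sequence[Chromatogram]],
    template: CommonPeakTemplate,
    rpa_threshold_pct: float = 5.0,
    rrt_threshold_pct: float = 1.0,
    rrt_window: float = DEFAULT_RRT_WINDOW,
) -> pd.DataFrame:
    """Max per-peak RSDs of RPA and RRT for each replicate set.

    Each set needs >= 3 replicates; a replicate missing the anchor peak is a
    hard error (the test design is broken, not merely noisy).
    """
    rows = []
    for name, reps in replicate_sets.items():
        if len(reps) < 3:
            raise ValueError(f"set {name!r} needs >= 3 replicates")
        m = assign_common_peaks(reps, template, rrt_window)
        if m.invalid_samples:
            raise AnchorNotFoundError(
                f"set {name!r}: anchor missing in replicates {m.invalid_samples}"
            )
        stats = relative_stats(m)
        others = [k for k in template.peak_ids if k != template.reference_peak_id]
        max_rpa = float(stats.loc[others, "rpa_rsd_pct"].max())
        max_rrt = float(stats.loc[others, "rrt_rsd_pct"].max())
        rows.append(
            {
                "test": name,
                "max_rpa_rsd_pct": max_rpa,
                "max_rrt_rsd_pct": max_rrt,
                "passed": max_rpa <= rpa_threshold_pct and max_rrt <= rrt_threshold_pct,
            }
        )
    return pd.DataFrame(rows).set_index("test")
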