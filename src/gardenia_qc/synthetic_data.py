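"""Seeded generators of virtual batch data for end-to-end testing.

No raw chromatograms or spectra accompany the published batch study, so the
pipeline is exercised on simulated data with the same statistical structure:

* per-batch true contents drawn from truncated normals whose means and SDs
  default to the empirical column statistics of the 40-batch content table;
* peak areas produced through the published calibration lines after the
  forward dilution chain (content -> ng on column), with multiplicative
  lognormal noise;
* retention times at the published common-peak positions with small
  multiplicative jitter, plus a few spurious peaks kept clear of every
  matching window;
* product-ion spectra built from a compound's formula and reference cascade
  with ppm-scale Gaussian mass noise and abundance-ordered intensities.

Every generator draws all randomness from the single scenario seed, and the
ground truth travels beside the generated set without ever feeding back into
pipeline inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .chem_mass import adduct_mz, anion_mz
from .datasets import (
    QUANTIFIED_ANALYTES,
    CompoundRecord,
    calibration_curves,
    table_contents,
)
from .fingerprint import ChromPeak, Chromatogram, CommonPeakTemplate, default_template
from .msms_annotation import FragmentIon, ProductSpectrum, default_loss_library, precursor_anion
from .quantitation import SamplePrep

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_batch_set",
    "generate_spectrum",
    "generate_validation_sets",
]

#: Fixed fingerprint-only areas for the 16 common peaks without calibration
#: lines (arbitrary but realistic magnitudes; deterministic test fixtures).
UNCALIBRATED_PEAK_AREAS: dict[int, float] = {
    1: 8.2e5, 6: 4.1e5, 7: 2.9e5, 13: 3.6e5, 14: 2.4e5, 16: 6.8e5,
    17: 5.1e5, 18: 7.4e5, 19: 4.8e5, 21: 3.3e5, 22: 2.8e5, 23: 1.9e5,
    24: 5.6e5, 26: 2.2e5, 27: 3.0e5, 28: 2.6e5,
}


def _content_stats() -> tuple[dict[str, float], dict[str, float]]:
    df = table_contents()[QUANTIFIED_ANALYTES]
    return df.mean().to_dict(), df.std(ddof=1).to_dict()


@dataclass
class ScenarioConfig:
    """Study conditions for a simulated batch set.

    Defaults emulate the published study: 40 batches, content distributions
    matching the 40-batch table's column statistics, ~0.1% RT jitter, 2%
    multiplicative area noise, up to 5 spurious peaks per run, and 2 ppm
    mass noise on spectra.
    """

    seed: int
    n_samples: int = 40
    true_content_means: Mapping[str, float] = field(default_factory=dict)
    true_content_sds: Mapping[str, float] = field(default_factory=dict)
    rt_jitter_sd: float = 0.001
    area_noise_cv: float = 0.02
    n_spurious_peaks: tuple[int, int] = (0, 5)
    ms_ppm_noise_sd: float = 2.0
    fixed_contents: pd.DataFrame | None = None
    prep: SamplePrep = field(default_factory=SamplePrep)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for v in (self.rt_jitter_sd, self.area_noise_cv, self.ms_ppm_noise_sd):
            if v < 0:
                raise ValueError("noise parameters must be >= 0")
        means, sds = _content_stats()
        self.true_content_means = {**means, **dict(self.true_content_means)}
        self.true_content_sds = {**sds, **dict(self.true_content_sds)}
        unknown = set(self.true_content_means) - set(QUANTIFIED_ANALYTES)
        if unknown:
            raise ValueError(f"unknown analytes in config: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """True per-sample contents (mg/g) and true peak RTs; never a pipeline input."""

    contents: pd.DataFrame
    rts: pd.DataFrame


def _analyte_peak_map() -> dict[str, int]:
    from .datasets import table_calibration

    return {r["analyte"]: int(r["peak"]) for _, r in table_calibration().iterrows()}


def generate_batch_set(
    config: ScenarioConfig,
    template: CommonPeakTemplate | None = None,
) -> tuple[list[Chromatogram], GroundTruth]:
    """Simulate a batch set of common-peak chromatograms.

    Quantified-peak areas run forward through the dilution chain and the
    published calibration lines; uncalibrated common peaks carry fixed
    template areas; all areas get lognormal noise of the configured CV and
    all RTs multiplicative jitter. The jitter of each peak is truncated at
    +/-2 SD and additionally at 45% of its relative gap to the nearest
    template neighbour, so generated RTs never cross elution order and every
    common peak stays inside the default RRT matching window — common-peak
    assignment on generated sets is deterministic, not merely probable.
    Spurious peaks are likewise rejected from every template RRT window.
    """
    rng = np.random.default_rng(config.seed)
    if template is None:
        template = default_template()
    curves = calibration_curves()
    peak_of = _analyte_peak_map()
    template_rt = dict(zip(template.peak_ids, template.rts))

    n = config.n_samples
    if config.fixed_contents is not None:
        contents = config.fixed_contents[QUANTIFIED_ANALYTES].copy()
        contents.index = [str(i) for i in contents.index]
        n = len(contents)
    else:
        draws = {}
        for a in QUANTIFIED_ANALYTES:
            x = rng.normal(config.true_content_means[a], config.true_content_sds[a], size=n)
            draws[a] = np.clip(x, 0.0, None)  # truncate at zero
        contents = pd.DataFrame(draws, index=[f"V{i+1}" for i in range(n)])

    sigma = np.sqrt(np.log1p(config.area_noise_cv**2))
    # Per-peak jitter bound: 2 SD, capped by 45% of the relative gap to the
    # nearest template neighbour (keeps elution order and window membership).
    rt_sorted = sorted(template_rt.values())
    jitter_bound: dict[int, float] = {}
    for k, t in template_rt.items():
        gaps = [abs(o - t) / t for o in rt_sorted if o != t]
        rel_gap = min(gaps) if gaps else np.inf
        jitter_bound[k] = min(2.0 * config.rt_jitter_sd, 0.45 * rel_gap)

    chroms: list[Chromatogram] = []
    true_rts = pd.DataFrame(
        np.nan, index=contents.index, columns=list(template.peak_ids)
    )
    analyte_channel = {a: curves[a].channel for a in QUANTIFIED_ANALYTES}
    for sid in contents.index:
        peaks: list[ChromPeak] = []
        for k in template.peak_ids:
            rt_true = template_rt[k]
            e = rng.normal(0.0, config.rt_jitter_sd)
            b = jitter_bound[k]
            rt = rt_true * (1.0 + float(np.clip(e, -b, b)))
            true_rts.loc[sid, k] = rt_true
            analyte = next((a for a, p in peak_of.items() if p == k), None)
            if analyte is not None:
                ng = contents.loc[sid, analyte] * config.prep.ng_per_mgg
                area = curves[analyte].slope * ng + curves[analyte].intercept
                channel = analyte_channel[analyte]
            else:
                area = UNCALIBRATED_PEAK_AREAS[k]
                channel = 254
            if sigma > 0:
                area *= np.exp(rng.normal(0.0, sigma))
            peaks.append(ChromPeak(rt=max(rt, 0.0), area=max(area, 0.0), channel=channel))
        n_spur = int(rng.integers(config.n_spurious_peaks[0], config.n_spurious_peaks[1] + 1))
        added = 0
        while added < n_spur:
            rt = float(rng.uniform(5.0, 80.0))
            if any(abs(rt / t - 1.0) < 0.02 for t in template_rt.values()):
                continue  # keep spurious peaks out of matching windows
            peaks.append(ChromPeak(rt=rt, area=float(rng.uniform(1e4, 8e4))))
            added += 1
        chroms.append(Chromatogram(sample_id=str(sid), peaks=peaks))
    return chroms, GroundTruth(contents=contents, rts=true_rts)


def generate_spectrum(
    record: CompoundRecord,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> ProductSpectrum:
    """Forward-model a product spectrum from a record's reference cascade.

    The precursor and each cascade intermediate appear at their theoretical
    m/z perturbed by Gaussian ppm noise, with intensities decreasing along
    the cascade (precursor survival included).
    """
    if not record.reference_cascade:
        raise ValueError(f"record {record.name!r} has no reference cascade")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    losses = {l.name: l for l in default_loss_library()}

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0.0, config.ms_ppm_noise_sd) * 1e-6)

    f = precursor_anion(record.formula, record.adduct)
    mzs = [anion_mz(f)]
    for name in record.reference_cascade:
        f = f - losses[name].formula
        mzs.append(anion_mz(f))
    frags = [
        FragmentIon(mz=jitter(mz), intensity=1000.0 * 0.7**i)
        for i, mz in enumerate(mzs)
    ]
    return ProductSpectrum(
        precursor_mz=jitter(adduct_mz(record.formula, record.adduct)),
        adduct=record.adduct,
        fragments=frags,
        retention_time=record.reference_rt,
        spectrum_id=record.name,
    )


def generate_validation_sets(
    config: ScenarioConfig,
    template: CommonPeakTemplate | None = None,
    injection_cv: float = 0.01,
    rt_sd: float = 0.0005,
    drift_cv: float = 0.01,
    prep_cv: float = 0.02,
) -> dict[str, list[Chromatogram]]:
    """Replicate sets mimicking precision / stability / repeatability designs.

    All three sets re-measure the same underlying sample six times:
    ``precision`` with injection noise only; ``stability`` adding a linear,
    peak-specific degradation drift across the six time points (constituents
    decay at different rates, so the drift survives the RPA ratio);
    ``repeatability`` adding independent per-peak preparation noise
    (extraction efficiency varies by compound; a common scale factor would
    cancel against the anchor).
    """
    rng = np.random.default_rng(config.seed)
    if template is None:
        template = default_template()
    base_contents = table_contents().iloc[[0]][QUANTIFIED_ANALYTES]
    n_peaks = len(template.peak_ids)
    # Deterministic per-peak decay weights in [0, 1]: earlier-eluting (more
    # polar) constituents degrade faster in this model.
    drift_weight = {
        k: 1.0 - i / max(n_peaks - 1, 1) for i, k in enumerate(template.peak_ids)
    }

    def one_set(name: str, area_cv: float, drift: float, per_peak_prep_cv: float) -> list[Chromatogram]:
        reps: list[Chromatogram] = []
        for r in range(6):
            cfg = ScenarioConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                n_samples=1,
                fixed_contents=base_contents,
                rt_jitter_sd=rt_sd,
                area_noise_cv=area_cv,
                n_spurious_peaks=(0, 0),
                prep=config.prep,
            )
            chrom, _ = generate_batch_set(cfg, template)
            peaks = []
            for k, p in zip(template.peak_ids, chrom[0].peaks):
                scale = 1.0
                if drift > 0:
                    scale *= 1.0 - drift * drift_weight[k] * r / 5.0
                if per_peak_prep_cv > 0:
                    scale *= float(np.exp(rng.normal(0.0, per_peak_prep_cv)))
                peaks.append(ChromPeak(rt=p.rt, area=p.area * scale, channel=p.channel))
            reps.append(Chromatogram(sample_id=f"{name}_{r+1}", peaks=peaks))
        return reps

    return {
        "precision": one_set("precision", injection_cv, 0.0, 0.0),
        "stability": one_set("stability", injection_cv, drift_cv, 0.0),
        "repeatability": one_set("repeatability", injection_cv, 0.0, prep_cv),
    }
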