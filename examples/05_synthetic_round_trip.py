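"""Generator round trips: the simulation is the test harness.

With zero noise the forward model (content -> ng on column -> area) and the
quantitation inverse cancel exactly; with default noise the recovered
contents track the generating truth within a few percent.
"""

import numpy as np

from gardenia_qc import (
    QUANTIFIED_ANALYTES,
    ScenarioConfig,
    default_template,
    generate_batch_set,
    table_contents,
)
from gardenia_qc.cli import quantify_batch

template = default_template()

# Zero-noise round trip on batch 1's published contents
s1 = table_contents().iloc[[0]][QUANTIFIED_ANALYTES]
cfg0 = ScenarioConfig(seed=1, rt_jitter_sd=0.0, area_noise_cv=0.0,
                      n_spurious_peaks=(0, 0), fixed_contents=s1)
chroms0, truth0 = generate_batch_set(cfg0)
err = np.abs(quantify_batch(chroms0, template)[QUANTIFIED_ANALYTES].to_numpy()
             - truth0.contents.to_numpy()).max()
print(f"zero-noise round trip, max |recovered - true|: {err:.2e} mg/g")

# Default-noise parameter recovery over 40 virtual batches
cfg = ScenarioConfig(seed=42)
chroms, truth = generate_batch_set(cfg)
out = quantify_batch(chroms, template)
mae = (out[QUANTIFIED_ANALYTES] - truth.contents).abs().mean()
rel = (mae / truth.contents.mean() * 100).round(2)
print("\nper-analyte mean absolute error at 2% area noise (% of mean content):")
for analyte in QUANTIFIED_ANALYTES:
    print(f"  {analyte:22s} {rel[analyte]:5.2f} %")
print("errors near the injected 2% CV confirm the pipeline adds no bias.")
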