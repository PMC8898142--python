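"""Neutral-loss cascade annotation of a product-ion spectrum.

Reconstructs the fragmentation of the acylated iridoid eluting as
fingerprint peak 16 ([M-H]- 597.1855): successive losses of a sinapoyl
residue, a glucose unit, CO2 and H2O lead down to m/z 167, identifying a
shanzhiside core carrying a sinapoyl group.
"""

from gardenia_qc import (
    FragmentIon,
    ProductSpectrum,
    annotate_cascade,
    compound_library,
    match_to_library,
    parse_formula,
)

observed = [597.1923, 391.1285, 229.0734, 223.0633, 205.0521, 185.0825, 167.0717]
spectrum = ProductSpectrum(
    precursor_mz=597.1855,
    adduct="[M-H]-",
    fragments=[FragmentIon(mz=m, intensity=1000.0 - i) for i, m in enumerate(observed)],
    retention_time=55.917,
    spectrum_id="peak16",
)

for frag in annotate_cascade(spectrum, parse_formula("C27H34O15")):
    path = " -> ".join(frag.loss_path) if frag.loss_path else (
        "(precursor survival)" if frag.loss_path == () else "unassigned")
    ion = f"[{frag.assigned_formula}]-" if frag.assigned_formula else ""
    print(f"m/z {frag.mz:9.4f}  {ion:14s} {path}")

# Library lookup without an entry for this compound: the cascade tail
# (glucose, CO2, H2O) is shanzhiside's own fragmentation, so the spectrum
# is flagged as a putative shanzhiside-skeleton derivative.
pruned = [r for r in compound_library() if r.peak_id != 16]
res = match_to_library(spectrum, pruned)
print(f"\nlibrary verdict: {res.name} ({res.identity_level}, "
      f"cascade matched: {res.matched_cascade})")
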