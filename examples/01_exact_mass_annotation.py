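"""Exact-mass annotation of negative-mode quasimolecular ions.

Computes theoretical [M-H]- / [M+Cl]- m/z for known Gardeniae Fructus
constituents, the ppm error of a measured ion, and a formula enumeration
from an accurate mass alone.
"""

from gardenia_qc import adduct_mz, enumerate_formulas, parse_formula, ppm_error

for name, formula, adduct, measured in [
    ("geniposide", "C17H24O10", "[M+Cl]-", 423.1076),
    ("rutin", "C27H30O16", "[M-H]-", 609.1482),
    ("crocin I", "C44H64O24", "[M+Cl]-", 1011.3519),
    ("shanzhiside", "C16H24O11", "[M-H]-", 391.1249),
]:
    theo = adduct_mz(parse_formula(formula), adduct)
    err = ppm_error(measured, theo)
    print(f"{name:12s} {formula:10s} {adduct:8s} theoretical {theo:.4f}"
          f"  measured {measured:.4f}  error {err:+.1f} ppm")

# From an accurate mass alone: which CHO formulas fit 597.1855 ([M-H]-)?
cands = enumerate_formulas(597.1855, "[M-H]-", tol_ppm=10.0)
print("\nformula candidates for m/z 597.1855 ([M-H]-, 10 ppm):",
      ", ".join(str(f) for f in cands))
# The top candidate is the precursor of the sinapoyl-shanzhiside cascade
# worked through in example 02; errors of a few ppm are instrument-typical.
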