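"""Independent brute-force oracles shared across test modules."""

from gardenia_qc.chem_mass import ELECTRON_MASS, MONOISOTOPIC_MASS


def brute_force_formulas(target_mz, adduct, tol_ppm, bounds):
    """Triple-loop CHO enumeration oracle, independent of the library path."""
    delta = {
        "[M-H]-": -1.00727646,
        "[M+Cl]-": MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS,
    }[adduct]
    hits = set()
    for c in range(bounds["C"][0], bounds["C"][1] + 1):
        for h in range(bounds["H"][0], bounds["H"][1] + 1):
            for o in range(bounds["O"][0], bounds["O"][1] + 1):
                if c + h + o == 0:
                    continue
                m = 12.0 * c + MONOISOTOPIC_MASS["H"] * h + MONOISOTOPIC_MASS["O"] * o
                r = c - h / 2.0 + 1.0
                if r < 0 or h % 2:
                    continue
                if abs(m + delta - target_mz) <= tol_ppm * 1e-6 * target_mz:
                    hits.add((c, h, o))
    return hits
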