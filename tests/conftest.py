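import pytest

from gardenia_qc import (
    FragmentIon,
    ProductSpectrum,
    compound_library,
    default_template,
    parse_formula,
    table_common_peaks,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def library():
    return compound_library()


@pytest.fixture(scope="session")
def ion_rows():
    """All per-adduct quasimolecular-ion rows of the packaged compound table."""
    return table_common_peaks()


@pytest.fixture
def sinapoyl_shanzhiside_spectrum():
    """The published product spectrum of fingerprint peak 16 ([M-H]- 597.1855)."""
    frags = [597.1923, 391.1285, 229.0734, 223.0633, 205.0521, 185.0825, 167.0717]
    return ProductSpectrum(
        precursor_mz=597.1855,
        adduct="[M-H]-",
        fragments=[FragmentIon(mz=m, intensity=1000.0 - i) for i, m in enumerate(frags)],
        retention_time=55.917,
        spectrum_id="peak16",
    )


@pytest.fixture
def sinapoyl_shanzhiside_formula():
    return parse_formula("C27H34O15")
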