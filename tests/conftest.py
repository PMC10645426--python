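import pytest

from specseq import SpecseqLibrary, make_truth_pwm

FLANK5 = "GAGTTCATCC"
FLANK3 = "CGGTAGATCT"


@pytest.fixture(scope="session")
def hd_library() -> SpecseqLibrary:
    """Monomeric homeodomain library: fixed TAA, three randomized 3' bases."""
    return SpecseqLibrary(
        name="hd-monomer",
        flank5=FLANK5,
        core_pattern="TAANNN",
        flank3=FLANK3,
    )


@pytest.fixture(scope="session")
def truth_pwm(hd_library):
    """A fixed random ground-truth additive energy model (consensus TAATCC)."""
    return make_truth_pwm(hd_library, "TAATCC", energy_scale=1.0, seed=11)
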