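"""Shared configuration for the analysis drivers.

One monomeric homeodomain library (fixed TAA, three randomized 3' bases),
two simulated genotypes: a wild-type-like protein with consensus TAATCC and
an altered-specificity mutant (residue-50-class change) with consensus
TAATTA.  Depths and seeds are fixed here so every driver is reproducible.
"""

from pathlib import Path

from specseq import SpecseqLibrary, make_truth_pwm

RESULTS = Path(__file__).resolve().parent.parent / "results"

SEED = 20230901
DEPTH = 200_000  # reads per gel fraction

WT_CONSENSUS = "TAATCC"
MUT_CONSENSUS = "TAATTA"


def library() -> SpecseqLibrary:
    return SpecseqLibrary(
        name="hd-monomer",
        flank5="GAGTTCATCC",
        core_pattern="TAANNN",
        flank3="CGGTAGATCT",
    )


def truth_models(lib):
    """Ground-truth additive energy models per genotype."""
    return {
        "wt": make_truth_pwm(lib, WT_CONSENSUS, energy_scale=1.0, seed=SEED),
        "mut": make_truth_pwm(lib, MUT_CONSENSUS, energy_scale=1.2,
                              seed=SEED + 1),
    }


CONSENSUS = {"wt": WT_CONSENSUS, "mut": MUT_CONSENSUS}
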