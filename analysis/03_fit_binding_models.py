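"""Fit additive binding-energy models (ePWMs) and logo matrices per genotype.

Regression uses only variants within two mismatches of each genotype's
consensus, with the consensus base pinned to 0 at every position.  Logo
matrices are the per-column mean-centered ePWMs (columns sum to 0); the
negated matrix is what a logo renderer would draw, preferred bases up.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
config = importlib.import_module("00_config")

from specseq import SpecseqLibrary, fit_epwm, logo_matrix
from specseq import io as sio

DATASETS = {"wt_rep1": "wt", "mut_rep1": "mut"}


def main() -> None:
    lib = SpecseqLibrary.from_json(config.RESULTS / "library.json")
    for name, genotype in DATASETS.items():
        et = sio.read_energy_table(
            config.RESULTS / f"energies_{name}.tsv", lib
        )
        pwm = fit_epwm(et, max_mismatch=2)
        sio.write_epwm(config.RESULTS / f"epwm_{name}.tsv", pwm)
        lm = logo_matrix(pwm)
        sio.write_logo_matrix(config.RESULTS / f"logo_{name}.tsv", lm)
        print(
            f"{name} ({genotype}, consensus {pwm.reference_variant}): "
            f"fit on {pwm.fit.n_variants_fit} variants, "
            f"R^2 = {pwm.fit.r_squared:.4f}, "
            f"residual sd = {pwm.fit.residual_sd:.4f} kT"
        )


if __name__ == "__main__":
    main()
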