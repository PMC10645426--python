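"""Simulate Spec-seq experiments: two wild-type replicates and one mutant.

Each experiment partitions the 64-variant homeodomain library into bound and
unbound fractions by equilibrium occupancy under its genotype's ground-truth
energy model, then draws multinomial sequencing counts.  Writes per-variant
count tables and the truth energies to results/.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
config = importlib.import_module("00_config")

from specseq import SimulationConfig, simulate_counts
from specseq import io as sio


def main() -> None:
    config.RESULTS.mkdir(exist_ok=True)
    lib = config.library()
    models = config.truth_models(lib)
    datasets = {
        "wt_rep1": ("wt", config.SEED + 10),
        "wt_rep2": ("wt", config.SEED + 11),
        "mut_rep1": ("mut", config.SEED + 12),
    }
    for name, (genotype, seed) in datasets.items():
        cfg = SimulationConfig(
            library=lib,
            truth_pwm=models[genotype],
            reads_per_fraction=(config.DEPTH, config.DEPTH),
            seed=seed,
        )
        fc, truth = simulate_counts(cfg)
        sio.write_counts(
            config.RESULTS / f"counts_{name}.tsv", fc,
            {"genotype": genotype, "seed": seed, "depth": config.DEPTH},
        )
        truth_df = pd.DataFrame(
            sorted(truth.energies.items()), columns=["variant", "ddG_true"]
        )
        sio.write_tsv(
            config.RESULTS / f"truth_{name}.tsv", truth_df,
            {"genotype": genotype, "seed": seed},
        )
        nb, nu = fc.totals
        print(f"{name}: {nb:.0f} bound / {nu:.0f} unbound reads "
              f"({genotype}, consensus {config.CONSENSUS[genotype]})")
    lib.to_json(config.RESULTS / "library.json")


if __name__ == "__main__":
    main()
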