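"""Compare energy tables: replicate concordance and mutant vs wild type.

Replicates of the same protein should fall on the identity line (Pearson r
near 1, per-experiment noise a few hundredths of a kT).  A genotype with
altered specificity decorrelates: its energies, each anchored at its own
consensus, no longer track the wild type's.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
config = importlib.import_module("00_config")

from specseq import SpecseqLibrary, compare_energy_tables
from specseq import io as sio


def main() -> None:
    lib = SpecseqLibrary.from_json(config.RESULTS / "library.json")
    tables = {
        name: sio.read_energy_table(
            config.RESULTS / f"energies_{name}.tsv", lib
        )
        for name in ("wt_rep1", "wt_rep2", "mut_rep1")
    }
    pairs = {
        "wt_replicates": ("wt_rep1", "wt_rep2"),
        "mut_vs_wt": ("wt_rep1", "mut_rep1"),
    }
    for label, (a, b) in pairs.items():
        rep = compare_energy_tables(tables[a], tables[b])
        sio.write_json(config.RESULTS / f"compare_{label}.json", rep.to_dict())
        print(
            f"{label}: r = {rep.pearson_r:.3f}, "
            f"noise = {rep.noise_level:.3f} kT, "
            f"slope = {rep.fit_slope:.3f} ({rep.n_shared} shared variants)"
        )


if __name__ == "__main__":
    main()
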