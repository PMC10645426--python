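"""Place samples on a developmental axis by gene-set correlation.

Takes the activated-gene set from the classification step and correlates
query expression profiles (here: noisy draws from known pseudo-ages of the
synthetic developmental matrix) against every reference age.  A sample
generated from the P14 profile should correlate best with P14.
"""

import importlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
config = importlib.import_module("00_config")

from specseq import developmental_correlation
from specseq import io as sio


def main() -> None:
    dev = sio.read_expression_matrix(config.RESULTS / "dev_expression.tsv")
    classes = sio.read_tsv(
        config.RESULTS / "gene_classes.tsv"
    ).set_index("gene")
    activated = set(classes.index[classes["class"] == "dependent_activated"])

    rng = np.random.default_rng(config.SEED + 40)
    query = pd.DataFrame(
        {
            f"sample_{age}": dev[age]
            * rng.lognormal(0.0, 0.05, size=len(dev))
            for age in ("P7", "P14")
        },
        index=dev.index,
    )
    corr = developmental_correlation(query, dev, activated)
    sio.write_expression_matrix(
        config.RESULTS / "developmental_correlation.tsv", corr,
        {"gene_set": "dependent_activated", "n_genes": len(activated)},
    )
    for sample, row in corr.iterrows():
        print(f"{sample}: best match {row.idxmax()} "
              f"(r = {row.max():.3f}); full row: "
              + ", ".join(f"{age} {r:.3f}" for age, r in row.items()))


if __name__ == "__main__":
    main()
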