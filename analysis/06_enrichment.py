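#!/usr/bin/env python
"""Term enrichment of the differentially abundant proteins.

Uses the synthetic annotation table derived from the generator's truth (one
term marks the proteins carrying a true tissue effect, the rest are random),
so the differentially abundant set is expected to enrich the true-response
term and nothing else.

Reads results/data/ and results/dap.tsv; writes results/enrichment.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from homeoprot import enrichment, simulate

DATA = Path("results/data")


def main() -> None:
    truth = simulate.TruthTable.from_json(DATA / "truth.json")
    annot = simulate.simulate_annotations(truth, np.random.default_rng(1))
    dap = pd.read_csv("results/dap.tsv", sep="\t", index_col=0)
    foreground = sorted(dap.index[dap["status"].isin(["up", "down"])])
    background = sorted(dap.index)
    out = enrichment.fisher_enrich(foreground, background, annot)
    out.to_csv("results/enrichment.tsv", sep="\t", index=False, na_rep="NA",
               float_format="%.6g")
    print(f"{len(foreground)} foreground vs {len(background)} background proteins")
    print(f"{len(out)} terms tested; top rows:")
    print(out.head(3).to_string(index=False))
    sig = out[out["q_value"] <= 0.05]
    print(f"{len(sig)} terms significant at q <= 0.05: "
          f"{', '.join(sig['term_id']) or 'none'}")
    print("-> results/enrichment.tsv")


if __name__ == "__main__":
    main()
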