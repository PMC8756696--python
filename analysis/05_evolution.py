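#!/usr/bin/env python
"""Ka/Ks estimation for the recovered pairs and rate-abundance correlations.

Protein pairs are globally aligned, back-translated to codon alignments, and
Ka/Ks estimated by Nei-Gojobori counting with Jukes-Cantor correction.
Low-divergence results (Ka/Ks < 0.001 or Ka = 0) are excluded; kept pairs
are classified as purifying / neutral / positive, and Ka/Ks is rank-
correlated with mean pair abundance and with differential abundance.

Reads results/data/ and results/pairs.tsv; writes results/kaks.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from homeoprot import abundance, evolution, homology, pipeline

DATA = Path("results/data")


def main() -> None:
    proteins = homology.read_fasta(DATA / "proteins.faa", "protein")
    cds = homology.read_fasta(DATA / "cds.fna", "cds")
    prot_by_id = {p.id: p for p in proteins}
    cds_by_id = {c.id: c.sequence for c in cds}
    pairs = pd.read_csv("results/pairs.tsv", sep="\t")
    aligner = homology.make_aligner()

    rows, results = [], {}
    for r in pairs.itertuples(index=False):
        row_a, row_b = homology.aligned_rows(
            prot_by_id[r.id_a], prot_by_id[r.id_b], aligner
        )
        pa = evolution.ProteinAlignment(r.id_a, r.id_b, row_a, row_b)
        res = evolution.kaks_counting(
            evolution.backtranslate(pa, cds_by_id[r.id_a], cds_by_id[r.id_b])
        )
        results[(r.id_a, r.id_b)] = (r.relation, res)
        rows.append((r.id_a, r.id_b, r.relation, res.ka, res.ks, res.ratio,
                     res.reason, res.selection))
    out = pd.DataFrame(rows, columns=["id_a", "id_b", "relation", "ka", "ks",
                                      "ratio", "excluded_reason", "selection"])
    out.to_csv("results/kaks.tsv", sep="\t", index=False, na_rep="NA",
               float_format="%.6g")

    kept = [(rel, res) for rel, res in results.values() if not res.excluded]
    print(f"{len(results)} pairs estimated, {len(kept)} kept after exclusions")
    for relation in ("paralog", "homeolog"):
        vals = [res.ratio for rel, res in kept if rel == relation]
        if vals:
            print(f"mean Ka/Ks ({relation}): {np.mean(vals):.3f} over {len(vals)} pairs")
    n_pos = sum(res.selection == "positive" for _, res in kept)
    print(f"{n_pos} pairs under positive selection; the rest purifying/neutral")

    design = pipeline._design_from_header(DATA / "quant.tsv")
    qm = abundance.read_quant(DATA / "quant.tsv", design)
    dap = pd.read_csv("results/dap.tsv", sep="\t", index_col=0)
    for relation in ("paralog", "homeolog"):
        means = abundance.mean_abundance(qm, "leaf")
        ratios, abund = [], []
        for (a, b), (rel, res) in results.items():
            if rel != relation or res.excluded:
                continue
            ratios.append(res.ratio)
            abund.append(np.nanmean([means.get(a, np.nan), means.get(b, np.nan)]))
        corr = evolution.correlate_rate_abundance(ratios, abund)
        if not corr["insufficient_data"]:
            print(
                f"Ka/Ks vs leaf abundance ({relation}): rho={corr['rho']:+.3f}, "
                f"p={corr['p_value']:.3f}, n={corr['n']}"
            )
    print("-> results/kaks.tsv")


if __name__ == "__main__":
    main()
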