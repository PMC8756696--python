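#!/usr/bin/env python
"""Homeolog abundance bias, paralog abundance divergence, cross-tissue
overlap and copy-level differential-abundance categories.

Reads results/data/, results/pairs.tsv and results/dap.tsv; writes
results/bias.tsv, results/divergence.tsv and results/categories.tsv.
"""

from pathlib import Path

import pandas as pd

from homeoprot import abundance, patterns, pipeline
from homeoprot.homology import AlignmentHit, HomologPair, read_fasta

DATA = Path("results/data")


def load_pairs(path: Path, lengths: dict) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        HomologPair(
            r.id_a, r.id_b, r.relation,
            AlignmentHit(r.id_a, r.id_b, r.pident,
                         int(r.coverage_a * lengths[r.id_a]),
                         lengths[r.id_a], lengths[r.id_b], 0.0),
        )
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    proteins = read_fasta(DATA / "proteins.faa", "protein")
    lengths = {p.id: len(p.sequence) for p in proteins}
    sub = {p.id: p.sub_genome for p in proteins}
    pairs = load_pairs(Path("results/pairs.tsv"), lengths)
    design = pipeline._design_from_header(DATA / "quant.tsv")
    qm = abundance.read_quant(DATA / "quant.tsv", design)
    dap = pd.read_csv(Path("results/dap.tsv"), sep="\t", index_col=0)

    bias, divergence = {}, {}
    for tissue in ("leaf", "root"):
        bias[tissue] = patterns.homeolog_bias(pairs, qm, tissue, sub)
        divergence[tissue] = patterns.paralog_divergence(pairs, qm, tissue)
    pd.concat(bias.values()).to_csv("results/bias.tsv", sep="\t", index=False,
                                    na_rep="NA", float_format="%.6g")
    pd.concat(divergence.values()).to_csv("results/divergence.tsv", sep="\t",
                                          index=False, na_rep="NA",
                                          float_format="%.6g")
    counts = patterns.compare_bias_counts(bias)
    for tissue, c in counts["per_tissue"].items():
        print(
            f"{tissue}: {c['n_A_biased']} A-biased, {c['n_B_biased']} B-biased "
            f"homeolog pairs (A:B binomial p={c['binomial_p']:.3f})"
        )
    print(f"A:B split across tissues: Fisher p={counts['cross_tissue_fisher_p']:.3f}")
    overlap = patterns.cross_tissue_overlap(divergence["leaf"], divergence["root"], qm)
    print(
        f"divergent paralog pairs: {overlap['n_positive_tissue_1']} leaf, "
        f"{overlap['n_positive_tissue_2']} root, {overlap['n_common']} common"
    )

    cats, summary = patterns.copy_level_categories(pairs, dap)
    cats.to_csv("results/categories.tsv", sep="\t", index=False, na_rep="NA",
                float_format="%.6g")
    for relation in ("homeolog", "paralog"):
        s = summary[relation]
        if s["asymmetric_percent"] is not None:
            print(
                f"{relation}: {s['asymmetric_count']}/{s['asymmetric_total']} "
                f"informative pairs asymmetric ({s['asymmetric_percent']}%)"
            )
        else:
            print(f"{relation}: no pairs with a differentially abundant member")
    print("-> results/bias.tsv, results/divergence.tsv, results/categories.tsv")


if __name__ == "__main__":
    main()
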