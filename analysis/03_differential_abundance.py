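#!/usr/bin/env python
"""Missingness summary and leaf-vs-root differential abundance.

Per-replicate missing fractions are compared between tissues with an exact
Mann-Whitney test; proteins are differentially abundant when
|log2(mean leaf / mean root)| > 2 (strictly) with t-test p <= 0.05 on log2
replicate values.

Reads results/data/quant.tsv, writes results/dap.tsv.
"""

from pathlib import Path

from homeoprot import abundance, pipeline

DATA = Path("results/data")


def main() -> None:
    design = pipeline._design_from_header(DATA / "quant.tsv")
    qm = abundance.read_quant(DATA / "quant.tsv", design)
    miss = abundance.summarize_missingness(qm)
    for tissue, rate in miss["mean_missing"].items():
        print(f"mean miss rate {tissue}: {100 * rate:.2f}%")
    print(
        f"tissue missingness comparison: U={miss['mannwhitney_u']:.1f}, "
        f"p={miss['p_value']:.3f} "
        f"({'not ' if miss['p_value'] > 0.05 else ''}significant)"
    )
    dap = abundance.differential_abundance(qm, "leaf", "root")
    abundance.write_dap(dap, Path("results/dap.tsv"))
    n_up = (dap["status"] == "up").sum()
    n_down = (dap["status"] == "down").sum()
    print(
        f"{len(dap)} proteins tested: {n_up + n_down} differentially abundant "
        f"({n_up} up in leaf, {n_down} up in root)"
    )
    print("-> results/dap.tsv")


if __name__ == "__main__":
    main()
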