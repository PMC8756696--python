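#!/usr/bin/env python
"""Identify paralog and homeolog pairs from the simulated proteome.

All-vs-all global protein alignment, the three retention filters (coverage
> 80% of each sequence, identity > 80%, E-value <= 1e-10 when present), and
reciprocal-best-hit pairing within the two relation classes.  Compares the
recovered pairs with the generator's truth.

Reads results/data/, writes results/pairs.tsv.
"""

from pathlib import Path

from homeoprot import homology, simulate

DATA = Path("results/data")


def main() -> None:
    proteins = homology.read_fasta(DATA / "proteins.faa", "protein")
    truth = simulate.TruthTable.from_json(DATA / "truth.json")
    hits = homology.all_vs_all_hits(proteins)
    kept = homology.filter_hits(hits)
    pairs = homology.pair_homologs(kept, {p.id: p.sub_genome for p in proteins})
    homology.write_pairs(pairs, Path("results/pairs.tsv"))
    found = {(p.id_a, p.id_b) for p in pairs}
    expected = truth.pair_keys()
    print(f"{len(hits)} candidate hits, {len(kept)} pass the filters")
    print(
        f"{len(pairs)} pairs "
        f"({sum(p.relation == 'homeolog' for p in pairs)} homeolog, "
        f"{sum(p.relation == 'paralog' for p in pairs)} paralog)"
    )
    print(
        f"truth recovery: {len(found & expected)}/{len(expected)} recovered, "
        f"{len(found - expected)} spurious"
    )
    print("-> results/pairs.tsv")


if __name__ == "__main__":
    main()
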