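# homeoprot

Homolog abundance patterns in allotetraploid proteomes.

Allotetraploids such as cultivated peanut (*Arachis hypogaea*, AABB) carry two
diverged sub-genomes, so most genes exist as a **homeolog** pair (one copy per
sub-genome) and some additionally as within-sub-genome **paralogs**. Given a
quantitative proteome (e.g. a TMT experiment over two tissues with three
biological replicates), the questions this package answers are:

- which proteins are differentially abundant between tissues;
- which homeolog pairs show **sub-genome abundance bias** and which paralog
  pairs show **abundance divergence**, per tissue and across tissues;
- whether one or both members of a pair respond to tissue (single- vs
  double-copy differential abundance — the single-copy case is "asymmetric
  abundance", a signature of functional divergence between copies);
- what selective pressure (Ka/Ks) acts on each pair and whether it
  anticorrelates with abundance (the E–R anticorrelation).

Because the interesting statistics are all filter counts and classification
rules, the package ships a synthetic allotetraploid proteome generator with a
full ground-truth table, so every classifier can be scored on parameter
recovery and null calibration without external data.

## Methods in brief

- **Pairing.** Pairwise protein hits (external 12-column tabular files, or the
  built-in global aligner: BLOSUM62, affine gaps 10/1) are retained when the
  alignment covers > 80% of *each* sequence, identity > 80%, and E ≤ 1e-10;
  pairs are reciprocal best hits within each relation class (within
  sub-genome = paralog, A×B = homeolog).
- **Differential abundance.** log2FC = log2(mean leaf / mean root) over
  replicates; a protein is called when |log2FC| > 2 (strict) and two-sided
  t-test p ≤ 0.05 on log2 replicate values (Welch by default).
- **Bias / divergence.** Homeolog bias uses the signed log2(A/B) ratio with
  the same (2, 0.05) rule; paralog divergence uses the absolute ratio.
- **Ka/Ks.** Protein alignments are back-translated onto the CDS
  (codon-sized gaps), then Nei–Gojobori counting: per-codon synonymous site
  fractions from single-base mutational opportunity, pathway-averaged
  difference counts (stop-codon paths excluded), Jukes–Cantor correction.
  Pairs with Ka/Ks < 0.001 or Ka = 0 are excluded as uninformatively
  diverged; Ka/Ks < 1, = 1, > 1 classify purifying / neutral / positive
  selection.
- **Enrichment.** One-sided hypergeometric (Fisher) tests per term with
  Benjamini–Hochberg adjustment.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic dataset and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_pair_homologs.py
python analysis/03_differential_abundance.py
python analysis/04_homolog_patterns.py
python analysis/05_evolution.py
python analysis/06_enrichment.py
```

Output of the first runs (seed 42):

```
simulated 144 proteins in 60 families
true pairs: 60 homeolog, 24 paralog; 25 biased

113 candidate hits, 100 pass the filters
84 pairs (60 homeolog, 24 paralog)
truth recovery: 84/84 recovered, 0 spurious

mean miss rate leaf: 3.01%
mean miss rate root: 3.47%
tissue missingness comparison: U=4.0, p=1.000 (not significant)
144 proteins tested: 12 differentially abundant (7 up in leaf, 5 up in root)

leaf: 14 A-biased, 7 B-biased homeolog pairs (A:B binomial p=0.189)
root: 12 A-biased, 6 B-biased homeolog pairs (A:B binomial p=0.238)
homeolog: 10/10 informative pairs asymmetric (100.0%)

mean Ka/Ks (paralog): 0.210 over 24 pairs
mean Ka/Ks (homeolog): 0.206 over 60 pairs
0 pairs under positive selection; the rest purifying/neutral
```

Reading the output: every true pair survives the alignment filters and RBH
pairing; the ~3% per-replicate missing rates are statistically
indistinguishable between tissues; the 12 differentially abundant proteins are
the injected tissue effects; the A/B bias counts recover the injected 8-fold
biases without a significant sub-genome skew (none was simulated); and the
mean Ka/Ks ≈ 0.21 matches the generator's omega range (0.05–0.4, mean 0.225),
i.e. purifying selection.

The same pipeline runs end-to-end programmatically or from the shell:

```python
from homeoprot import pipeline, simulate
summary = pipeline.run_pipeline(
    pipeline.RunConfig(outdir="results/run", seed=42,
                       sim=simulate.SimulationConfig())
)
```

```bash
homeoprot run --out results/run --seed 42     # same thing; see homeoprot --help
```

Real data enter through `RunConfig(proteins_fasta=..., cds_fasta=...,
quant_tsv=..., hits_tsv=...)` with sub-genome labels taken from chromosome
names (`chrA01…/chrB01…` by default; `Arahy.01–.20` rules included).

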