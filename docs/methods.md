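# Methods

This note documents the models and procedures homeoprot implements, the
defaults and why, what the synthetic generator does and does not emulate, and
the numerical choices at the edges.

## The analysis model

The unit of analysis is a **homolog pair** of quantified proteins in an
allotetraploid: a *homeolog* pair has one member on each sub-genome (A and
B); a *paralog* pair arose by duplication within one sub-genome. All headline
statistics are counts of pairs or proteins passing strict rule-based
classifiers:

| classifier | statistic | rule |
|---|---|---|
| differential abundance | log2(mean leaf / mean root) | \|log2FC\| > 2 **and** p ≤ 0.05 |
| homeolog bias | log2(mean A / mean B) within a tissue | signed ratio > 2 (A) or < −2 (B), p ≤ 0.05 |
| paralog divergence | \|log2(copy1 / copy2)\| within a tissue | ratio > 2, p ≤ 0.05 |

All inequalities on the log2 ratio are strict, and the p rule is a
conjunction — a 4-fold change with p = 0.2 is *not* called. Means are
arithmetic means of raw abundances over present replicates; the t-tests run
on log2 replicate values, where the threshold lives and where lognormal
replicate noise is additive.

**t-test variant.** The default is Welch (unequal variances), the robust
choice at n = 3 when nothing is known about the two groups' variances. The
pooled-variance variant is available (`equal_var=True`). At n = 3 per group
Welch is conservative: with homoscedastic Gaussian noise its empirical
type-I error at nominal 0.05 is ≈ 0.03, because the Welch–Satterthwaite
degrees of freedom are noisy at this sample size. The pooled test is exactly
calibrated in that regime. The test suite checks both statements; users who
need exact nominal calibration under a homoscedastic assumption should set
the flag.

**Degenerate variance.** When both groups are constant and equal the test is
0/0; we define p := 1 (no evidence of a difference). Constant but different
groups give p := 0 (the statistic diverges). Proteins with fewer than two
present replicates in either group are `untestable` and excluded from all
denominators — no pseudocounts, no imputation.

**Multiple testing.** The headline path uses raw p ≤ 0.05, which is the
classification rule being studied; Benjamini–Hochberg q-values are available
by flag on the DA caller and are always attached to enrichment results.

## Pairing

Hits are filtered by three criteria, all strict: alignment length > 80% of
the query length **and** > 80% of the subject length; percent identity > 80;
E-value ≤ 1e-10 when present (the built-in aligner produces none).
"Similarity" is read as the identity column of the 12-column tabular format.

Pairing is reciprocal best hit (RBH) by score within each relation class,
computed on an undirected graph (both hit directions collapsed to the
maximum score per unordered pair), so symmetric built-in alignments and
two-directional external tables behave identically. Ties break to the
lexicographically smaller partner id; pair ids are stored smaller-first.
Proteins whose chromosome matches no sub-genome rule are `unassigned` and
take part in no relation class. An `all` mode emits every passing pair
instead of RBH for sensitivity analyses.

The built-in aligner is a global (end-gap-penalized) BLOSUM62 alignment with
affine gap costs 10 (open) / 1 (extend) — conventional protein defaults. At
pipeline scale, all-vs-all alignment is prescreened by shared 4-mers
(default ≥ 8 shared): unrelated ~300-residue proteins essentially never pass
the prescreen, and anything the prescreen drops could not reach the > 80%
identity filter. The aligner is validated against an independent
dynamic-programming oracle in the tests.

## Ka/Ks

The estimator is Nei–Gojobori counting with Jukes–Cantor correction,
chosen because it is fully auditable — every component is checkable by
exhaustive enumeration, which the test suite does for all 61×61 sense-codon
pairs:

- **Sites.** For each codon, each of the nine single-base changes
  contributes 1/3 site; a change is synonymous iff it preserves the amino
  acid. Changes to stop codons count as nonsynonymous, so S + N = 3 exactly
  per codon. Site totals are averaged over the two sequences.
- **Differences.** For a differing codon pair, all orderings of the
  differing positions are enumerated; orderings that pass through a stop
  codon are excluded, and synonymous/nonsynonymous step counts are averaged
  over the remainder. If every ordering is blocked, steps between sense
  codons are averaged over all orderings and the pair is flagged.
- **Correction.** d = −3/4 ln(1 − 4p/3); p = 0 maps to exactly 0, p ≥ 3/4
  is saturated and invalidates the estimate.

Codon columns containing gaps, ambiguity codes or stops are skipped.
Pairs with Ka/Ks < 0.001 or Ka = 0 are excluded as too weakly diverged to
classify; Ks = 0 (undefined ratio) falls under the same low-divergence
exclusion. Selection classes on kept pairs: ratio < 1 purifying, > 1
positive, = 1 neutral within 1e-9 (the trichotomy is exact; floating point
needs a tolerance).

Protein alignments for back-translation come from the same built-in global
aligner (for two sequences this is equivalent to running a standard MSA tool
pairwise); externally aligned FASTA pairs are also accepted. Back-translation
verifies codon-by-codon that each CDS translates to its aligned protein
(trailing stops trimmed) and reports the first mismatching residue.

Rate–abundance correlations are Spearman rank correlations between kept
pairs' Ka/Ks and (a) the pair's mean abundance per tissue and (b) the pair's
mean |log2FC| between tissues; fewer than 3 complete observations yields a
flagged, numberless report.

## The synthetic generator

`SimulationConfig` defaults are the study conditions the package assumes
throughout its tests:

| parameter | default | meaning |
|---|---|---|
| `n_families` | 60 | gene families (one A copy + one B copy each) |
| `paralog_fraction` | 0.4 | exact fraction of families with a same-sub-genome duplicate |
| `n_codons` | 300 | CDS length (~average plant protein) |
| `omega_range` | (0.05, 0.4) | true dN/dS per family, uniform (purifying regime) |
| `ks_target` | 0.2 | expected pairwise synonymous divergence |
| `tissues`, `n_replicates` | (leaf, root), 3 | the quantification design |
| `bias_effect_log2` | 3.0 | true bias offset (8-fold) on biased pairs |
| `biased_fraction` | 0.3 | exact fraction of pairs given a true bias |
| `noise_sigma` | 0.2 | replicate noise SD on log2 scale (tight TMT replicates) |
| `missing_rate` | 0.025 | per-cell missing probability (≈ the 2.5% regime of real runs) |
| `da_fraction`, `da_effect_log2` | 0.08, 3.0 | true tissue effects per protein |
| `base_log2_mean/sd` | 10, 1.5 | baseline log2 abundance distribution |
| `er_coupling` | 0 | > 0 couples omega to family abundance (E–R anticorrelation) |

Sequence evolution: ancestral codons uniform over the 61 sense codons;
single-nucleotide proposals uniform over sites and target bases; synonymous
proposals always accepted, nonsynonymous with probability omega, stop-creating
never — i.e. exactly the mutational model the NG86 estimator assumes, which
is what makes recovery tests interpretable. With uniform proposals the
per-proposal synonymous rate per synonymous site is 3/(9L) independent of
composition, so `3·L·ks_target` proposals (split across the two lineages)
give the target synonymous divergence in expectation.

Abundance: log2 abundance = family baseline + tissue effect + bias offset +
N(0, σ); cells are missing completely at random. Effects are
**compositional**: a homeolog bias is a sub-genome-level effect (every copy
of the favoured sub-genome in the family is offset), and a paralog bias
falls entirely on the duplicate copy, so a biased pair never shifts the
ratio of an overlapping pair and the truth table stays exactly recoverable.
Fractions (`paralog_fraction`, `biased_fraction`, `da_fraction`) select
exact counts, not Bernoulli draws — the counts are design, not noise.

What the generator does **not** emulate: peptide-level effects (digestion,
TMT reporter compression, ratio distortion), intensity-dependent missingness
(real proteomics dropout is left-censored, not MCAR), shared-peptide
quantification interference between close homeologs, isoforms, and
family-size distributions beyond one duplicate. Passing recovery tests
therefore demonstrates the *classifiers* behave as specified under the
assumed noise model, not that the thresholds are optimal for real TMT data.

## Statistical tests at the edges

- **Missingness comparison.** Per-replicate missing fractions are compared
  between tissues with a two-sided Mann–Whitney test. For small designs
  (≤ 200 arrangements, e.g. 3 vs 3) the null distribution of U is enumerated
  over all group assignments, which is exact even under ties; larger designs
  fall back to scipy. With 3 vs 3 the smallest attainable two-sided p is 0.1,
  so the comparison can never be "significant" at 0.05 — matching the
  qualitative use of this test as a data-quality check. All rates equal
  (everything zero, say) is degenerate and reports p = 1.
- **Bias-count comparisons.** The A:B split within a tissue gets an exact
  two-sided binomial test against 0.5; the split across two tissues a 2×2
  Fisher exact test. (Which test the original analyses used is never stated
  in this literature; exact tests are the defensible choice at these counts.)
- **Cross-tissue overlap.** Pairs untestable in either tissue leave the
  denominator. Pairs called in both tissues get a paired two-sided Wilcoxon
  signed-rank comparison of mean pair abundance between tissues.
- **Enrichment.** One-sided hypergeometric upper tail per term
  (over-representation), terms smaller than `min_term_size=2` skipped, BH
  step-up across tested terms (disable with `bh_adjust=False`).

## Design choices that were genuinely open

- **RBH vs all passing pairs**: RBH is the default because it yields the
  at-most-one-partner-per-class structure the pair classifiers assume; the
  `all` mode exists because the filter counts themselves are sometimes the
  quantity of interest.
- **Asymmetric-abundance denominator**: the single-copy fraction is reported
  among pairs with ≥ 1 differentially abundant member (the "informative"
  pairs); pairs with no DA member say nothing about asymmetry.
- **Sub-genome assignment** is an ordered regex rule list
  (first match wins), with defaults `chrA*/chrB*` and an alternative set for
  *Arachis* `Arahy.01–.10` → A, `.11–.20` → B; anything unmatched is
  `unassigned` and excluded from pairing rather than guessed.
- **Problem sizes in tests**: recovery and calibration experiments use
  60–1000 families and 10–200 replicate runs — large enough that binomial
  tolerance bands are meaningful, small enough that the whole suite runs in
  seconds.

## Known limitations

- NG86 underestimates omega slightly under this generator (≈ 4% relative):
  the simulator rejects stop-creating mutations while the site counter books
  stop-adjacent changes as nonsynonymous opportunity. This is inherent to
  the counting convention, visible in the recovery tests, and well inside
  their tolerances.
- One hit row = one alignment; HSP stitching is out of scope, so coverage
  filters on fragmented external hits are conservative.
- No codon-model ML estimators (branch/site models), no synteny-aware
  homeolog calling, no multi-genome orthology graphs.
- The enrichment module does no GO DAG propagation; terms are taken as given.
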