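"""End-to-end orchestration: simulate (or load) -> pair homologs ->
differential abundance -> bias / divergence -> copy-level categories ->
Ka/Ks -> rate-abundance correlations -> optional enrichment.

Every stage logs its input/output row counts, writes its table under the
output directory, and contributes to a machine-readable summary.json whose
counts equal the written tables' row counts.  Re-running with the same
configuration and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, enrichment, evolution, homology, patterns, simulate

log = logging.getLogger("homeoprot")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``sim`` drives a synthetic dataset, or ``proteins_fasta`` /
    ``cds_fasta`` / ``quant_tsv`` (+ optional ``hits_tsv``) point at real
    inputs.  Thresholds default to the analysis' headline rules.
    """

    outdir: str = "results/run"
    seed: int = 0
    sim: simulate.SimulationConfig | None = None
    proteins_fasta: str | None = None
    cds_fasta: str | None = None
    quant_tsv: str | None = None
    hits_tsv: str | None = None
    annotations_tsv: str | None = None
    lfc_threshold: float = 2.0
    alpha: float = 0.05
    identity: float = 80.0
    coverage: float = 0.80
    e_value: float = 1e-10
    kaks_exclusion: float = 1e-3
    pairing_mode: str = "rbh"
    subgenome_rules: tuple[tuple[str, str], ...] = homology.DEFAULT_SUBGENOME_RULES

    def validate(self) -> None:
        for name in ("lfc_threshold", "identity", "coverage", "e_value",
                     "kaks_exclusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sim is None and not (self.proteins_fasta and self.quant_tsv):
            raise ValueError("either a simulation config or input paths required")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage(name: str, n_in: int | None, n_out: int) -> None:
    log.info("stage %-22s in=%s out=%d", name, "-" if n_in is None else n_in, n_out)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and write all outputs.

    Returns the summary dictionary (also written as summary.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- stage: inputs -------------------------------------------------------
    truth = None
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        proteins, cds_records, truth = simulate.simulate_families(sim_cfg)
        qm = simulate.simulate_quant(proteins, truth, sim_cfg)
        simulate.write_dataset(outdir, proteins, cds_records, truth, qm, sim_cfg)
    else:
        proteins = homology.read_fasta(
            config.proteins_fasta, "protein", config.subgenome_rules
        )
        cds_records = (
            homology.read_fasta(config.cds_fasta, "cds", config.subgenome_rules)
            if config.cds_fasta
            else []
        )
        design = _design_from_header(config.quant_tsv)
        qm = abundance.read_quant(config.quant_tsv, design)
    _stage("inputs", None, len(proteins))
    summary["n_proteins"] = len(proteins)
    summary["n_quantified"] = int(len(qm.values))
    tissues = qm.tissues
    if len(tissues) != 2:
        raise ValueError("pipeline expects exactly two tissues")
    t1, t2 = tissues

    # --- stage: missingness --------------------------------------------------
    miss = abundance.summarize_missingness(qm)
    summary["missingness"] = miss
    _stage("missingness", len(qm.values), len(miss["per_sample_missing"]))

    # --- stage: homolog pairing ---------------------------------------------
    sub_genomes = {p.id: p.sub_genome for p in proteins}
    if config.hits_tsv:
        lengths = {p.id: len(p.sequence) for p in proteins}
        hits = homology.read_alignment_table(config.hits_tsv, lengths)
    else:
        hits = homology.all_vs_all_hits(proteins)
    thresholds = homology.FilterThresholds(
        coverage=config.coverage, identity=config.identity, e_value=config.e_value
    )
    kept_hits = homology.filter_hits(hits, thresholds)
    pairs = homology.pair_homologs(kept_hits, sub_genomes, mode=config.pairing_mode)
    homology.write_pairs(pairs, outdir / "pairs.tsv")
    _stage("pair_homologs", len(hits), len(pairs))
    summary["n_hits"] = len(hits)
    summary["n_hits_passing"] = len(kept_hits)
    summary["n_paralog_pairs"] = sum(p.relation == "paralog" for p in pairs)
    summary["n_homeolog_pairs"] = sum(p.relation == "homeolog" for p in pairs)

    # --- stage: differential abundance --------------------------------------
    dap = abundance.differential_abundance(
        qm, t1, t2, lfc_threshold=config.lfc_threshold, alpha=config.alpha
    )
    abundance.write_dap(dap, outdir / "dap.tsv")
    _stage("differential_abundance", len(qm.values), len(dap))
    summary["n_da"] = int(dap["status"].isin(patterns.DA_STATUSES).sum())
    summary["n_da_up"] = int((dap["status"] == "up").sum())
    summary["n_da_down"] = int((dap["status"] == "down").sum())

    # --- stage: divergence / bias per tissue --------------------------------
    divergence = {}
    bias = {}
    for tissue in tissues:
        divergence[tissue] = patterns.paralog_divergence(
            pairs, qm, tissue, threshold=config.lfc_threshold, alpha=config.alpha
        )
        bias[tissue] = patterns.homeolog_bias(
            pairs, qm, tissue, sub_genomes,
            threshold=config.lfc_threshold, alpha=config.alpha,
        )
    pd.concat(divergence.values()).to_csv(
        outdir / "divergence.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.6g",
    )
    pd.concat(bias.values()).to_csv(
        outdir / "bias.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    summary["divergent_pairs"] = {
        t: int((divergence[t]["status"] == "divergent").sum()) for t in tissues
    }
    summary["bias_counts"] = patterns.compare_bias_counts(bias)
    summary["divergence_overlap"] = patterns.cross_tissue_overlap(
        divergence[t1], divergence[t2], qm
    )
    summary["bias_overlap"] = patterns.cross_tissue_overlap(bias[t1], bias[t2], qm)
    _stage("patterns", len(pairs), sum(len(v) for v in divergence.values()))

    # --- stage: copy-level categories ---------------------------------------
    categories, cat_summary = patterns.copy_level_categories(pairs, dap)
    categories.to_csv(
        outdir / "categories.tsv", sep="\t", index=False, na_rep="NA",
        float_format="%.6g",
    )
    summary["copy_categories"] = cat_summary
    _stage("copy_categories", len(pairs), len(categories))

    # --- stage: Ka/Ks --------------------------------------------------------
    cds_by_id = {c.id: c.sequence for c in cds_records}
    prot_by_id = {p.id: p for p in proteins}
    aligner = homology.make_aligner()
    kaks_rows = []
    results = []
    for pair in pairs:
        if pair.id_a not in cds_by_id or pair.id_b not in cds_by_id:
            continue
        row_a, row_b = homology.aligned_rows(
            prot_by_id[pair.id_a], prot_by_id[pair.id_b], aligner
        )
        pa = evolution.ProteinAlignment(pair.id_a, pair.id_b, row_a, row_b)
        ca = evolution.backtranslate(pa, cds_by_id[pair.id_a], cds_by_id[pair.id_b])
        res = evolution.kaks_counting(ca)
        results.append((pair.relation, res))
        kaks_rows.append(
            (
                pair.id_a, pair.id_b, pair.relation, res.ka, res.ks, res.ratio,
                res.n_sites_n, res.n_sites_s, res.reason, res.selection,
            )
        )
    kaks_df = pd.DataFrame(
        kaks_rows,
        columns=["id_a", "id_b", "relation", "ka", "ks", "ratio",
                 "sites_n", "sites_s", "excluded_reason", "selection"],
    )
    kaks_df.to_csv(
        outdir / "kaks.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    kept, excluded = evolution.apply_exclusions([r for _, r in results])
    summary["kaks"] = {
        "n_pairs_estimated": len(results),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "n_positive_selection": sum(r.selection == "positive" for r in kept),
        "n_purifying_selection": sum(r.selection == "purifying" for r in kept),
        "n_neutral": sum(r.selection == "neutral" for r in kept),
    }
    for relation in ("paralog", "homeolog"):
        vals = [
            res.ratio for rel, res in results if rel == relation and not res.excluded
        ]
        summary["kaks"][f"mean_ratio_{relation}"] = (
            float(np.mean(vals)) if vals else None
        )
    _stage("kaks", len(pairs), len(kaks_df))

    # --- stage: rate-abundance correlations ---------------------------------
    correlations: dict = {}
    dap_abs = dap["log2fc"].abs()
    for relation in ("paralog", "homeolog"):
        correlations[relation] = {}
        rel_pairs = [
            (pair, res)
            for pair, (rel, res) in zip(pairs, results)
            if rel == relation and not res.excluded
        ]
        for tissue in tissues:
            means = abundance.mean_abundance(qm, tissue)
            ratios, abund = [], []
            for pair, res in rel_pairs:
                ratios.append(res.ratio)
                abund.append(
                    np.nanmean([means.get(pair.id_a, np.nan),
                                means.get(pair.id_b, np.nan)])
                )
            correlations[relation][f"abundance_{tissue}"] = (
                evolution.correlate_rate_abundance(ratios, abund)
            )
        ratios, diffs = [], []
        for pair, res in rel_pairs:
            ratios.append(res.ratio)
            diffs.append(
                np.nanmean([dap_abs.get(pair.id_a, np.nan),
                            dap_abs.get(pair.id_b, np.nan)])
            )
        correlations[relation]["differential_abundance"] = (
            evolution.correlate_rate_abundance(ratios, diffs)
        )
    summary["correlations"] = correlations
    _stage("correlations", len(results), len(correlations))

    # --- stage: enrichment (optional) ---------------------------------------
    annot = None
    if config.annotations_tsv:
        annot = enrichment.read_annotations(config.annotations_tsv)
    elif truth is not None:
        annot = simulate.simulate_annotations(
            truth, np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        )
    if annot is not None:
        foreground = sorted(dap.index[dap["status"].isin(patterns.DA_STATUSES)])
        background = sorted(dap.index)
        enr = enrichment.fisher_enrich(foreground, background, annot)
        enr.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, na_rep="NA",
            float_format="%.6g",
        )
        summary["enrichment"] = {
            "n_terms_tested": int(len(enr)),
            "n_significant_q05": int((enr["q_value"] <= 0.05).sum()) if len(enr) else 0,
            "top_term": str(enr["term_id"].iloc[0]) if len(enr) else None,
        }
        _stage("enrichment", len(annot), len(enr))

    # --- truth-based recovery (synthetic runs only) -------------------------
    if truth is not None:
        summary["recovery"] = _score_recovery(truth, pairs, bias, tissues)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
    return summary


def _score_recovery(truth, pairs, bias, tissues) -> dict:
    """Compare recovered pairs and bias classes with the generator's truth."""
    true_pairs = truth.pair_keys()
    found = {(p.id_a, p.id_b) for p in pairs}
    out = {
        "n_true_pairs": len(true_pairs),
        "n_recovered_pairs": len(found & true_pairs),
        "n_spurious_pairs": len(found - true_pairs),
    }
    truly_biased = {
        (p.id_a, p.id_b): p.bias_direction
        for p in truth.pairs
        if p.relation == "homeolog" and p.bias_direction != "none"
    }
    n_hit = n_class = 0
    fp = unbiased_tested = 0
    for tissue in tissues:
        df = bias[tissue]
        for row in df.itertuples(index=False):
            key = (row.id_a, row.id_b)
            if key in truly_biased:
                n_class += 1
                expect = f"{truly_biased[key]}_biased"
                if row.bias_class == expect:
                    n_hit += 1
            elif row.bias_class in ("A_biased", "B_biased"):
                fp += 1
                unbiased_tested += 1
            elif row.bias_class == "unbiased":
                unbiased_tested += 1
    out["bias_true_classified"] = n_class
    out["bias_true_recovered"] = n_hit
    out["bias_recovery_rate"] = (n_hit / n_class) if n_class else None
    out["bias_false_positive_rate"] = (fp / unbiased_tested) if unbiased_tested else None
    return out


def _design_from_header(path) -> dict[str, tuple[str, int]]:
    """Infer (tissue, replicate) from <tissue>_<replicate> column names."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    design = {}
    for col in header[1:]:
        tissue, _, rep = col.rpartition("_")
        if not tissue or not rep.isdigit():
            raise ValueError(
                f"sample column {col!r} is not of the form <tissue>_<replicate>"
            )
        design[col] = (tissue, int(rep))
    return design
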