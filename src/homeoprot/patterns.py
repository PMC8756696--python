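"""Homolog abundance patterns: paralog divergence, homeolog bias, cross-tissue
overlap, bias-count comparisons and copy-level differential-abundance classes.

A paralogous pair is abundantly divergent in a tissue when
|log2(copy1/copy2)| of the tissue means exceeds 2 (strictly) at t-test
p <= 0.05.  A homeologous pair is biased towards sub-genome A (B) when the
signed log2(A/B) ratio exceeds 2 (is below -2) at p <= 0.05.  Copy-level
categories ask how many members of a pair are differentially abundant between
the two tissues: both (double copy), exactly one (single copy, "asymmetric
abundance"), or none.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import QuantMatrix, _welch_or_pooled, mean_abundance
from .homology import HomologPair

DA_STATUSES = ("up", "down")


def _member_log2_values(qm: QuantMatrix, pid: str, tissue: str) -> np.ndarray:
    if pid not in qm.values.index:
        return np.array([])
    vals = qm.values.loc[pid, qm.samples_for(tissue)].to_numpy(dtype=float)
    return np.log2(vals[~np.isnan(vals)])


def _pair_test(
    qm: QuantMatrix, id_1: str, id_2: str, tissue: str, equal_var: bool
) -> tuple[float, float] | None:
    """(log2 ratio of tissue means, t-test p) or None when untestable."""
    v1 = _member_log2_values(qm, id_1, tissue)
    v2 = _member_log2_values(qm, id_2, tissue)
    if len(v1) < 2 or len(v2) < 2:
        return None
    mean1 = float(np.mean(2.0 ** v1))
    mean2 = float(np.mean(2.0 ** v2))
    ratio = float(np.log2(mean1 / mean2))
    p = _welch_or_pooled(v1, v2, equal_var)
    return ratio, p


def paralog_divergence(
    pairs: Iterable[HomologPair],
    qm: QuantMatrix,
    tissue: str,
    threshold: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Classify paralogous pairs as divergent / not divergent in one tissue.

    Copy order is canonical (lexicographic) but irrelevant: only the absolute
    log2 ratio enters the rule.
    """
    rows = []
    for pair in pairs:
        if pair.relation != "paralog":
            continue
        res = _pair_test(qm, pair.id_a, pair.id_b, tissue, equal_var)
        if res is None:
            rows.append((pair.id_a, pair.id_b, tissue, np.nan, np.nan, "untestable"))
            continue
        ratio, p = res
        divergent = abs(ratio) > threshold and p <= alpha
        rows.append(
            (
                pair.id_a, pair.id_b, tissue, abs(ratio), p,
                "divergent" if divergent else "not_divergent",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "tissue", "abs_log2_ratio", "p_value", "status"],
    )


def homeolog_bias(
    pairs: Iterable[HomologPair],
    qm: QuantMatrix,
    tissue: str,
    sub_genomes: Mapping[str, str],
    threshold: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Classify homeologous pairs as A-biased / B-biased / unbiased in a tissue.

    The ratio is oriented sub-genome A over B regardless of the pair's
    canonical id order.
    """
    rows = []
    for pair in pairs:
        if pair.relation != "homeolog":
            continue
        sg = {sub_genomes.get(pair.id_a), sub_genomes.get(pair.id_b)}
        if sg != {"A", "B"}:
            raise ValueError(
                f"homeolog pair ({pair.id_a}, {pair.id_b}) lacks one member on "
                "each sub-genome"
            )
        id_A = pair.id_a if sub_genomes[pair.id_a] == "A" else pair.id_b
        id_B = pair.id_b if id_A == pair.id_a else pair.id_a
        res = _pair_test(qm, id_A, id_B, tissue, equal_var)
        if res is None:
            rows.append((pair.id_a, pair.id_b, tissue, np.nan, np.nan, "untestable"))
            continue
        ratio, p = res
        if ratio > threshold and p <= alpha:
            cls = "A_biased"
        elif ratio < -threshold and p <= alpha:
            cls = "B_biased"
        else:
            cls = "unbiased"
        rows.append((pair.id_a, pair.id_b, tissue, ratio, p, cls))
    return pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "tissue", "log2_ratio_ab", "p_value", "bias_class"],
    )


POSITIVE_CLASSES = {"divergent", "A_biased", "B_biased"}


def _positive_mask(df: pd.DataFrame) -> pd.Series:
    col = "status" if "status" in df.columns else "bias_class"
    return df[col].isin(POSITIVE_CLASSES)


def _testable_mask(df: pd.DataFrame) -> pd.Series:
    col = "status" if "status" in df.columns else "bias_class"
    return df[col] != "untestable"


def cross_tissue_overlap(
    results_t1: pd.DataFrame,
    results_t2: pd.DataFrame,
    qm: QuantMatrix | None = None,
) -> dict:
    """Overlap of divergent/biased calls between two tissues.

    Pairs untestable in either tissue leave the denominator.  When a quant
    matrix is supplied, the pairs called in both tissues get a paired
    two-sided Wilcoxon signed-rank comparison of their mean pair abundance
    between the tissues.
    """
    key = ["id_a", "id_b"]
    u1 = set(map(tuple, results_t1[key].itertuples(index=False)))
    u2 = set(map(tuple, results_t2[key].itertuples(index=False)))
    if u1 != u2:
        raise ValueError(
            f"pair universes differ between tissues: {sorted(u1 ^ u2)[:5]} ..."
        )
    t1 = results_t1.set_index(key)
    t2 = results_t2.set_index(key)
    testable = t1.index[_testable_mask(results_t1).values].intersection(
        t2.index[_testable_mask(results_t2).values]
    )
    pos1 = set(t1.index[_positive_mask(results_t1).values]) & set(testable)
    pos2 = set(t2.index[_positive_mask(results_t2).values]) & set(testable)
    common = pos1 & pos2
    out = {
        "tissue_1": str(results_t1["tissue"].iloc[0]) if len(results_t1) else "",
        "tissue_2": str(results_t2["tissue"].iloc[0]) if len(results_t2) else "",
        "n_testable_both": int(len(testable)),
        "n_positive_tissue_1": int(len(pos1)),
        "n_positive_tissue_2": int(len(pos2)),
        "n_common": int(len(common)),
        "n_only_tissue_1": int(len(pos1 - pos2)),
        "n_only_tissue_2": int(len(pos2 - pos1)),
    }
    if qm is not None and len(common) >= 3:
        tissue1 = out["tissue_1"]
        tissue2 = out["tissue_2"]
        m1 = mean_abundance(qm, tissue1)
        m2 = mean_abundance(qm, tissue2)
        x, y = [], []
        for id_a, id_b in sorted(common):
            x.append(np.nanmean([m1.get(id_a, np.nan), m1.get(id_b, np.nan)]))
            y.append(np.nanmean([m2.get(id_a, np.nan), m2.get(id_b, np.nan)]))
        x, y = np.asarray(x), np.asarray(y)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() >= 3 and np.any(x[ok] != y[ok]):
            res = stats.wilcoxon(x[ok], y[ok], alternative="two-sided")
            out["paired_abundance_test"] = {
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "n": int(ok.sum()),
            }
        else:
            out["paired_abundance_test"] = {
                "statistic": None, "p_value": 1.0, "n": int(ok.sum()),
            }
    return out


def compare_bias_counts(bias_results: Mapping[str, pd.DataFrame]) -> dict:
    """A-vs-B biased homeolog counts per tissue, an exact two-sided binomial
    test of each tissue's A:B split against 0.5, and (for two tissues) a 2x2
    Fisher exact test of the split across tissues."""
    out: dict = {"per_tissue": {}}
    tissues = list(bias_results)
    for tissue in tissues:
        df = bias_results[tissue]
        n_a = int((df["bias_class"] == "A_biased").sum())
        n_b = int((df["bias_class"] == "B_biased").sum())
        if n_a + n_b > 0:
            p = float(stats.binomtest(n_a, n_a + n_b, 0.5).pvalue)
        else:
            p = 1.0
        out["per_tissue"][tissue] = {
            "n_A_biased": n_a,
            "n_B_biased": n_b,
            "n_biased_total": n_a + n_b,
            "binomial_p": p,
        }
    if len(tissues) == 2:
        t1, t2 = tissues
        table = [
            [out["per_tissue"][t1]["n_A_biased"], out["per_tissue"][t1]["n_B_biased"]],
            [out["per_tissue"][t2]["n_A_biased"], out["per_tissue"][t2]["n_B_biased"]],
        ]
        if min(sum(table[0]), sum(table[1])) > 0:
            _, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            p = 1.0
        out["cross_tissue_fisher_p"] = float(p)
        out["table"] = table
    return out


def copy_level_categories(
    pairs: Iterable[HomologPair],
    dap: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Categorise pairs by how many members are differentially abundant.

    Both members DA -> double_copy; exactly one -> single_copy; none ->
    neither.  The summary reports, among pairs with at least one DA member,
    the single-copy ("asymmetric abundance") fraction as count/total and
    percent, and compares the pairs' |delta log2FC| between single- and
    double-copy categories with a two-sided Mann-Whitney test.
    """
    rows = []
    for pair in pairs:
        states = []
        deltas = []
        for pid in (pair.id_a, pair.id_b):
            if pid in dap.index:
                states.append(dap.loc[pid, "status"] in DA_STATUSES)
                deltas.append(dap.loc[pid, "log2fc"])
            else:
                states.append(False)
                deltas.append(np.nan)
        n_da = sum(states)
        category = {2: "double_copy", 1: "single_copy", 0: "neither"}[n_da]
        delta = abs(deltas[0] - deltas[1]) if not any(np.isnan(deltas)) else np.nan
        rows.append((pair.id_a, pair.id_b, pair.relation, n_da, category, delta))
    df = pd.DataFrame(
        rows,
        columns=["id_a", "id_b", "relation", "n_da_members", "category", "abs_delta_log2fc"],
    )
    summary: dict = {}
    for relation in ("paralog", "homeolog"):
        sub = df[df["relation"] == relation]
        n_single = int((sub["category"] == "single_copy").sum())
        n_double = int((sub["category"] == "double_copy").sum())
        n_neither = int((sub["category"] == "neither").sum())
        informative = n_single + n_double
        rel_summary = {
            "n_pairs": int(len(sub)),
            "n_single_copy": n_single,
            "n_double_copy": n_double,
            "n_neither": n_neither,
            "n_informative": informative,
        }
        rel_summary.update(asymmetric_fraction(n_single, informative))
        single_d = sub.loc[sub["category"] == "single_copy", "abs_delta_log2fc"].dropna()
        double_d = sub.loc[sub["category"] == "double_copy", "abs_delta_log2fc"].dropna()
        if len(single_d) >= 2 and len(double_d) >= 2:
            res = stats.mannwhitneyu(single_d, double_d, alternative="two-sided")
            rel_summary["delta_magnitude_test"] = {
                "u": float(res.statistic), "p_value": float(res.pvalue),
            }
        else:
            rel_summary["delta_magnitude_test"] = None
        summary[relation] = rel_summary
    return df, summary


def asymmetric_fraction(n_single: int, n_informative: int) -> dict:
    """Single-copy fraction among pairs with >= 1 DA member, as count/total and
    percent; degenerate (0 informative pairs) reports no fraction."""
    if n_informative == 0:
        return {"asymmetric_count": 0, "asymmetric_total": 0,
                "asymmetric_fraction": None, "asymmetric_percent": None}
    frac = n_single / n_informative
    return {
        "asymmetric_count": int(n_single),
        "asymmetric_total": int(n_informative),
        "asymmetric_fraction": frac,
        "asymmetric_percent": round(100.0 * frac, 2),
    }
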