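"""Term enrichment of a foreground protein set against a background.

One-sided (over-representation) Fisher exact tests per term via the
hypergeometric distribution, with optional Benjamini-Hochberg adjustment.
Annotations are a user-supplied table (protein_id, term_id, term_label);
retrieving them from GO/KEGG services is out of scope.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    if "term_label" not in df.columns:
        df["term_label"] = ""
    return df


def _term_sets(annotations: pd.DataFrame) -> dict[str, set[str]]:
    return {
        term: set(sub["protein_id"])
        for term, sub in annotations.groupby("term_id")
    }


def fisher_enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame | Mapping[str, Set[str]],
    min_term_size: int = 2,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Per-term one-sided hypergeometric enrichment test.

    For a term annotating K of the N background proteins, of which k fall in
    the n-protein foreground, p = P[X >= k], X ~ Hypergeom(N, K, n).  Rows are
    sorted by p (term id breaking ties); q_value is the BH step-up adjustment
    across tested terms.
    """
    fg = set(foreground)
    bg = set(background)
    offenders = sorted(fg - bg)
    if offenders:
        raise ValueError(f"foreground ids missing from background: {offenders}")
    if isinstance(annotations, pd.DataFrame):
        term_sets = _term_sets(annotations)
        labels = dict(
            annotations.drop_duplicates("term_id")[["term_id", "term_label"]]
            .itertuples(index=False)
        )
    else:
        term_sets = {t: set(s) for t, s in annotations.items()}
        labels = {t: "" for t in term_sets}
    N, n = len(bg), len(fg)
    rows = []
    for term in sorted(term_sets):
        members = term_sets[term] & bg
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        # sample odds ratio of the 2x2 table (with 0 -> inf handled by numpy)
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((term, labels.get(term, ""), k, K, n, N, odds, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_label", "k", "K", "n", "N", "odds_ratio", "p_value"],
    )
    if len(out):
        if bh_adjust:
            out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        else:
            out["q_value"] = np.nan
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
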