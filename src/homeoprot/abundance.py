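"""Protein quantification matrices and tissue differential abundance.

The quantification table is protein x sample with an explicit tissue /
replicate design (here two tissues, three biological replicates each, as in a
six-plex TMT experiment).  Differential abundance between two tissues is
called on log2(mean_a / mean_b) with a two-sided t-test on log2 replicate
values; a protein is differentially abundant when |log2FC| > 2 (strictly) and
p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

MISSING_SENTINELS = {"", "NA", "NaN", "nan", "na"}

#: arrangements below this size get an exact enumerated Mann-Whitney null
EXACT_MWU_LIMIT = 200


@dataclass
class QuantMatrix:
    """Protein x sample abundances (NaN = missing) plus the sample design."""

    values: pd.DataFrame                      # index protein_id, columns samples
    design: Mapping[str, tuple[str, int]]     # sample -> (tissue, replicate)

    def __post_init__(self) -> None:
        unknown = [c for c in self.values.columns if c not in self.design]
        if unknown:
            raise ValueError(f"samples absent from design: {unknown}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if (self.values < 0).any().any():
            bad = self.values.stack()
            bad = bad[bad < 0]
            pid, sample = bad.index[0]
            raise ValueError(
                f"negative abundance for protein {pid!r} in sample {sample!r}"
            )
        if (self.values == 0).any().any():
            bad = self.values.stack()
            bad = bad[bad == 0]
            pid, sample = bad.index[0]
            raise ValueError(
                f"non-positive abundance for protein {pid!r} in sample {sample!r}"
            )

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for sample in self.values.columns:
            t = self.design[sample][0]
            if t not in seen:
                seen.append(t)
        return seen

    def samples_for(self, tissue: str) -> list[str]:
        cols = [c for c in self.values.columns if self.design[c][0] == tissue]
        if not cols:
            raise ValueError(f"unknown tissue {tissue!r}")
        return cols


def read_quant(path, design: Mapping[str, tuple[str, int]]) -> QuantMatrix:
    """Read a TSV quant table (first column protein_id, one column per sample);
    empty cells and 'NA' are missing; negative values are rejected."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_SENTINELS),
        keep_default_na=False,
    )
    df = df.apply(pd.to_numeric).astype(float)
    df.index = df.index.astype(str)
    return QuantMatrix(values=df, design=design)


def write_quant(qm: QuantMatrix, path) -> None:
    out = qm.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def mean_abundance(qm: QuantMatrix, tissue: str) -> pd.Series:
    """Per-protein arithmetic mean over the tissue's non-missing replicates;
    NaN when no replicate is present."""
    cols = qm.samples_for(tissue)
    return qm.values[cols].mean(axis=1, skipna=True)


# --- missingness ------------------------------------------------------------

def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with the null enumerated over all group
    assignments of the pooled values (exact even under ties)."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev_obs - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def summarize_missingness(qm: QuantMatrix) -> dict:
    """Per-replicate missing fractions by tissue plus a two-sided Mann-Whitney
    comparison of the per-replicate fractions between the two tissues."""
    rates: dict[str, list[float]] = {}
    per_sample: dict[str, float] = {}
    n_prot = len(qm.values)
    for sample in qm.values.columns:
        tissue = qm.design[sample][0]
        frac = float(qm.values[sample].isna().sum()) / n_prot if n_prot else 0.0
        per_sample[sample] = frac
        rates.setdefault(tissue, []).append(frac)
    tissues = list(rates)
    if len(tissues) != 2:
        raise ValueError("missingness comparison needs exactly two tissues")
    x = np.asarray(rates[tissues[0]], dtype=float)
    y = np.asarray(rates[tissues[1]], dtype=float)
    if min(len(x), len(y)) < 2:
        raise ValueError("need >= 2 replicates per tissue")
    if np.all(x == x[0]) and np.all(y == x[0]):
        u, p = len(x) * len(y) / 2.0, 1.0  # degenerate: identical constant rates
    else:
        from math import comb

        if comb(len(x) + len(y), len(x)) <= EXACT_MWU_LIMIT:
            u, p = _exact_mwu(x, y)
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
    return {
        "per_sample_missing": per_sample,
        "per_tissue_missing": {t: [float(v) for v in rates[t]] for t in tissues},
        "mean_missing": {t: float(np.mean(rates[t])) for t in tissues},
        "mannwhitney_u": float(u),
        "p_value": float(p),
    }


# --- differential abundance -------------------------------------------------

def _welch_or_pooled(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> float:
    """Two-sided two-sample t-test p-value with degenerate-variance handling:
    identical constant groups -> p = 1; zero variance but different means ->
    p = 0 (infinitely strong evidence at face value)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t.pvalue)


def differential_abundance(
    qm: QuantMatrix,
    tissue_a: str,
    tissue_b: str,
    lfc_threshold: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = False,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Call per-protein differential abundance of tissue_a over tissue_b.

    log2FC = log2(mean_a / mean_b) on raw means; the t-test runs on log2
    replicate values (Welch by default).  Status is 'up' when log2FC > the
    threshold (strict) and p <= alpha, 'down' for the mirror rule, and
    'untestable' when either tissue has < 2 present replicates.  Columns:
    protein_id (index), log2fc, p_value, n_a, n_b, status (+ q_value with
    ``bh_adjust``).
    """
    if lfc_threshold <= 0 or not 0 <= alpha <= 1:
        raise ValueError("thresholds must be positive / alpha in [0, 1]")
    va = qm.values[qm.samples_for(tissue_a)].to_numpy(dtype=float)
    vb = qm.values[qm.samples_for(tissue_b)].to_numpy(dtype=float)
    n_a = (~np.isnan(va)).sum(axis=1)
    n_b = (~np.isnan(vb)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(va), np.nan, va), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(vb), np.nan, vb), axis=1)
    log2fc = np.full(len(qm.values), np.nan)
    p = np.full(len(qm.values), np.nan)
    testable = (n_a >= 2) & (n_b >= 2)
    la, lb = np.log2(va), np.log2(vb)
    for i in np.flatnonzero(testable):
        a = la[i][~np.isnan(la[i])]
        b = lb[i][~np.isnan(lb[i])]
        log2fc[i] = np.log2(mean_a[i] / mean_b[i])
        p[i] = _welch_or_pooled(a, b, equal_var)
    status = np.where(
        ~testable,
        "untestable",
        np.where(
            (log2fc > lfc_threshold) & (p <= alpha),
            "up",
            np.where((log2fc < -lfc_threshold) & (p <= alpha), "down", "not_significant"),
        ),
    )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "n_a": n_a,
            "n_b": n_b,
            "status": status,
        },
        index=qm.values.index,
    )
    out.index.name = "protein_id"
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        q = np.full(len(out), np.nan)
        mask = ~np.isnan(p)
        if mask.any():
            q[mask] = multipletests(p[mask], method="fdr_bh")[1]
        out["q_value"] = q
    return out


def write_dap(dap: pd.DataFrame, path) -> None:
    dap.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
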