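"""Molecular-evolution rates for homolog pairs.

Builds codon alignments from protein alignments by back-translation, estimates
nonsynonymous (Ka) and synonymous (Ks) substitution rates with the
Nei-Gojobori counting method (mutational-opportunity site fractions, pathway
averaging over minimal substitution paths, Jukes-Cantor multiple-hit
correction), applies divergence-based exclusion rules, classifies selection
(purifying / neutral / positive), and correlates rates with protein abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

BASES = "ACGT"
GAP = "-"

#: codon -> amino acid for the 61 sense codons of the standard code
CODON_TO_AA: Mapping[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

# Exclusion / classification thresholds
LOW_DIVERGENCE_RATIO = 1e-3   # pairs with Ka/Ks below this are uninformative
NEUTRAL_TOL = 1e-9            # |ratio - 1| below this counts as neutral
SATURATION_P = 0.75           # Jukes-Cantor correction undefined at p >= 3/4


def translate_cds(cds: str) -> str:
    """Translate a codon-clean CDS (no internal stops) to protein."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            if i == len(cds) - 3:
                break  # trailing stop tolerated
            raise ValueError(f"internal stop codon {codon} at nt {i}")
        try:
            aas.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"unrecognised codon {codon!r} at nt {i}") from None
    return "".join(aas)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (S_i, N_i) of one sense codon.

    Each of the nine single-base changes contributes 1/3 of a site; changes to
    stop codons count as nonsynonymous, so S_i + N_i = 3 exactly.
    """
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_TO_AA.get(mutant) == CODON_TO_AA[codon]:
                syn += 1
    s = syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathway-averaged (nonsyn, syn) difference counts between two sense codons.

    All orderings of the differing positions are enumerated; orderings whose
    intermediate codons are stops are discarded.  When every ordering is
    blocked, only steps between sense codons are counted (averaged over all
    orderings) and the flag in the third slot is set.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0, False
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diffs):
        cur = c1
        nd = sd = 0
        nd_ok = sd_ok = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            cur_sense = cur in CODON_TO_AA
            nxt_sense = nxt in CODON_TO_AA
            if cur_sense and nxt_sense:
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    sd += 1
                    sd_ok += 1
                else:
                    nd += 1
                    nd_ok += 1
            else:
                blocked = True
            cur = nxt
        if not blocked:
            valid.append((nd, sd))
        fallback.append((nd_ok, sd_ok))
    if valid:
        nd_avg = sum(v[0] for v in valid) / len(valid)
        sd_avg = sum(v[1] for v in valid) / len(valid)
        return nd_avg, sd_avg, False
    nd_avg = sum(v[0] for v in fallback) / len(fallback)
    sd_avg = sum(v[1] for v in fallback) / len(fallback)
    return nd_avg, sd_avg, True


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differing sites."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= SATURATION_P:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


@dataclass
class ProteinAlignment:
    """A gapped pairwise protein alignment (two equal-length rows)."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError(
                f"alignment rows differ in length for ({self.id_a}, {self.id_b})"
            )
        for i, (x, y) in enumerate(zip(self.row_a, self.row_b)):
            if x == GAP and y == GAP:
                raise ValueError(f"all-gap column {i} in ({self.id_a}, {self.id_b})")


@dataclass
class CodonAlignment:
    """A gapped pairwise codon alignment; gap runs are codon-sized."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b) or len(self.row_a) % 3 != 0:
            raise ValueError("codon alignment rows must be equal and divisible by 3")

    def codon_columns(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.row_a), 3):
            yield self.row_a[i : i + 3], self.row_b[i : i + 3]


@dataclass
class KaKsResult:
    id_a: str
    id_b: str
    ka: float
    ks: float
    ratio: float  # NaN when undefined
    n_sites_n: float
    n_sites_s: float
    nd: float
    sd: float
    n_codons_compared: int
    n_flagged_codons: int = 0
    excluded: bool = False
    reason: str = "none"  # none | low_divergence | saturated | no_data
    selection: str = "not_classified"  # purifying | neutral | positive | not_classified


def _strip_trailing_stop(cds: str, n_residues: int) -> str:
    if len(cds) == 3 * (n_residues + 1) and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def backtranslate(pa: ProteinAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread each CDS onto its aligned protein, expanding gaps to codon gaps.

    Each CDS must translate exactly to its degapped protein row (a trailing
    stop codon is tolerated and trimmed); mismatches are reported with the
    pair, residue position and both residues.
    """
    rows = []
    for pid, row, cds in ((pa.id_a, pa.row_a, cds_a), (pa.id_b, pa.row_b, cds_b)):
        protein = row.replace(GAP, "")
        cds = _strip_trailing_stop(cds.upper(), len(protein))
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"{pid}: CDS length {len(cds)} does not match "
                f"{len(protein)} aligned residues"
            )
        observed = translate_cds(cds)
        for k, (exp, obs) in enumerate(zip(protein, observed)):
            if exp != obs:
                raise ValueError(
                    f"pair ({pa.id_a}, {pa.id_b}): translation mismatch for {pid} "
                    f"at residue {k + 1}: protein has {exp!r}, CDS encodes {obs!r}"
                )
        out = []
        j = 0
        for ch in row:
            if ch == GAP:
                out.append(GAP * 3)
            else:
                out.append(cds[3 * j : 3 * j + 3])
                j += 1
        rows.append("".join(out))
    return CodonAlignment(pa.id_a, pa.id_b, rows[0], rows[1])


def kaks_counting(ca: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori counting estimate of Ka, Ks and their ratio for one pair.

    Codon columns containing gaps, ambiguous bases or stop codons are skipped.
    Site counts are averaged over the two sequences; observed differences are
    pathway-averaged; proportions are Jukes-Cantor corrected.  Exclusion and
    selection classes follow the divergence rules applied downstream.
    """
    S = N = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    n_flagged = 0
    for ca_codon, cb_codon in ca.codon_columns():
        if ca_codon not in CODON_TO_AA or cb_codon not in CODON_TO_AA:
            continue  # gapped, ambiguous or stop column
        s1, n1 = codon_sites(ca_codon)
        s2, n2 = codon_sites(cb_codon)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        nd, sd, flagged = codon_path_differences(ca_codon, cb_codon)
        Nd += nd
        Sd += sd
        n_flagged += flagged
        n_codons += 1
    res = KaKsResult(
        ca.id_a, ca.id_b, ka=float("nan"), ks=float("nan"), ratio=float("nan"),
        n_sites_n=N, n_sites_s=S, nd=Nd, sd=Sd,
        n_codons_compared=n_codons, n_flagged_codons=n_flagged,
    )
    if n_codons == 0 or S <= 0 or N <= 0:
        res.excluded = True
        res.reason = "no_data"
        return res
    pn = Nd / N
    ps = Sd / S
    res.ka = jukes_cantor(pn) if pn < SATURATION_P else float("nan")
    res.ks = jukes_cantor(ps) if ps < SATURATION_P else float("nan")
    if np.isnan(res.ka) or np.isnan(res.ks):
        res.excluded = True
        res.reason = "saturated"
        return res
    if res.ks > 0:
        res.ratio = res.ka / res.ks
    _apply_rules(res)
    return res


def _apply_rules(res: KaKsResult) -> None:
    """Divergence-exclusion and selection-classification rules for one result."""
    if res.reason in ("saturated", "no_data"):
        res.excluded = True
        return
    if res.ka == 0 or np.isnan(res.ratio) or res.ratio < LOW_DIVERGENCE_RATIO:
        res.excluded = True
        res.reason = "low_divergence"
        res.selection = "not_classified"
        return
    res.excluded = False
    res.reason = "none"
    if abs(res.ratio - 1.0) <= NEUTRAL_TOL:
        res.selection = "neutral"
    elif res.ratio > 1.0:
        res.selection = "positive"
    else:
        res.selection = "purifying"


def apply_exclusions(
    results: Iterable[KaKsResult],
) -> tuple[list[KaKsResult], list[KaKsResult]]:
    """Partition results into (kept, excluded) by the low-divergence and
    saturation rules; each result's reason and selection class are refreshed."""
    kept: list[KaKsResult] = []
    excluded: list[KaKsResult] = []
    for res in results:
        _apply_rules(res)
        (excluded if res.excluded else kept).append(res)
    return kept, excluded


def correlate_rate_abundance(
    ratios: Sequence[float],
    values: Sequence[float],
    method: str = "spearman",
) -> dict:
    """Rank correlation between Ka/Ks ratios and an abundance-type quantity.

    Returns rho, p and n; with fewer than 3 complete observations the report
    is flagged insufficient and carries no fabricated numbers.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ratios and values must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        return {"rho": None, "p_value": None, "n": n, "insufficient_data": True}
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return {
        "rho": float(rho),
        "p_value": float(p),
        "n": n,
        "insufficient_data": False,
    }
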