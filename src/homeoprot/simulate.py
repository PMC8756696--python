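"""Synthetic allotetraploid proteome generator.

Emulates the data structure the analysis assumes: gene families with one copy
on each sub-genome (a homeolog pair, as in an AABB allotetraploid formed from
two diploid progenitors) plus within-sub-genome duplicates (paralog pairs);
CDS pairs diverged by a codon-level substitution process with a controlled
dN/dS (omega) and synonymous divergence; and a protein x sample abundance
matrix for two tissues x three replicates with lognormal replicate noise,
per-copy log2 bias effects, true tissue fold changes and
missing-completely-at-random dropout.  Ground truth is returned alongside so
every downstream classifier can be scored against what was injected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import QuantMatrix
from .evolution import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    translate_cds,
)
from .homology import SequenceRecord


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic allotetraploid proteome.

    Defaults mirror the experimental design being emulated: two tissues
    (leaf, root) x three biological replicates, ~2.5% missing measurements,
    strong (8-fold) true bias on a minority of pairs, and moderate purifying
    selection on the coding sequences.
    """

    n_families: int = 60
    paralog_fraction: float = 0.4
    n_codons: int = 300
    omega_range: tuple[float, float] = (0.05, 0.4)
    ks_target: float = 0.2
    tissues: tuple[str, str] = ("leaf", "root")
    n_replicates: int = 3
    bias_effect_log2: float = 3.0
    biased_fraction: float = 0.3
    noise_sigma: float = 0.2
    missing_rate: float = 0.025
    seed: int = 0
    # true tissue differential abundance injected per protein
    da_fraction: float = 0.08
    da_effect_log2: float = 3.0
    # log2-abundance baseline distribution
    base_log2_mean: float = 10.0
    base_log2_sd: float = 1.5
    # >0 couples omega to family baseline abundance (E-R anticorrelation)
    er_coupling: float = 0.0

    def validate(self) -> None:
        for name in ("paralog_fraction", "biased_fraction", "missing_rate",
                     "da_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_families < 1:
            raise ValueError(f"n_families must be positive, got {self.n_families}")
        if self.n_codons < 1:
            raise ValueError(f"n_codons must be positive, got {self.n_codons}")
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be >= 2, got {self.n_replicates}")
        lo, hi = self.omega_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(
                f"omega_range values must be > 0 and ordered, got {self.omega_range}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.ks_target < 0:
            raise ValueError(f"ks_target must be >= 0, got {self.ks_target}")
        if len(self.tissues) != 2:
            raise ValueError("exactly two tissues are supported")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["omega_range"] = tuple(data["omega_range"])
        data["tissues"] = tuple(data["tissues"])
        return cls(**data)


@dataclass
class TruePair:
    id_a: str
    id_b: str
    relation: str            # paralog | homeolog
    omega: float
    bias_direction: str      # A | B | copy1 | copy2 | none
    bias_log2: float

    def __post_init__(self) -> None:
        if (self.bias_direction == "none") != (self.bias_log2 == 0.0):
            raise ValueError("bias direction 'none' iff magnitude is 0")


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-pair relation / omega / bias, and
    per-protein baseline, tissue log2 fold change and bias offset."""

    pairs: list[TruePair] = field(default_factory=list)
    # protein id -> {base_log2, tissue_lfc, bias_offset_log2}
    proteins: dict[str, dict[str, float]] = field(default_factory=dict)

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(p.id_a, p.id_b) for p in self.pairs}

    def to_json(self, path) -> None:
        data = {
            "pairs": [dataclasses.asdict(p) for p in self.pairs],
            "proteins": self.proteins,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            pairs=[TruePair(**p) for p in data["pairs"]],
            proteins=data["proteins"],
        )


# --- codon-level sequence evolution -----------------------------------------

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Ancestral CDS: codons drawn uniformly from the 61 sense codons."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _check_codon_clean(cds: str) -> None:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nt {i}")
        if codon not in CODON_TO_AA:
            raise ValueError(f"invalid codon {codon!r} at nt {i}")


def _evolve_lineage(
    cds: str, omega: float, n_proposals: int, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Apply single-nucleotide substitution proposals to one lineage.

    Proposals are uniform over sites and target bases; a synonymous proposal
    is always accepted, a nonsynonymous one with probability omega, and a
    proposal creating a stop codon never.  Returns the evolved sequence and
    the realized (synonymous, nonsynonymous) event counts.
    """
    seq = list(cds)
    n_syn = n_non = 0
    L = len(seq)
    sites = rng.integers(0, L, size=n_proposals)
    base_choices = rng.integers(0, 3, size=n_proposals)
    accept_draws = rng.random(size=n_proposals)
    for site, bidx, u in zip(sites, base_choices, accept_draws):
        old = seq[site]
        alts = [b for b in BASES if b != old]
        new = alts[bidx]
        c0 = site - site % 3
        codon_old = "".join(seq[c0 : c0 + 3])
        codon_new = codon_old[: site - c0] + new + codon_old[site - c0 + 1 :]
        if codon_new in STOP_CODONS:
            continue
        if CODON_TO_AA[codon_new] == CODON_TO_AA[codon_old]:
            seq[site] = new
            n_syn += 1
        elif u < omega:
            seq[site] = new
            n_non += 1
    return "".join(seq), n_syn, n_non


def proposals_for_ks(n_codons: int, ks_target: float) -> int:
    """Total proposals (both lineages combined) that put the expected
    synonymous events per synonymous site at ks_target.

    With proposals uniform over the 9L single-base changes, the chance that a
    proposal is synonymous equals (synonymous changes)/(9L) and the NG86
    synonymous site count is (synonymous changes)/3, so the per-site
    synonymous rate per proposal is 3/(9L) regardless of composition; hence
    M = 3 * L * ks_target.
    """
    return int(round(3 * n_codons * ks_target))


def evolve_pair(
    ancestral_cds: str,
    omega: float,
    ks_target: float,
    seed: int | np.random.Generator,
) -> tuple[str, str, dict]:
    """Evolve two lineages independently from an ancestral CDS.

    The pairwise synonymous divergence is ks_target in expectation (split
    evenly across the lineages).  Returns the two descendant CDS and the
    realized substitution counts per lineage.
    """
    _check_codon_clean(ancestral_cds)
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_total = proposals_for_ks(len(ancestral_cds) // 3, ks_target)
    m1 = m_total // 2
    m2 = m_total - m1
    cds_1, syn1, non1 = _evolve_lineage(ancestral_cds, omega, m1, rng)
    cds_2, syn2, non2 = _evolve_lineage(ancestral_cds, omega, m2, rng)
    counts = {
        "syn_1": syn1, "nonsyn_1": non1,
        "syn_2": syn2, "nonsyn_2": non2,
        "syn_total": syn1 + syn2, "nonsyn_total": non1 + non2,
        "n_proposals": m_total,
    }
    return cds_1, cds_2, counts


# --- family / proteome simulation -------------------------------------------

def _chromosome(sub_genome: str, family_index: int) -> str:
    return f"chr{sub_genome}{family_index % 10 + 1:02d}"


def simulate_families(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthTable]:
    """Generate protein records, CDS records and the ground-truth table.

    Each family carries one A-copy and one B-copy (a homeolog pair); a
    ``paralog_fraction`` subset additionally carries a same-sub-genome
    duplicate (a paralog pair).  Proteins are exact translations of their CDS.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins: list[SequenceRecord] = []
    cds_records: list[SequenceRecord] = []
    truth = TruthTable()
    omega_lo, omega_hi = config.omega_range

    base_log2 = rng.normal(config.base_log2_mean, config.base_log2_sd,
                           size=config.n_families)
    if config.er_coupling > 0:
        # high-abundance families evolve slowly: omega decreases with the
        # family baseline's rank (plus a little jitter)
        ranks = np.argsort(np.argsort(base_log2)) / max(config.n_families - 1, 1)
        omegas = omega_hi - (omega_hi - omega_lo) * ranks
        omegas = np.clip(
            omegas + rng.normal(0, config.er_coupling * (omega_hi - omega_lo) * 0.1,
                                size=config.n_families),
            omega_lo, omega_hi,
        )
    else:
        omegas = rng.uniform(omega_lo, omega_hi, size=config.n_families)

    # exactly round(fraction * n) families carry a duplicate (counts are part
    # of the study design, not sampling noise)
    n_paralog_families = int(round(config.paralog_fraction * config.n_families))
    has_paralog = np.zeros(config.n_families, dtype=bool)
    if n_paralog_families:
        has_paralog[
            rng.choice(config.n_families, size=n_paralog_families, replace=False)
        ] = True
    paralog_sub = rng.choice(["A", "B"], size=config.n_families)

    def add_copy(fam: str, sub: str, copy_no: int, cds: str, fidx: int) -> str:
        pid = f"{fam}.{sub}{copy_no}"
        chrom = _chromosome(sub, fidx)
        cds_records.append(SequenceRecord(pid, cds, "cds", chrom, sub))
        proteins.append(
            SequenceRecord(pid, translate_cds(cds), "protein", chrom, sub)
        )
        return pid

    for f in range(config.n_families):
        fam = f"F{f + 1:04d}"
        omega = float(omegas[f])
        ancestor = random_cds(config.n_codons, rng)
        cds_a, cds_b, _ = evolve_pair(ancestor, omega, config.ks_target, rng)
        id_a = add_copy(fam, "A", 1, cds_a, f)
        id_b = add_copy(fam, "B", 1, cds_b, f)
        truth.pairs.append(TruePair(id_a, id_b, "homeolog", omega, "none", 0.0))
        for pid in (id_a, id_b):
            truth.proteins[pid] = {
                "base_log2": float(base_log2[f]),
                "tissue_lfc": 0.0,
                "bias_offset_log2": 0.0,
            }
        if has_paralog[f]:
            sub = str(paralog_sub[f])
            parent_id = id_a if sub == "A" else id_b
            parent_cds = cds_a if sub == "A" else cds_b
            m = proposals_for_ks(config.n_codons, config.ks_target)
            dup_cds, _, _ = _evolve_lineage(parent_cds, omega, m, rng)
            dup_id = add_copy(fam, sub, 2, dup_cds, f)
            truth.proteins[dup_id] = {
                "base_log2": float(base_log2[f]),
                "tissue_lfc": 0.0,
                "bias_offset_log2": 0.0,
            }
            pid1, pid2 = sorted((parent_id, dup_id))
            truth.pairs.append(TruePair(pid1, pid2, "paralog", omega, "none", 0.0))

    # Inject true bias effects on a subset of pairs.  Effects are kept
    # compositional so a biased pair never shifts the ratio of another pair
    # sharing one of its members: a homeolog bias is a sub-genome-level
    # effect (every copy of the favoured sub-genome in the family gets the
    # offset, leaving within-sub-genome paralog ratios untouched), while a
    # paralog bias falls entirely on the duplicate copy (absent from the
    # homeolog pair).
    n_biased = int(round(config.biased_fraction * len(truth.pairs)))
    biased = np.zeros(len(truth.pairs), dtype=bool)
    if n_biased:
        biased[rng.choice(len(truth.pairs), size=n_biased, replace=False)] = True
    favour_first = rng.random(len(truth.pairs)) < 0.5
    for i, pair in enumerate(truth.pairs):
        if not biased[i] or config.bias_effect_log2 == 0.0:
            continue
        fam = pair.id_a.split(".", 1)[0]
        if pair.relation == "homeolog":
            favoured = pair.id_a if favour_first[i] else pair.id_b
            sub = favoured.rsplit(".", 1)[1][0]  # 'A' or 'B'
            direction = sub
            for pid in truth.proteins:
                if pid.startswith(f"{fam}.{sub}"):
                    truth.proteins[pid]["bias_offset_log2"] += config.bias_effect_log2
        else:
            # the duplicate copy (number 2) carries the whole offset, signed
            duplicate = pair.id_a if pair.id_a.endswith("2") else pair.id_b
            sign = 1.0 if favour_first[i] else -1.0
            truth.proteins[duplicate]["bias_offset_log2"] += sign * config.bias_effect_log2
            favoured = duplicate if sign > 0 else (
                pair.id_b if duplicate == pair.id_a else pair.id_a
            )
            direction = "copy1" if favoured == pair.id_a else "copy2"
        truth.pairs[i] = TruePair(
            pair.id_a, pair.id_b, pair.relation, pair.omega,
            direction, config.bias_effect_log2,
        )

    # inject true tissue fold changes per protein
    all_ids = sorted(truth.proteins)
    n_da = int(round(config.da_fraction * len(all_ids)))
    da = np.zeros(len(all_ids), dtype=bool)
    if n_da:
        da[rng.choice(len(all_ids), size=n_da, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=len(all_ids))
    for i, pid in enumerate(all_ids):
        if da[i] and config.da_effect_log2 != 0.0:
            truth.proteins[pid]["tissue_lfc"] = float(signs[i] * config.da_effect_log2)

    return proteins, cds_records, truth


def simulate_quant(
    proteins: Sequence[SequenceRecord],
    truth: TruthTable,
    config: SimulationConfig,
) -> QuantMatrix:
    """Abundance matrix: 2 ** (base + tissue effect + bias offset + noise),
    with each cell independently missing at ``missing_rate``.

    The true tissue log2 fold change is oriented first-tissue over second
    (leaf over root with the default design) and applied entirely to the
    first tissue.
    """
    config.validate()
    missing_ids = [p.id for p in proteins if p.id not in truth.proteins]
    if missing_ids:
        raise ValueError(f"proteins without truth entries: {missing_ids[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    ids = [p.id for p in sorted(proteins, key=lambda r: r.id)]
    columns = [
        f"{tissue}_{rep + 1}"
        for tissue in config.tissues
        for rep in range(config.n_replicates)
    ]
    n, m = len(ids), len(columns)
    log2 = np.empty((n, m))
    for i, pid in enumerate(ids):
        info = truth.proteins[pid]
        for j, col in enumerate(columns):
            tissue = col.rsplit("_", 1)[0]
            effect = info["tissue_lfc"] if tissue == config.tissues[0] else 0.0
            log2[i, j] = info["base_log2"] + effect + info["bias_offset_log2"]
    log2 = log2 + rng.normal(0.0, config.noise_sigma, size=(n, m))
    values = np.power(2.0, log2)
    mask = rng.random(size=(n, m)) < config.missing_rate
    values[mask] = np.nan
    df = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=columns)
    design = {
        col: (col.rsplit("_", 1)[0], int(col.rsplit("_", 1)[1])) for col in columns
    }
    return QuantMatrix(values=df, design=design)


def simulate_annotations(
    truth: TruthTable,
    rng: np.random.Generator | int = 0,
    n_background_terms: int = 10,
) -> pd.DataFrame:
    """A synthetic annotation table (protein_id, term_id, term_label).

    One term ("TERM:DA") covers the proteins carrying a true tissue effect
    (so enrichment of the differentially abundant set against the proteome is
    expected); the remaining terms annotate random protein subsets.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ids = sorted(truth.proteins)
    rows = []
    for pid in ids:
        if truth.proteins[pid]["tissue_lfc"] != 0.0:
            rows.append((pid, "TERM:DA", "true tissue response"))
    for t in range(n_background_terms):
        size = int(rng.integers(5, max(6, len(ids) // 4)))
        for pid in rng.choice(ids, size=min(size, len(ids)), replace=False):
            rows.append((str(pid), f"TERM:{t:03d}", f"random annotation {t}"))
    return pd.DataFrame(rows, columns=["protein_id", "term_id", "term_label"])


def write_dataset(
    outdir,
    proteins: Sequence[SequenceRecord],
    cds: Sequence[SequenceRecord],
    truth: TruthTable,
    qm: QuantMatrix,
    config: SimulationConfig,
) -> None:
    """Write proteins.faa, cds.fna, quant.tsv, truth.json and config.json."""
    from pathlib import Path

    from .abundance import write_quant
    from .homology import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sorted(proteins, key=lambda r: r.id), outdir / "proteins.faa")
    write_fasta(sorted(cds, key=lambda r: r.id), outdir / "cds.fna")
    write_quant(qm, outdir / "quant.tsv")
    truth.to_json(outdir / "truth.json")
    config.to_json(outdir / "config.json")
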