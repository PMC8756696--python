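"""Paralog / homeolog pair identification from pairwise alignment statistics.

Hits come either from an external 12-column tabular alignment file (BLAST
outfmt 6) or from the built-in global protein aligner; they pass three
filters (coverage > 80% of each sequence, identity > 80%, E-value <= 1e-10)
and are paired by reciprocal best hit within two relation classes:
within-sub-genome (paralog) and cross-sub-genome A x B (homeolog).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

HIT_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein or CDS sequence with its chromosome and sub-genome label."""

    id: str
    sequence: str
    kind: str  # "protein" | "cds"
    chromosome: str = ""
    sub_genome: str = "unassigned"  # "A" | "B" | "unassigned"

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "cds"):
            raise ValueError(f"{self.id}: kind must be 'protein' or 'cds'")
        if self.kind == "cds" and len(self.sequence) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length not divisible by 3")


@dataclass
class AlignmentHit:
    """One pairwise alignment hit with the statistics the filters need."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_length: int
    subject_length: int
    score: float
    e_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"{self.query_id}/{self.subject_id}: identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length > self.query_length + self.subject_length:
            raise ValueError(
                f"{self.query_id}/{self.subject_id}: alignment length exceeds "
                "the two sequence lengths combined"
            )


@dataclass(frozen=True)
class HomologPair:
    """Two proteins related as paralogs (same sub-genome) or homeologs.

    ids are in canonical order (lexicographically smaller first)."""

    id_a: str
    id_b: str
    relation: str  # "paralog" | "homeolog"
    hit: AlignmentHit

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair {self.id_a}")
        if self.relation not in ("paralog", "homeolog"):
            raise ValueError(f"unknown relation {self.relation!r}")


# --- sub-genome assignment --------------------------------------------------

#: default synthetic naming: chrA01..chrA10 -> A, chrB01..chrB10 -> B
DEFAULT_SUBGENOME_RULES: tuple[tuple[str, str], ...] = (
    (r"^chrA\d+$", "A"),
    (r"^chrB\d+$", "B"),
)

#: Arachis hypogaea Tifrunner naming: Arahy.01-.10 -> A, Arahy.11-.20 -> B
ARACHIS_SUBGENOME_RULES: tuple[tuple[str, str], ...] = (
    (r"^Arahy\.(0[1-9]|10)$", "A"),
    (r"^Arahy\.(1[1-9]|20)$", "B"),
)


def assign_subgenome(
    chromosome: str,
    rules: Sequence[tuple[str, str]] = DEFAULT_SUBGENOME_RULES,
) -> str:
    """Map a chromosome name to a sub-genome label; first matching rule wins."""
    for pattern, label in rules:
        if re.search(pattern, chromosome):
            return label
    return "unassigned"


# --- FASTA I/O --------------------------------------------------------------

def read_fasta(
    path,
    kind: str,
    rules: Sequence[tuple[str, str]] = DEFAULT_SUBGENOME_RULES,
) -> list[SequenceRecord]:
    """Read sequences; a ``chromosome=NAME`` token in the description (written
    by :func:`write_fasta`) sets the chromosome and hence the sub-genome."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        chrom = ""
        m = re.search(r"chromosome=(\S+)", rec.description)
        if m:
            chrom = m.group(1)
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                kind=kind,
                chromosome=chrom,
                sub_genome=assign_subgenome(chrom, rules),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        BioSeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"chromosome={r.chromosome}" if r.chromosome else "",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# --- tabular hit I/O --------------------------------------------------------

def read_alignment_table(path, lengths: Mapping[str, int]) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file (BLAST outfmt 6).

    The tabular format omits sequence lengths, so they are supplied separately
    (normally from the FASTA).  Self-hits are dropped; malformed rows raise
    with their line number; a hit naming a sequence with no known length is a
    hard error naming the id.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            if query == subject:
                continue
            try:
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            for sid in (query, subject):
                if sid not in lengths:
                    raise ValueError(
                        f"{path}: line {lineno}: no sequence length known for "
                        f"id {sid!r}"
                    )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=query,
                        subject_id=subject,
                        percent_identity=pident,
                        alignment_length=length,
                        query_length=lengths[query],
                        subject_length=lengths[subject],
                        score=bitscore,
                        e_value=evalue,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_hits(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits in the 12-column tabular layout (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            evalue = 0.0 if h.e_value is None else h.e_value
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.percent_identity:.3f}",
                        str(h.alignment_length), "0", "0", "1",
                        str(h.query_length), "1", str(h.subject_length),
                        f"{evalue:.3g}", f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )


# --- built-in pairwise aligner ----------------------------------------------

def make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    """Global protein aligner with affine gaps (penalties given positive)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pairwise(
    a: SequenceRecord,
    b: SequenceRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentHit:
    """Globally align two proteins; identity is counted over aligned columns.

    percent_identity = identical residue pairs / aligned columns x 100, where
    aligned columns exclude (non-occurring in pairwise output) all-gap
    columns; alignment_length is the number of aligned columns; no E-value.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-"
    )
    columns = len(row_a)
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        percent_identity=100.0 * matches / columns,
        alignment_length=columns,
        query_length=len(a.sequence),
        subject_length=len(b.sequence),
        score=float(aln.score),
        e_value=None,
    )


def aligned_rows(
    a: SequenceRecord,
    b: SequenceRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, str]:
    """The two gapped rows of the best global alignment (for back-translation)."""
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    return str(aln[0]), str(aln[1])


def _shared_kmers(s1: str, s2: str, k: int = 4) -> int:
    k1 = {s1[i : i + k] for i in range(len(s1) - k + 1)}
    k2 = {s2[i : i + k] for i in range(len(s2) - k + 1)}
    return len(k1 & k2)


def all_vs_all_hits(
    records: Sequence[SequenceRecord],
    aligner: Align.PairwiseAligner | None = None,
    min_shared_kmers: int = 8,
) -> list[AlignmentHit]:
    """Align every candidate protein pair, prescreened by shared 4-mers.

    Unrelated proteins share almost no 4-mers and could never reach the >80%
    identity filter, so skipping them changes nothing downstream while keeping
    all-vs-all runs at fixture scale fast.
    """
    if aligner is None:
        aligner = make_aligner()
    recs = sorted(records, key=lambda r: r.id)
    hits = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if _shared_kmers(recs[i].sequence, recs[j].sequence) < min_shared_kmers:
                continue
            hits.append(align_pairwise(recs[i], recs[j], aligner))
    return hits


# --- filtering and pairing --------------------------------------------------

@dataclass(frozen=True)
class FilterThresholds:
    """Hit-retention thresholds; coverage and identity are strict (>)."""

    coverage: float = 0.80
    identity: float = 80.0
    e_value: float = 1e-10


def filter_hits(
    hits: Iterable[AlignmentHit],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[AlignmentHit]:
    """Keep hits whose alignment covers > 80% of EACH sequence, with identity
    > 80%, and E-value <= 1e-10 when an E-value is present."""
    kept = []
    for h in hits:
        if h.alignment_length <= thresholds.coverage * h.query_length:
            continue
        if h.alignment_length <= thresholds.coverage * h.subject_length:
            continue
        if h.percent_identity <= thresholds.identity:
            continue
        if h.e_value is not None and h.e_value > thresholds.e_value:
            continue
        kept.append(h)
    return kept


def _relation_of(sg_a: str, sg_b: str) -> str | None:
    if sg_a in ("A", "B") and sg_a == sg_b:
        return "paralog"
    if {sg_a, sg_b} == {"A", "B"}:
        return "homeolog"
    return None  # unassigned members take part in no relation class


def pair_homologs(
    hits: Iterable[AlignmentHit],
    sub_genomes: Mapping[str, str],
    mode: str = "rbh",
) -> list[HomologPair]:
    """Pair proteins within each relation class.

    Hit directions are collapsed to one score per unordered pair (max score),
    so external tables with both directions and the symmetric built-in aligner
    behave identically.  In ``rbh`` mode a pair is emitted only when each
    member is the other's best-scoring partner in that class (ties broken by
    lexicographic partner id); ``all`` mode emits every passing pair.
    """
    if mode not in ("rbh", "all"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    best_hit: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        if h.query_id not in sub_genomes or h.subject_id not in sub_genomes:
            missing = h.query_id if h.query_id not in sub_genomes else h.subject_id
            raise ValueError(f"no sub-genome assignment for {missing!r}")
        key = tuple(sorted((h.query_id, h.subject_id)))
        if key not in best_hit or h.score > best_hit[key].score:
            best_hit[key] = h

    def relation(key: tuple[str, str]) -> str | None:
        return _relation_of(sub_genomes[key[0]], sub_genomes[key[1]])

    if mode == "all":
        pairs = [
            HomologPair(key[0], key[1], rel, hit)
            for key, hit in sorted(best_hit.items())
            if (rel := relation(key)) is not None
        ]
        return pairs

    # best partner per protein per relation class
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for key, hit in best_hit.items():
        rel = relation(key)
        if rel is None:
            continue
        for me, other in (key, key[::-1]):
            cur = best.get((me, rel))
            cand = (hit.score, other)
            # higher score wins; on a score tie the lexicographically smaller
            # partner id wins (determinism)
            if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                best[(me, rel)] = cand
    pairs = []
    for key, hit in sorted(best_hit.items()):
        rel = relation(key)
        if rel is None:
            continue
        a, b = key
        if best.get((a, rel), (None, None))[1] == b and best.get((b, rel), (None, None))[1] == a:
            pairs.append(HomologPair(a, b, rel, hit))
    return pairs


def write_pairs(pairs: Iterable[HomologPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\trelation\tpident\tcoverage_a\tcoverage_b\tevalue\n")
        for p in pairs:
            h = p.hit
            cov_q = h.alignment_length / h.query_length
            cov_s = h.alignment_length / h.subject_length
            if h.query_id == p.id_a:
                cov_a, cov_b = cov_q, cov_s
            else:
                cov_a, cov_b = cov_s, cov_q
            ev = "" if h.e_value is None else f"{h.e_value:.3g}"
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.relation}\t{h.percent_identity:.2f}\t"
                f"{cov_a:.3f}\t{cov_b:.3f}\t{ev}\n"
            )
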