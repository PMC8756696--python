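"""Alignment-hit parsing, filtering, the built-in aligner and RBH pairing."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from homeoprot import homology
from homeoprot.homology import (
    ARACHIS_SUBGENOME_RULES,
    AlignmentHit,
    FilterThresholds,
    SequenceRecord,
    align_pairwise,
    assign_subgenome,
    filter_hits,
    pair_homologs,
    read_alignment_table,
    write_hits,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_oracle(s1: str, s2: str, gap_open=10.0, gap_extend=1.0) -> float:
    """Independent affine-gap global alignment score by memoized recursion
    over (i, j, state); the first gap position costs gap_open, each further
    position gap_extend."""
    from functools import lru_cache

    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, last):
        # last move: 0 = match/mismatch, 1 = gap in s2 (consumed s1),
        # 2 = gap in s1 (consumed s2)
        if i == 0 and j == 0:
            # the empty prefix: any first gap must pay the open cost, so only
            # the match-state start is free
            return 0.0 if last == 0 else NEG
        if last == 0:
            if i == 0 or j == 0:
                return NEG
            sub = float(BLOSUM62[s1[i - 1], s2[j - 1]])
            return max(best(i - 1, j - 1, s) for s in range(3)) + sub
        if last == 1:
            if i == 0:
                return NEG
            return max(
                best(i - 1, j, 1) - gap_extend,
                best(i - 1, j, 0) - gap_open,
                best(i - 1, j, 2) - gap_open,
            )
        if j == 0:
            return NEG
        return max(
            best(i, j - 1, 2) - gap_extend,
            best(i, j - 1, 0) - gap_open,
            best(i, j - 1, 1) - gap_open,
        )

    return max(best(len(s1), len(s2), s) for s in range(3))


def _rec(pid, seq, chrom="chrA01"):
    return SequenceRecord(pid, seq, "protein", chrom, assign_subgenome(chrom))


class TestSubgenomeAssignment:
    @pytest.mark.parametrize(
        "chrom,rules,expected",
        [
            ("chrA03", homology.DEFAULT_SUBGENOME_RULES, "A"),
            ("chrB10", homology.DEFAULT_SUBGENOME_RULES, "B"),
            ("Arahy.14", ARACHIS_SUBGENOME_RULES, "B"),
            ("Arahy.03", ARACHIS_SUBGENOME_RULES, "A"),
            ("scaffold_99", homology.DEFAULT_SUBGENOME_RULES, "unassigned"),
        ],
    )
    def test_rule_matching(self, chrom, rules, expected):
        assert assign_subgenome(chrom, rules) == expected


class TestAlignmentTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "hits.tsv"
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return path

    ROW = ["q1", "s1", 95.0, 100, 3, 0, 1, 100, 1, 100, 1e-30, 180.5]

    def test_parses_rows_and_drops_self_hits(self, tmp_path):
        rows = [
            self.ROW,
            ["q1", "q1", 100.0, 100, 0, 0, 1, 100, 1, 100, 0.0, 200.0],
            ["q2", "s2", 85.0, 90, 5, 1, 1, 90, 1, 90, 1e-20, 150.0],
        ]
        path = self._write(tmp_path, rows)
        hits = read_alignment_table(path, {"q1": 100, "s1": 105, "q2": 95, "s2": 100})
        assert len(hits) == 2
        assert hits[0].query_id == "q1" and hits[0].subject_id == "s1"
        assert hits[0].percent_identity == 95.0
        assert hits[0].e_value == 1e-30

    def test_non_numeric_identity_cites_line_number(self, tmp_path):
        rows = [self.ROW, ["q2", "s2", "NOTNUM", 90, 0, 0, 1, 90, 1, 90, 1e-5, 10.0]]
        path = self._write(tmp_path, rows)
        with pytest.raises(ValueError, match="line 2"):
            read_alignment_table(path, {"q1": 100, "s1": 105, "q2": 95, "s2": 100})

    def test_missing_length_names_the_id(self, tmp_path):
        path = self._write(tmp_path, [self.ROW])
        with pytest.raises(ValueError, match="'s1'"):
            read_alignment_table(path, {"q1": 100})

    def test_write_read_roundtrip(self, tmp_path, rng):
        hits = [
            AlignmentHit(f"q{i}", f"s{i}", float(rng.uniform(50, 100)),
                         int(rng.integers(50, 150)), 150, 150,
                         float(rng.uniform(10, 300)), float(10.0 ** -rng.integers(5, 50)))
            for i in range(10)
        ]
        path = tmp_path / "out.tsv"
        write_hits(hits, path)
        lengths = {h.query_id: 150 for h in hits} | {h.subject_id: 150 for h in hits}
        back = read_alignment_table(path, lengths)
        for orig, rt in zip(hits, back):
            assert rt.query_id == orig.query_id
            assert rt.subject_id == orig.subject_id
            assert rt.percent_identity == pytest.approx(orig.percent_identity, abs=1e-3)
            assert rt.alignment_length == orig.alignment_length
            assert rt.e_value == pytest.approx(orig.e_value, rel=1e-2)
            assert rt.score == pytest.approx(orig.score, abs=0.05)


class TestFilters:
    def _hit(self, pident=95.0, length=90, qlen=100, slen=100, evalue=1e-30):
        return AlignmentHit("q", "s", pident, length, qlen, slen, 100.0, evalue)

    def test_each_criterion_rejects_exactly_one_hit(self):
        """Six hits each violating one criterion plus one passing hit leave
        exactly one survivor."""
        hits = [
            self._hit(length=75),                # coverage of query too low
            self._hit(length=80),                # coverage exactly 80% (strict)
            self._hit(pident=70.0),              # identity too low
            self._hit(pident=80.0),              # identity exactly 80 (strict)
            self._hit(evalue=1e-5),              # E-value too large
            self._hit(slen=150),                 # subject coverage too low
            self._hit(),                         # passes everything
        ]
        kept = filter_hits(hits)
        assert len(kept) == 1
        assert kept[0] is hits[-1]

    def test_identity_exactly_80_rejected(self):
        assert filter_hits([self._hit(pident=80.0)]) == []

    def test_evalue_absent_is_accepted(self):
        assert len(filter_hits([self._hit(evalue=None)])) == 1

    def test_empty_input_empty_output(self):
        assert filter_hits([]) == []

    def test_monotonicity_raising_thresholds(self, rng):
        hits = [
            self._hit(
                pident=float(rng.uniform(60, 100)),
                length=int(rng.integers(60, 100)),
                evalue=float(10.0 ** -rng.integers(1, 40)),
            )
            for _ in range(100)
        ]
        base = len(filter_hits(hits))
        for t in (
            FilterThresholds(coverage=0.9),
            FilterThresholds(identity=90.0),
            FilterThresholds(e_value=1e-20),
        ):
            assert len(filter_hits(hits, t)) <= base


class TestAligner:
    def test_identical_sequences(self):
        a = _rec("a", "MKLVINSEQ")
        b = _rec("b", "MKLVINSEQ")
        hit = align_pairwise(a, b)
        assert hit.percent_identity == 100.0
        assert hit.alignment_length == 9

    def test_symmetry(self):
        a = _rec("a", "HEAGAWGHEE")
        b = _rec("b", "PAWHEAE")
        h1 = align_pairwise(a, b)
        h2 = align_pairwise(b, a)
        assert h1.score == h2.score
        assert h1.percent_identity == pytest.approx(h2.percent_identity)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pairwise(_rec("a", ""), _rec("b", "MK"))

    def test_textbook_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        hit = align_pairwise(_rec("a", a), _rec("b", b))
        assert hit.score == pytest.approx(gotoh_oracle(a, b))

    def test_random_short_pairs_match_dp_oracle(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(50):
            s1 = "".join(rng.choice(alphabet, size=rng.integers(3, 11)))
            s2 = "".join(rng.choice(alphabet, size=rng.integers(3, 11)))
            hit = align_pairwise(_rec("a", s1), _rec("b", s2))
            assert hit.score == pytest.approx(gotoh_oracle(s1, s2)), (s1, s2)


class TestPairing:
    def _hits_from_scores(self, scores):
        return [
            AlignmentHit(q, s, 95.0, 90, 100, 100, sc, 1e-30)
            for (q, s), sc in scores.items()
        ]

    def test_mutual_best_cross_subgenome_is_homeolog(self):
        hits = self._hits_from_scores({("a1", "b1"): 200.0})
        pairs = pair_homologs(hits, {"a1": "A", "b1": "B"})
        assert len(pairs) == 1
        assert pairs[0].relation == "homeolog"
        assert (pairs[0].id_a, pairs[0].id_b) == ("a1", "b1")

    def test_rbh_on_toy_score_table(self):
        """A1<->A2 mutual best leaves A3 unpaired (brute-force RBH)."""
        scores = {
            ("A1", "A2"): 300.0,
            ("A1", "A3"): 150.0,
            ("A2", "A3"): 100.0,
        }
        sub = {"A1": "A", "A2": "A", "A3": "A"}
        pairs = pair_homologs(self._hits_from_scores(scores), sub)
        assert len(pairs) == 1
        assert {pairs[0].id_a, pairs[0].id_b} == {"A1", "A2"}
        assert pairs[0].relation == "paralog"

    def test_rbh_matches_exhaustive_enumeration_on_toy_sets(self, rng):
        """On <= 8-protein random score tables, pair_homologs equals a
        brute-force enumeration of mutual best hits per relation class."""
        for trial in range(20):
            ids = [f"P{i}" for i in range(int(rng.integers(4, 9)))]
            sub = {i: ("A" if rng.random() < 0.5 else "B") for i in ids}
            scores = {}
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    if rng.random() < 0.7:
                        scores[(a, b)] = float(np.round(rng.uniform(10, 300), 1))
            pairs = pair_homologs(self._hits_from_scores(scores), sub)
            # oracle: exhaustive mutual-best search
            def relation(a, b):
                return "paralog" if sub[a] == sub[b] else "homeolog"
            def score(a, b):
                return scores.get((a, b), scores.get((b, a)))
            expected = set()
            for a, b in scores:
                rel = relation(a, b)
                s_ab = score(a, b)
                best_a = max(
                    (score(a, x), x) for x in ids
                    if x != a and score(a, x) is not None and relation(a, x) == rel
                )
                best_b = max(
                    (score(b, x), x) for x in ids
                    if x != b and score(b, x) is not None and relation(b, x) == rel
                )
                if best_a[0] == s_ab and best_b[0] == s_ab:
                    expected.add((tuple(sorted((a, b))), rel))
            got = {((p.id_a, p.id_b), p.relation) for p in pairs}
            # ties can make the oracle's "a mutual best" non-unique; check
            # containment both ways on tie-free tables (scores rounded to .1
            # over a wide range are almost surely tie-free)
            assert got == expected, (scores, sub)

    def test_unassigned_excluded_from_homeolog_pairing(self):
        hits = self._hits_from_scores({("a1", "x1"): 200.0})
        pairs = pair_homologs(hits, {"a1": "A", "x1": "unassigned"})
        assert pairs == []

    def test_each_protein_in_at_most_one_pair_per_class(self, small_dataset):
        proteins, _, _, _ = small_dataset
        hits = homology.all_vs_all_hits(proteins)
        kept = filter_hits(hits)
        pairs = pair_homologs(kept, {p.id: p.sub_genome for p in proteins})
        for rel in ("paralog", "homeolog"):
            members = [
                pid for p in pairs if p.relation == rel for pid in (p.id_a, p.id_b)
            ]
            assert len(members) == len(set(members))

    def test_truth_recovery_on_synthetic_fixture(self):
        """With zero alignment noise and divergence comfortably inside the
        filters, recovered pairs equal the generator's truth exactly."""
        from homeoprot import simulate

        cfg = simulate.SimulationConfig(
            n_families=10, paralog_fraction=0.5, n_codons=200,
            ks_target=0.1, omega_range=(0.05, 0.3), seed=3,
        )
        proteins, _, truth = simulate.simulate_families(cfg)
        hits = homology.all_vs_all_hits(proteins)
        pairs = pair_homologs(filter_hits(hits), {p.id: p.sub_genome for p in proteins})
        got = {(p.id_a, p.id_b, p.relation) for p in pairs}
        expected = {(p.id_a, p.id_b, p.relation) for p in truth.pairs}
        assert got == expected

    def test_subgenome_relabel_swaps_no_relations(self):
        scores = {("a1", "b1"): 200.0, ("a1", "a2"): 150.0}
        sub = {"a1": "A", "a2": "A", "b1": "B"}
        swapped = {k: {"A": "B", "B": "A"}[v] for k, v in sub.items()}
        p1 = pair_homologs(self._hits_from_scores(scores), sub)
        p2 = pair_homologs(self._hits_from_scores(scores), swapped)
        assert {(p.id_a, p.id_b, p.relation) for p in p1} == {
            (p.id_a, p.id_b, p.relation) for p in p2
        }


class TestFastaRoundtrip:
    def test_chromosome_and_subgenome_survive(self, small_dataset, tmp_path):
        proteins, _, _, _ = small_dataset
        homology.write_fasta(proteins, tmp_path / "p.faa")
        back = homology.read_fasta(tmp_path / "p.faa", "protein")
        assert {(r.id, r.sequence, r.chromosome, r.sub_genome) for r in back} == {
            (r.id, r.sequence, r.chromosome, r.sub_genome) for r in proteins
        }
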