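import pytest
from hypothesis import given
from hypothesis import strategies as st

from rhombosort import (
    GenomeSet,
    ProteinRecord,
    RankedHitList,
    ScoringParams,
    import_ranked_hits,
    pairwise_identity,
    rank_homologs,
    read_genome_set,
    reduce_redundancy,
)
from rhombosort.sequence_io import AMINO_ACIDS, LoadError, local_score

aa_seq = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40)


def _record(pid="p1", gid="g1", idx=0, seq="MKTAYIAK"):
    return ProteinRecord(pid, gid, "chr", idx, "+", seq)


class TestRecords:
    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            _record(seq="")

    def test_duplicate_protein_id_rejected(self):
        with pytest.raises(LoadError):
            GenomeSet([_record(), _record(idx=1)])

    def test_duplicate_gene_index_rejected(self):
        with pytest.raises(LoadError):
            GenomeSet([_record(), _record(pid="p2", idx=0)])

    def test_ordering_within_replicon(self):
        gs = GenomeSet([_record(pid="b", idx=5), _record(pid="a", idx=2)])
        assert [r.protein_id for r in gs.genomes["g1"]] == ["a", "b"]


class TestReadWrite:
    def test_single_protein_round(self, tmp_path):
        gs = GenomeSet([_record()])
        gs.write(tmp_path / "p.fasta", tmp_path / "p.tsv")
        assert read_genome_set(tmp_path / "p.fasta", tmp_path / "p.tsv") == gs

    def test_generated_pangenome_round_trip(self, small_pangenome, tmp_path):
        gs, _ = small_pangenome
        gs.write(tmp_path / "pan.fasta", tmp_path / "pan.tsv")
        assert read_genome_set(tmp_path / "pan.fasta", tmp_path / "pan.tsv") == gs

    def test_table_row_without_fasta_record_errors(self, tmp_path):
        (tmp_path / "p.fasta").write_text(">p1\nMKT\n")
        (tmp_path / "p.tsv").write_text(
            "genome_id\treplicon_id\tgene_index\tstrand\tprotein_id\n"
            "g1\tchr\t1\t+\tp1\ng1\tchr\t2\t+\tp2\n"
        )
        with pytest.raises(LoadError, match="p2"):
            read_genome_set(tmp_path / "p.fasta", tmp_path / "p.tsv")


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == 1.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("KKKKKKKK", "DDDDDDDD") == 0.0

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # hand-counted global alignments of 10-mers (no-gap optimum)
            ("MKTAYIAKQR", "MKTAYIAKQR", 1.0),
            ("MKTAYIAKQR", "MKTAYIGKQR", 0.9),
            ("MKTAYIAKQR", "MKTWYIGKQL", 0.7),
            ("AAAAAPAAAA", "AAAAAAAAAA", 0.9),
        ],
    )
    def test_hand_counted_ten_mers(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_terminal_overhang_excluded(self):
        # identical core, long unmatched tail: overhang must not dilute
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQRDDDDDDDDDD") == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKT")

    @given(a=aa_seq, b=aa_seq)
    def test_symmetric(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def _greedy_oracle(items, max_identity):
    """Independent greedy re-implementation: longest first, id tiebreak."""
    pending = sorted(items, key=lambda kv: (-len(kv[1]), kv[0]))
    kept = []
    for sid, seq in pending:
        ok = True
        for _kid, kseq in kept:
            if pairwise_identity(seq, kseq) > max_identity:
                ok = False
                break
        if ok:
            kept.append((sid, seq))
    return [sid for sid, _ in kept]


class TestReduceRedundancy:
    def test_exact_duplicates_single_survivor(self):
        out = reduce_redundancy({"a": "MKTAYIAKQR", "b": "MKTAYIAKQR"}, 0.8)
        assert out == ["a"]

    def test_distinct_set_unchanged(self):
        seqs = {"a": "KKKKKKKKKK", "b": "DDDDDDDDDD", "c": "WWWWWWWWWW"}
        assert sorted(reduce_redundancy(seqs, 0.5)) == ["a", "b", "c"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            reduce_redundancy({"a": "MKT"}, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_greedy(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        seqs = {}
        for i in range(10):
            chars = list(base)
            for j in range(len(chars)):
                if rng.random() < 0.25:
                    chars[j] = AMINO_ACIDS[rng.integers(20)]
            seqs[f"s{i}"] = "".join(chars)[: rng.integers(20, 31)]
        assert reduce_redundancy(seqs, 0.8) == _greedy_oracle(list(seqs.items()), 0.8)

    def test_retained_pairs_below_threshold(self, small_pangenome):
        gs, truth = small_pangenome
        fam = {pid: gs.get_protein(pid).sequence for pid in truth.enzyme_ids[:12]}
        kept = reduce_redundancy(fam, 0.8)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert pairwise_identity(fam[a], fam[b]) <= 0.8


class TestRankHomologs:
    EXHAUSTIVE = ScoringParams(score_floor=0.0, max_hits=None, max_candidates=None)

    def _db(self, seqs):
        return GenomeSet(
            [ProteinRecord(f"p{i}", f"g{i}", "chr", 0, "+", s) for i, s in enumerate(seqs)]
        )

    def test_self_hit_is_rank_one(self):
        db = self._db(["MKTAYIAKQRQISFVK", "DDDDDDDDDDDD", "WWWWWWWWWWWW"])
        hits = rank_homologs(db.get_protein("p0"), db, self.EXHAUSTIVE)
        assert hits.hits[0][0] == "p0"

    def test_order_matches_independent_scoring(self):
        seqs = ["MKTAYIAKQRQISFVKSHF", "MKTAYIGKQRQISFVKAHF", "MKTWYIAKQLQISAVKSHF", "GGSGGSGGSGGS"]
        db = self._db(seqs)
        q = db.get_protein("p0")
        hits = rank_homologs(q, db, self.EXHAUSTIVE)
        expected = sorted(
            ((local_score(q.sequence, s), f"p{i}") for i, s in enumerate(seqs)),
            key=lambda t: (-t[0], t[1]),
        )
        assert [h[0] for h in hits.hits] == [pid for _s, pid in expected]
        assert [h[2] for h in hits.hits] == [s for s, _pid in expected]

    def test_all_below_floor_empty(self):
        db = self._db(["MKTAYIAKQR", "DDDDDDDDDD"])
        params = ScoringParams(score_floor=1e6, max_hits=None, max_candidates=None)
        assert len(rank_homologs(db.get_protein("p0"), db, params)) == 0

    def test_permutation_invariant(self):
        seqs = ["MKTAYIAKQRQISFVKSHF", "MKTAYIGKQRQISFVKAHF", "MKTWYIAKQLQISAVKSHF"]
        recs = [ProteinRecord(f"p{i}", f"g{i}", "chr", 0, "+", s) for i, s in enumerate(seqs)]
        a = rank_homologs(recs[0], GenomeSet(recs), self.EXHAUSTIVE)
        b = rank_homologs(recs[0], GenomeSet(reversed(recs)), self.EXHAUSTIVE)
        assert a.hits == b.hits

    def test_prefilter_agrees_with_exhaustive_on_family(self, small_pangenome):
        gs, truth = small_pangenome
        q = gs.get_protein(sorted(truth.cognates.values())[0])
        fast = rank_homologs(q, gs, ScoringParams(score_floor=150.0, max_hits=None))
        slow = rank_homologs(q, gs, ScoringParams(score_floor=150.0, max_hits=None, max_candidates=None))
        assert fast.hits == slow.hits


class TestImportExport:
    def test_round_trip(self, tmp_path):
        rl = RankedHitList("q", [("s1", "g1", 300.0), ("s2", "g2", 120.5)])
        rl.write(tmp_path / "hits.tsv")
        back = import_ranked_hits(tmp_path / "hits.tsv", {"s1": "g1", "s2": "g2"})
        assert back.query_id == "q" and back.hits == rl.hits

    def test_empty_file(self, tmp_path):
        (tmp_path / "hits.tsv").write_text("")
        assert len(import_ranked_hits(tmp_path / "hits.tsv", {}, query_id="q")) == 0

    def test_duplicate_subject_keeps_best(self, tmp_path):
        rows = [
            "q\ts1\t90\t10\t1\t0\t1\t10\t1\t10\t1e-5\t50",
            "q\ts1\t95\t10\t0\t0\t1\t10\t1\t10\t1e-9\t80",
        ]
        (tmp_path / "hits.tsv").write_text("\n".join(rows) + "\n")
        back = import_ranked_hits(tmp_path / "hits.tsv", {"s1": "g1"})
        assert back.hits == [("s1", "g1", 80.0)]

    def test_unmappable_subject_errors(self, tmp_path):
        (tmp_path / "hits.tsv").write_text("q\ts1\t90\t10\t1\t0\t1\t10\t1\t10\t1e-5\t50\n")
        with pytest.raises(LoadError, match="s1"):
            import_ranked_hits(tmp_path / "hits.tsv", {})
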