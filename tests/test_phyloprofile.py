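import math

import numpy as np
import pytest

from rhombosort import (
    GenomeSet,
    PhyloProfile,
    ProteinRecord,
    RankedHitList,
    binomial_score,
    build_profile,
    ppp_genome,
    ppp_score_protein,
)


def _genome_set(n_genomes=5, per_genome=2):
    recs = [
        ProteinRecord(f"g{g}_p{i}", f"g{g}", "chr", i, "+", "MKTAYIAKQR")
        for g in range(n_genomes)
        for i in range(per_genome)
    ]
    return GenomeSet(recs)


class TestBuildProfile:
    def test_basic_counts(self):
        gs = _genome_set()
        prof = build_profile(gs, ["g0_p0", "g1_p0"], min_count=1)
        assert prof.K == 2 and prof.N == 5 and not prof.excluded

    def test_single_hit_excluded_under_min_count_two(self):
        gs = _genome_set()
        prof = build_profile(gs, ["g0_p0", "g0_p1", "g1_p0"], min_count=2)
        assert prof.labels["g0"] == 1
        assert "g1" in prof.excluded and "g1" not in prof.labels
        assert prof.N == 4 and prof.K == 1

    def test_no_hits(self):
        prof = build_profile(_genome_set(), [], min_count=1)
        assert prof.K == 0 and prof.N == 5

    def test_empty_genome_set_errors(self):
        with pytest.raises(ValueError):
            build_profile(GenomeSet([]), [])

    def test_round_trip(self, tmp_path):
        gs = _genome_set()
        prof = build_profile(gs, ["g0_p0", "g0_p1", "g1_p0"], min_count=2)
        prof.write(tmp_path / "prof.tsv")
        assert PhyloProfile.read(tmp_path / "prof.tsv") == prof


def _oracle_log10_pmf(n, k, p_num, p_den):
    """Arbitrary-precision -log10 binomial pmf via exact rationals."""
    from fractions import Fraction

    import mpmath

    p = Fraction(p_num, p_den)
    prob = Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k)
    return float(-mpmath.log(mpmath.mpf(prob.numerator) / mpmath.mpf(prob.denominator), 10))


class TestBinomialScore:
    def test_printed_score_reproduced(self):
        s = binomial_score(107, 104, 108, 1465, "point")
        assert s.score == pytest.approx(112.572, abs=0.002)

    def test_closed_form_small_case(self):
        s = binomial_score(3, 0, 1, 2, "point")
        assert s.score == pytest.approx(-math.log10(0.125), abs=1e-12)

    def test_against_high_precision_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 501))
            k = int(rng.integers(0, n + 1))
            N = int(rng.integers(10, 2001))
            K = int(rng.integers(1, N))
            got = binomial_score(n, k, K, N, "point").score
            want = _oracle_log10_pmf(n, k, K, N)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_upper_tail_sums_point_terms(self):
        # tail mass equals the log-sum of point masses, checked via the oracle
        n, k, K, N = 40, 30, 20, 100
        tail = binomial_score(n, k, K, N, "upper_tail").score
        terms = [10 ** -_oracle_log10_pmf(n, j, K, N) for j in range(k, n + 1)]
        assert tail == pytest.approx(-math.log10(sum(terms)), rel=1e-9)

    def test_invalid_ranges(self):
        for n, k, K, N in [(0, 0, 1, 2), (3, 4, 1, 2), (3, 1, 0, 2), (3, 1, 2, 2)]:
            with pytest.raises(ValueError):
                binomial_score(n, k, K, N)

    def test_monotone_in_k_in_enrichment_regime(self):
        for mode in ("point", "upper_tail"):
            for n, K, N in [(50, 10, 100), (200, 30, 500)]:
                lo = math.ceil(n * K / N)
                scores = [binomial_score(n, k, K, N, mode).score for k in range(lo, n + 1)]
                assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_monotone_in_n_at_full_agreement(self):
        scores = [binomial_score(n, n, 10, 100, "point").score for n in range(1, 50)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_no_underflow_at_large_depth(self):
        s = binomial_score(10_000, 9_000, 100, 1000, "point")
        assert np.isfinite(s.score) and s.score > 0

    def test_point_close_to_tail_when_strongly_enriched(self):
        # in the strong-enrichment regime the tail is dominated by its first term
        for n, k, K, N in [(107, 104, 108, 1465), (100, 96, 108, 1465), (50, 49, 10, 100)]:
            point = binomial_score(n, k, K, N, "point").score
            tail = binomial_score(n, k, K, N, "upper_tail").score
            assert abs(point - tail) < 0.01


def _profile(n_yes, n_no):
    labels = {f"y{i}": 1 for i in range(n_yes)}
    labels.update({f"n{i}": 0 for i in range(n_no)})
    return PhyloProfile(labels=labels)


def _brute_force_best(hit_list, profile, mode="point"):
    """Exhaustive prefix maximization, independent of the walk implementation."""
    best = (0.0, 0)
    for depth in range(1, len(hit_list.hits) + 1):
        genomes = []
        for sid, gid, _s in hit_list.hits[:depth]:
            if gid not in profile.excluded and gid not in genomes:
                genomes.append(gid)
        n = len(genomes)
        if n == 0:
            continue
        k = sum(profile.labels[g] for g in genomes)
        score = binomial_score(n, k, profile.K, profile.N, mode).score
        if score > best[0] + 1e-12:
            best = (score, depth)
    return best


class TestPPPScore:
    def test_table_arithmetic_list(self):
        labels = {f"y{i}": 1 for i in range(108)}
        labels.update({f"n{i}": 0 for i in range(1465 - 108)})
        profile = PhyloProfile(labels=labels)
        hits = [(f"s{i}", f"n{i}", 1000.0 - i) for i in range(3)]
        hits += [(f"s{i + 3}", f"y{i}", 900.0 - i) for i in range(104)]
        result = ppp_score_protein(RankedHitList("q", hits), profile)
        assert result.best.score == pytest.approx(112.572, abs=0.002)
        assert result.best.n == 107 and result.best.k == 104
        assert result.depth == 107

    def test_all_no_genomes_closed_form(self):
        profile = _profile(2, 8)
        hits = [(f"s{i}", f"n{i}", 100.0 - i) for i in range(5)]
        result = ppp_score_protein(RankedHitList("q", hits), profile)
        # k=0 at every depth: best is the deepest prefix of the cheap kind
        expected = max(
            -math.log10((1 - profile.p) ** n) + math.log10(math.comb(n, 0)) for n in range(1, 6)
        )
        assert result.best.k == 0
        assert result.best.score == pytest.approx(expected)

    def test_empty_list(self):
        result = ppp_score_protein(RankedHitList("q", []), _profile(2, 8))
        assert result.best.score == 0.0 and result.depth == 0

    def test_excluded_genomes_skipped(self):
        labels = {"y0": 1, "y1": 1, "n0": 0, "n1": 0}
        profile = PhyloProfile(labels=labels, excluded=frozenset({"x0"}))
        hits = [("a", "x0", 10.0), ("b", "y0", 9.0), ("c", "y1", 8.0)]
        result = ppp_score_protein(RankedHitList("q", hits), profile)
        assert result.best.n == 2 and result.best.k == 2

    def test_unknown_genome_errors(self):
        with pytest.raises(KeyError):
            ppp_score_protein(RankedHitList("q", [("a", "zz", 1.0)]), _profile(2, 2))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_prefix_maximization(self, seed):
        rng = np.random.default_rng(seed)
        profile = _profile(6, 24)
        genome_pool = list(profile.labels)
        for _ in range(20):
            m = int(rng.integers(1, 40))
            gids = rng.choice(genome_pool, size=m, replace=True)
            hits = [(f"s{i}", str(g), float(1000 - i)) for i, g in enumerate(gids)]
            rl = RankedHitList("q", hits)
            got = ppp_score_protein(rl, profile)
            want_score, want_depth = _brute_force_best(rl, profile)
            assert got.best.score == pytest.approx(want_score)
            assert got.depth == want_depth

    def test_invariant_under_genome_relabeling(self):
        profile = _profile(3, 7)
        hits = [("a", "y0", 5.0), ("b", "n0", 4.0), ("c", "y1", 3.0)]
        base = ppp_score_protein(RankedHitList("q", hits), profile)
        renamed = PhyloProfile(
            labels={f"Z_{g}": l for g, l in profile.labels.items()}
        )
        hits2 = [(s, f"Z_{g}", v) for s, g, v in hits]
        again = ppp_score_protein(RankedHitList("q", hits2), renamed)
        assert again.best.score == base.best.score


class TestPPPGenome:
    def test_single_protein_genome(self, small_pangenome):
        gs, truth = small_pangenome
        profile = build_profile(gs, list(truth.targets))
        gid = sorted(gs.genomes)[0]
        results = ppp_genome(gid, gs, profile)
        assert len(results) == len(gs.genomes[gid])
        scores = [r.best.score for r in results]
        assert scores == sorted(scores, reverse=True)

    def test_unknown_genome_errors(self, small_pangenome):
        gs, truth = small_pangenome
        profile = build_profile(gs, list(truth.targets))
        with pytest.raises(KeyError):
            ppp_genome("nope", gs, profile)

    def test_deterministic_rerun(self, small_pangenome):
        gs, truth = small_pangenome
        profile = build_profile(gs, list(truth.targets))
        gid = sorted(truth.cognates)[0]
        a = ppp_genome(gid, gs, profile)
        b = ppp_genome(gid, gs, profile)
        assert a == b
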