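"""Log-odds scanning: exact p-value DP, strand handling, Storey q-values."""

import dataclasses
import itertools
import math

import numpy as np
import pytest

from promscan import (
    BackgroundModel,
    assign_qvalues,
    build_score_distribution,
    scan_promoter,
    scan_promoters,
    storey_qvalues,
    to_log_odds,
    window_score,
)
from promscan.promoters import PromoterRecord
from promscan.scan import PredictedSite
from promscan._seq import revcomp

from conftest import make_matrix, random_matrix, sharp_matrix


def _prom(seq, gene="g1", species="sp"):
    return PromoterRecord(gene, species, "chr1", 1, len(seq), "+", seq)


class TestWindowScore:
    def test_uniform_motif_scores_zero(self, uniform_bg):
        m = make_matrix("u", [[0.25] * 4] * 4)
        lo = to_log_odds(m, uniform_bg)
        assert window_score(lo, "ACGT") == pytest.approx(0.0, abs=1e-6)

    def test_consensus_of_deterministic_motif(self, uniform_bg):
        m = make_matrix("d", [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]])
        lo = to_log_odds(m, uniform_bg)
        assert window_score(lo, "ACT") == pytest.approx(6.0, abs=1e-6)

    def test_window_with_n_unscorable(self, uniform_bg):
        m = make_matrix("d", [[1, 0, 0, 0]] * 3)
        lo = to_log_odds(m, uniform_bg)
        assert window_score(lo, "ANA") is None


def _enumeration_tail(dist, bg):
    """Independent oracle: enumerate all 4^L windows, tally binned tails."""
    L = dist.column_bins.shape[0]
    q = bg.as_array()
    mass: dict[int, float] = {}
    for w in itertools.product(range(4), repeat=L):
        s = sum(int(dist.column_bins[j, b]) for j, b in enumerate(w))
        pr = float(np.prod([q[b] for b in w]))
        mass[s] = mass.get(s, 0.0) + pr
    tail = {}
    acc = 0.0
    for s in sorted(mass, reverse=True):
        acc += mass[s]
        tail[s] = acc
    return tail


class TestScoreDistribution:
    def test_deterministic_l3_max_score_probability(self, uniform_bg):
        m = make_matrix("d", [[1, 0, 0, 0]] * 3)
        lo = to_log_odds(m, uniform_bg)
        dist = build_score_distribution(lo, uniform_bg)
        kmax = dist.kmin + len(dist.tail) - 1
        assert dist.pvalue_of_binsum(kmax) == pytest.approx((1 / 4) ** 3)

    def test_tail_at_min_is_one_and_non_increasing(self, uniform_bg):
        rng = np.random.default_rng(20)
        dist = build_score_distribution(
            to_log_odds(random_matrix(rng, 5), uniform_bg), uniform_bg
        )
        assert dist.tail[0] == pytest.approx(1.0)
        assert np.all(np.diff(dist.tail) <= 1e-15)

    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_dp_matches_enumeration(self, L):
        rng = np.random.default_rng(30 + L)
        bg = BackgroundModel("b", (0.28, 0.22, 0.22, 0.28))
        m = random_matrix(rng, L)
        dist = build_score_distribution(to_log_odds(m, bg), bg)
        oracle = _enumeration_tail(dist, bg)
        for s, p in oracle.items():
            assert dist.pvalue_of_binsum(s) == pytest.approx(p, abs=1e-9)


class TestScanPromoter:
    @pytest.fixture
    def setup(self, uniform_bg):
        rng = np.random.default_rng(40)
        m = sharp_matrix("M1", [0, 1, 2, 3, 0, 1, 2, 3, 0, 1])
        lo = to_log_odds(m, uniform_bg)
        dist = build_score_distribution(lo, uniform_bg)
        background = "".join(np.random.default_rng(41).choice(list("ACGT"), 300))
        return m, lo, dist, background

    def test_planted_consensus_found_at_exact_coordinates(self, setup):
        m, lo, dist, bgseq = setup
        cons = m.consensus()
        seq = bgseq[:100] + cons + bgseq[110:]
        sites = scan_promoter(lo, _prom(seq), dist)
        hits = [(s.start, s.stop, s.strand) for s in sites if s.matched_seq == cons]
        assert (101, 110, "+") in hits

    def test_reverse_complement_planted_found_on_minus_strand(self, setup):
        m, lo, dist, bgseq = setup
        cons = m.consensus()
        seq = bgseq[:100] + revcomp(cons) + bgseq[110:]
        sites = scan_promoter(lo, _prom(seq), dist)
        hits = [(s.start, s.stop, s.strand, s.matched_seq) for s in sites]
        assert (101, 110, "-", cons) in hits

    def test_promoter_shorter_than_motif_yields_empty(self, setup):
        m, lo, dist, _ = setup
        assert scan_promoter(lo, _prom("ACGTA"), dist) == []

    def test_windows_with_n_are_skipped(self, setup):
        m, lo, dist, bgseq = setup
        cons = m.consensus()
        broken = cons[:5] + "N" + cons[6:]
        seq = bgseq[:100] + broken + bgseq[110:]
        sites = scan_promoter(lo, _prom(seq), dist)
        assert not any(s.start == 101 and s.strand == "+" for s in sites)

    def test_strand_symmetry_exact(self, setup):
        m, lo, dist, bgseq = setup
        seq = bgseq[:50] + m.consensus() + bgseq[60:200]
        p = _prom(seq)
        p_rc = dataclasses.replace(p, sequence=revcomp(seq))
        L = p.length
        fwd = sorted((s.start, s.stop, s.strand, s.score, s.p_value)
                     for s in scan_promoter(lo, p, dist))
        mirrored = sorted(
            (L - s.stop + 1, L - s.start + 1, "+" if s.strand == "-" else "-", s.score, s.p_value)
            for s in scan_promoter(lo, p_rc, dist)
        )
        assert fwd == mirrored  # bit-exact scores and p-values


class TestQValues:
    def test_bh_formula_with_pi0_one(self):
        # 10 candidates all at p = 0.01: worst rank gives q = m p / m = p
        p = np.full(10, 0.01)
        q = storey_qvalues(p, pi0=1.0)
        np.testing.assert_allclose(q, 0.01)

    def test_single_candidate_p_one(self):
        assert storey_qvalues(np.array([1.0]), pi0=1.0)[0] == pytest.approx(1.0)

    def test_monotone_in_p_within_stratum(self):
        rng = np.random.default_rng(50)
        p = np.sort(rng.uniform(size=100))
        q = storey_qvalues(p)
        assert np.all(np.diff(q) >= -1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.0]))

    def test_assign_qvalues_strata_and_threshold(self):
        sites = [
            PredictedSite("m1", "t", "f", "g1", 1, 5, "+", 1.0, 1e-6, species="a"),
            PredictedSite("m1", "t", "f", "g2", 1, 5, "+", 1.0, 0.9, species="a"),
            PredictedSite("m2", "t", "f", "g1", 1, 5, "+", 1.0, 1e-6, species="a"),
        ]
        kept = assign_qvalues(sites, q_max=0.2, pi0=1.0)
        assert {(s.motif_id, s.gene_id) for s in kept} == {("m1", "g1"), ("m2", "g1")}
        assert all(not math.isnan(s.q_value) for s in kept)

    def test_null_set_inflates_q_of_marginal_candidates(self, uniform_bg):
        # the same candidate p is judged against the full scored-window set
        cand = np.array([1e-3])
        null = np.concatenate([cand, np.linspace(1e-3, 1, 10_000)])
        q_alone = storey_qvalues(cand, pi0=1.0)[0]
        q_vs_null = storey_qvalues(cand, null_p=null, pi0=1.0)[0]
        assert q_vs_null > q_alone


def test_scan_promoters_null_strata_keys(uniform_bg):
    rng = np.random.default_rng(60)
    m = sharp_matrix("M1", [0, 1, 2, 3, 0, 1])
    lo = to_log_odds(m, uniform_bg)
    dist = build_score_distribution(lo, uniform_bg)
    proms = [_prom("".join(rng.choice(list("ACGT"), 100)), gene=f"g{i}") for i in range(3)]
    cands, nulls = scan_promoters(lo, proms, dist)
    assert set(nulls) == {("M1", "sp")}
    # both strands of every scorable window contribute to the null set
    assert len(nulls[("M1", "sp")]) == 3 * 2 * (100 - 6 + 1)
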