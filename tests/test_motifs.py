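"""Position-matrix parsing, log-odds, similarity, deduplication and DKL."""

import math

import numpy as np
import pytest

from promscan import (
    BackgroundModel,
    MotifParseError,
    PositionMatrix,
    deduplicate,
    dkl_index,
    motif_similarity,
    parse_motifs,
    reverse_complement,
    to_log_odds,
)

from conftest import make_matrix, random_matrix, sharp_matrix

JASPAR_DOC = """\
>MA0001.1 TF_A
A [ 4  0  2  0 ]
C [ 0  0  2  0 ]
G [ 0  4  0  2 ]
T [ 0  0  0  2 ]
>MA0002.1 TF_B
A [ 2 2 2 2 ]
C [ 2 2 2 2 ]
G [ 2 2 2 2 ]
T [ 2 2 2 2 ]
"""

MEME_DOC = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M_PROB tf_prob
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
 0.5 0.5 0.0 0.0
 0.0 0.0 1.0 0.0
 0.25 0.25 0.25 0.25
"""


class TestParsing:
    def test_jaspar_counts_normalized(self):
        motifs = parse_motifs(JASPAR_DOC, fmt="jaspar")
        m = motifs[0]
        assert m.motif_id == "MA0001.1"
        np.testing.assert_allclose(m.probs[0], [1, 0, 0, 0])
        np.testing.assert_allclose(m.probs[2], [0.5, 0.5, 0, 0])
        assert m.counts is not None

    def test_symmetric_counts_give_uniform_columns(self):
        motifs = parse_motifs(JASPAR_DOC, fmt="jaspar")
        np.testing.assert_allclose(motifs[1].probs, 0.25)

    def test_meme_probabilities_pass_through(self):
        (m,) = parse_motifs(MEME_DOC, fmt="meme")
        np.testing.assert_allclose(m.probs[0], [0.5, 0.5, 0, 0])
        np.testing.assert_allclose(m.probs[2], [0.25] * 4)

    def test_metadata_join_and_unknown_family(self):
        import pandas as pd

        meta = pd.DataFrame(
            {"motif_id": ["MA0001.1"], "tf_name": ["TFA"], "tf_family": ["MADS box"],
             "species": ["ath"], "evidence": ["experimental"]}
        )
        motifs = parse_motifs(JASPAR_DOC, metadata=meta, fmt="jaspar")
        assert motifs[0].tf_family == "MADS box"
        assert motifs[0].evidence == "experimental"
        assert motifs[1].tf_family == "unknown"

    def test_negative_counts_rejected(self):
        with pytest.raises(MotifParseError):
            PositionMatrix("bad", np.full((2, 4), 0.25), counts=np.array([[1, -1, 0, 0]] * 2))

    def test_malformed_document_names_error(self):
        with pytest.raises(MotifParseError):
            parse_motifs(">M1\nA [ 1 2 ]\nC [ 1 2 ]\n", fmt="jaspar")


class TestLogOdds:
    def test_uniform_column_uniform_bg_scores_zero(self, uniform_bg):
        m = make_matrix("u", [[0.25] * 4] * 3)
        lo = to_log_odds(m, uniform_bg)
        np.testing.assert_allclose(lo.scores, 0.0, atol=1e-7)

    def test_deterministic_column_formula(self, uniform_bg):
        # oracle: direct evaluation of log2(((p + eps)/(1 + 4 eps)) / q)
        eps = 1e-8
        m = make_matrix("d", [[1, 0, 0, 0]])
        lo = to_log_odds(m, uniform_bg, pseudo=eps)
        expect_a = math.log2(((1 + eps) / (1 + 4 * eps)) / 0.25)
        expect_c = math.log2((eps / (1 + 4 * eps)) / 0.25)
        assert lo.scores[0, 0] == pytest.approx(expect_a)
        assert lo.scores[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert lo.scores[0, 1] == pytest.approx(expect_c)
        assert lo.scores[0, 1] == pytest.approx(-24.575, abs=1e-3)

    def test_zero_pseudo_rejected(self, uniform_bg):
        with pytest.raises(ValueError):
            to_log_odds(make_matrix("d", [[1, 0, 0, 0]]), uniform_bg, pseudo=0.0)

    def test_exactly_invertible(self):
        rng = np.random.default_rng(11)
        bg = BackgroundModel("b", (0.3, 0.2, 0.2, 0.3))
        m = random_matrix(rng, 7)
        lo = to_log_odds(m, bg, pseudo=1e-6)
        np.testing.assert_allclose(lo.to_probabilities(bg), m.probs, atol=1e-12)


class TestReverseComplement:
    def test_single_column_a_to_t(self):
        m = make_matrix("a", [[1, 0, 0, 0]])
        np.testing.assert_allclose(reverse_complement(m).probs, [[0, 0, 0, 1]])

    def test_involution(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6)
        np.testing.assert_allclose(reverse_complement(reverse_complement(m)).probs, m.probs)

    def test_palindrome_fixed_point(self):
        rng = np.random.default_rng(4)
        half = rng.dirichlet(np.ones(4), size=3)
        probs = np.vstack([half, half[::-1, ::-1]])
        m = make_matrix("pal", probs)
        np.testing.assert_allclose(reverse_complement(m).probs, m.probs)


def _oracle_similarity(a: PositionMatrix, b: PositionMatrix) -> float:
    """Independent exhaustive offset/orientation scan with np.corrcoef."""
    best = -np.inf
    min_ov = math.ceil(0.7 * min(a.length, b.length))
    for bp in (b.probs, b.probs[::-1, ::-1]):
        for off in range(-(b.length - 1), a.length):
            lo, hi = max(0, off), min(a.length, off + b.length)
            if hi - lo < min_ov:
                continue
            rs = []
            for j in range(lo, hi):
                x, y = a.probs[j], bp[j - off]
                if x.std() == 0 or y.std() == 0:
                    rs.append(1.0 if (x.std() == 0 and y.std() == 0 and np.allclose(x, y)) else 0.0)
                else:
                    rs.append(np.corrcoef(x, y)[0, 1])
            best = max(best, float(np.mean(rs)))
    return best


class TestSimilarity:
    def test_self_similarity(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 8)
        rep = motif_similarity(m, m)
        assert rep.similarity == pytest.approx(1.0)
        assert rep.offset == 0 and rep.orientation == "forward"

    def test_revcomp_detected(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 8)
        rep = motif_similarity(m, reverse_complement(m))
        assert rep.similarity == pytest.approx(1.0)
        assert rep.orientation == "revcomp"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_matrix(rng, 8, "a"), random_matrix(rng, 8, "b")
        rep = motif_similarity(a, b)
        assert rep.similarity == pytest.approx(_oracle_similarity(a, b), abs=1e-12)
        assert -1.0 <= rep.similarity <= 1.0 + 1e-12

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        a, b = random_matrix(rng, 6, "a"), random_matrix(rng, 9, "b")
        assert motif_similarity(a, b).similarity == pytest.approx(
            motif_similarity(b, a).similarity, abs=1e-12
        )

    def test_short_motifs_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            motif_similarity(random_matrix(rng, 3), random_matrix(rng, 8))


class TestDeduplicate:
    def test_experimental_preferred_over_inferred(self):
        rng = np.random.default_rng(9)
        probs = rng.dirichlet(np.ones(4), size=8)
        exp = make_matrix("m_exp", probs, evidence="experimental")
        inf = make_matrix("m_inf", probs.copy(), evidence="inferred")
        kept, dropped = deduplicate([inf, exp])
        assert [m.motif_id for m in kept] == ["m_exp"]
        assert dropped == [("m_inf", "m_exp", pytest.approx(1.0))]

    def test_revcomp_pair_collapses(self):
        rng = np.random.default_rng(10)
        m = random_matrix(rng, 8, "fwd")
        rc = reverse_complement(m)
        rc.motif_id = "rc"
        kept, dropped = deduplicate([m, rc])
        assert len(kept) == 1 and len(dropped) == 1

    def test_dissimilar_all_kept(self):
        a = sharp_matrix("a", [0, 0, 0, 0, 0, 0, 0, 0])
        b = sharp_matrix("b", [2, 1, 2, 1, 2, 1, 2, 1])
        kept, dropped = deduplicate([a, b])
        assert len(kept) == 2 and dropped == []

    def test_order_stable_under_permutation(self):
        rng = np.random.default_rng(12)
        mats = [random_matrix(rng, 8, f"m{i}") for i in range(6)]
        mats.append(make_matrix("dup0", mats[0].probs.copy()))
        kept1, _ = deduplicate(mats)
        kept2, _ = deduplicate(mats[::-1])
        assert [m.motif_id for m in kept1] == [m.motif_id for m in kept2]

    def test_dropped_similar_to_representative(self):
        rng = np.random.default_rng(13)
        mats = [random_matrix(rng, 8, f"m{i}") for i in range(4)]
        mats.append(make_matrix("dup2", mats[2].probs.copy()))
        kept, dropped = deduplicate(mats)
        by_id = {m.motif_id: m for m in mats}
        for d_id, k_id, sim in dropped:
            assert sim > 0.8
            assert motif_similarity(by_id[d_id], by_id[k_id]).similarity == pytest.approx(sim)


class TestDKL:
    def test_uniform_motif_uniform_bg_zero(self, uniform_bg):
        m = make_matrix("u", [[0.25] * 4] * 5)
        assert dkl_index(m, uniform_bg) == pytest.approx(0.0)

    def test_deterministic_columns_closed_form(self, uniform_bg):
        for L in (1, 3, 7):
            m = make_matrix("d", [[0, 0, 1, 0]] * L)
            assert dkl_index(m, uniform_bg) == pytest.approx(-2.0 * L)

    def test_uniform_column_contributes_nothing(self, uniform_bg):
        rng = np.random.default_rng(14)
        m = random_matrix(rng, 6)
        extended = make_matrix("ext", np.vstack([m.probs, [[0.25] * 4]]))
        assert dkl_index(extended, uniform_bg) == pytest.approx(dkl_index(m, uniform_bg))

    def test_nonpositive_for_uniform_bg(self, uniform_bg):
        rng = np.random.default_rng(15)
        for _ in range(20):
            m = random_matrix(rng, 5)
            assert dkl_index(m, uniform_bg) <= 1e-12
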