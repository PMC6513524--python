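import math

import numpy as np
import pytest

from levikit.io import ProteinSequence
from levikit.similarity import (
    AlignmentParams,
    align_local,
    bsr_to_distance,
    build_bsr,
    ingest_score_csv,
    raw_to_bits,
)

from oracles import enumerate_local_score

PARAMS = AlignmentParams()


def p(seq, name="p"):
    return ProteinSequence(name, seq)


def test_self_alignment_is_diagonal_sum():
    # BLOSUM62 diagonal: A4 + C9 + D6 + E5 + F6 + G6 = 36
    assert align_local(p("ACDEFG"), p("ACDEFG")) == 36


def test_dissimilar_sequences_score_zero():
    assert align_local(p("KKKK"), p("PPPP")) == 0


def test_alignment_symmetry():
    a, b = p("MKVLEW"), p("MKLWEV")
    assert align_local(a, b) == align_local(b, a)


def test_alignment_params_validation():
    with pytest.raises(ValueError):
        AlignmentParams(gap_open=1, gap_extend=2)  # extend > open
    with pytest.raises(ValueError):
        AlignmentParams(lambda_=-0.1)


def test_alignment_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    matrix = PARAMS.substitution_matrix()
    alphabet = "ACGT"  # valid residues forming a reduced alphabet
    for _ in range(40):
        la, lb = rng.integers(1, 9, size=2)
        a = "".join(alphabet[i] for i in rng.integers(0, 4, size=la))
        b = "".join(alphabet[i] for i in rng.integers(0, 4, size=lb))
        expected = enumerate_local_score(
            a, b, matrix, PARAMS.gap_open, PARAMS.gap_extend
        )
        assert align_local(p(a), p(b)) == expected, (a, b)


@pytest.mark.parametrize(
    "raw,expected",
    [(36, 18.4755), (0, 4.6083)],
)
def test_raw_to_bits_formula(raw, expected):
    bits = raw_to_bits(raw, PARAMS)
    assert bits == pytest.approx(
        (0.267 * raw - math.log(0.041)) / math.log(2)
    )
    assert bits == pytest.approx(expected, abs=1e-3)


def test_raw_to_bits_monotone():
    values = [raw_to_bits(r, PARAMS) for r in range(0, 200, 7)]
    assert all(x < y for x, y in zip(values, values[1:]))


def test_build_bsr_identical_records():
    score, bsr, dist = build_bsr([p("MKVLEWAC", "a"), p("MKVLEWAC", "b")])
    assert np.allclose(bsr.bsr, 1.0)
    assert np.allclose(dist.dist, 0.0)


def test_build_bsr_matrix_contracts(family_data):
    records, _ = family_data
    subset = records[:6]
    score, bsr, dist = build_bsr(subset)
    assert np.all(np.diag(bsr.bsr) == 1.0)
    assert np.allclose(dist.dist, dist.dist.T)
    assert np.all(np.diag(dist.dist) == 0.0)
    assert dist.dist.min() >= 0.0 and dist.dist.max() <= 1.0


def test_unrelated_proteins_near_maximal_distance():
    rng = np.random.default_rng(5)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    a = "".join(aas[i] for i in rng.integers(0, 20, size=150))
    b = "".join(aas[i] for i in rng.integers(0, 20, size=150))
    _, _, dist = build_bsr([p(a, "a"), p(b, "b")])
    assert dist.dist[0, 1] > 0.8


def test_order_equivariance(family_data):
    records, _ = family_data
    subset = records[:5]
    _, _, dist = build_bsr(subset)
    perm = [4, 2, 0, 3, 1]
    _, _, dist_p = build_bsr([subset[i] for i in perm])
    assert dist_p.ids == [subset[i].id for i in perm]
    reindex = [dist.ids.index(i) for i in dist_p.ids]
    assert np.allclose(dist_p.dist, dist.dist[np.ix_(reindex, reindex)])


def test_build_bsr_requires_two_unique_records():
    with pytest.raises(ValueError):
        build_bsr([p("MKV")])
    with pytest.raises(ValueError, match="duplicate"):
        build_bsr([p("MKV", "a"), p("MKL", "a")])


def test_ingest_score_csv_hand_example(tmp_path):
    path = tmp_path / "scores.csv"
    path.write_text("a,a,250\na,b,40\nb,b,260\nb,a,41\n")
    score = ingest_score_csv(path)
    bsr, dist = bsr_to_distance(score)
    i, j = score.ids.index("a"), score.ids.index("b")
    assert bsr.bsr[i, j] == pytest.approx(40 / 250)
    assert bsr.bsr[j, i] == pytest.approx(41 / 260)
    assert dist.dist[i, j] == pytest.approx(1 - (40 / 250 + 41 / 260) / 2)


def test_ingest_score_csv_keeps_best_hsp(tmp_path):
    path = tmp_path / "scores.csv"
    path.write_text("a,a,250\nb,b,260\na,b,40\na,b,55\nb,a,41\n")
    score = ingest_score_csv(path)
    assert score.bits[score.ids.index("a"), score.ids.index("b")] == 55


def test_ingest_score_csv_missing_pairs_flagged(tmp_path):
    path = tmp_path / "scores.csv"
    path.write_text("a,a,250\nb,b,260\na,b,40\n")
    score = ingest_score_csv(path)
    i, j = score.ids.index("a"), score.ids.index("b")
    assert score.bits[j, i] == 0.0 and score.no_hit[j, i]
    assert not score.no_hit[i, j]


def test_ingest_score_csv_outfmt6_full_rows(tmp_path):
    path = tmp_path / "scores.tsv"
    row = "{q}\t{s}\t100.0\t10\t0\t0\t1\t10\t1\t10\t1e-5\t{bits}\n"
    path.write_text(
        row.format(q="a", s="a", bits=250)
        + row.format(q="a", s="b", bits=40)
        + row.format(q="b", s="b", bits=260)
        + row.format(q="b", s="a", bits=41)
    )
    score = ingest_score_csv(path)
    assert score.bits[score.ids.index("a"), score.ids.index("b")] == 40


def test_ingest_score_csv_errors(tmp_path):
    no_self = tmp_path / "noself.csv"
    no_self.write_text("a,a,250\na,b,40\n")
    with pytest.raises(ValueError, match="self-hit.*'b'"):
        ingest_score_csv(no_self)
    bad = tmp_path / "bad.csv"
    bad.write_text("a,a,250\na,b,oops\n")
    with pytest.raises(ValueError, match=":2"):
        ingest_score_csv(bad)
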