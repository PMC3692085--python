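"""Symmetrization, deformation filtering, Spearman, LOOCV."""

import numpy as np
import pandas as pd
import pytest

from pentashape import (
    DeformationThresholds,
    FeatureVector,
    QueryTable,
    concatenate,
    deformation_mask,
    dinucleotide_summary,
    loocv,
    spearman,
    symmetrize,
)
from pentashape.kmer import revcomp
from pentashape.synthetic import FeatureNoise, make_corpus, make_model
from pentashape.validation import validate_predictions

DICKERSON = "CGCGAATTCGCG"


# ---------------------------------------------------------------------------
# symmetrize
# ---------------------------------------------------------------------------

def test_symmetrize_fixed_point():
    v = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
    assert np.array_equal(symmetrize(v, "CGTACG"), v)


def test_symmetrize_two_bp_pairwise_mean():
    assert np.array_equal(symmetrize(np.array([4.0, 6.0]), "AT"), [5.0, 5.0])


def test_symmetrize_hand_worked_dodecamer_profile():
    v = np.arange(12, dtype=float)
    got = symmetrize(v, DICKERSON)
    expected = (v + v[::-1]) / 2  # every pair (i, 13-i) averaged
    assert np.array_equal(got, expected)
    assert np.array_equal(got, got[::-1])


def test_symmetrize_step_indexed_profile():
    v = np.arange(11, dtype=float)  # steps of a 12-bp palindrome
    got = symmetrize(v, DICKERSON)
    assert np.array_equal(got, (v + v[::-1]) / 2)


def test_symmetrize_is_a_projection():
    rng = np.random.default_rng(1)
    v = rng.normal(size=12)
    once = symmetrize(v, DICKERSON)
    assert np.array_equal(symmetrize(once, DICKERSON), once)


def test_symmetrize_keeps_all_nan_pairs_undefined():
    v = np.array([np.nan, 1.0, 2.0, np.nan, 5.0, np.nan])
    got = symmetrize(v, "CGTACG")
    assert np.isnan(got[0]) and np.isnan(got[5])  # both members undefined
    assert got[1] == got[4] == 3.0
    assert got[2] == got[3] == 2.0  # single defined member kept, symmetric


def test_symmetrize_refuses_non_palindrome():
    with pytest.raises(ValueError, match="palindromic"):
        symmetrize(np.zeros(6), "AAAAAT")


# ---------------------------------------------------------------------------
# deformation filtering
# ---------------------------------------------------------------------------

def test_bdna_norms_fully_retained():
    L = 20
    bp, step = deformation_mask(
        mgw=np.full(L, 5.8), roll=np.zeros(L - 1), helt=np.full(L - 1, 35.0)
    )
    assert bp.all() and step.all()


def test_single_wide_groove_removes_three_bp_flanks():
    mgw = np.full(15, 5.8)
    mgw[7] = 9.0  # 1-based position 8
    bp, _ = deformation_mask(mgw=mgw)
    invalid = np.nonzero(~bp)[0] + 1
    assert list(invalid) == [5, 6, 7, 8, 9, 10, 11]
    assert bp.sum() == 8


def test_narrow_groove_triggers_low_cutoff():
    mgw = np.full(15, 5.8)
    mgw[0] = 1.0
    bp, _ = deformation_mask(mgw=mgw)
    assert list(np.nonzero(~bp)[0]) == [0, 1, 2, 3]  # flank clipped at boundary


def test_extreme_roll_invalidates_step_and_flanks():
    roll = np.zeros(14)
    roll[6] = -25.0  # |Roll| > 20 at step joining bp 7 and 8 (1-based)
    bp, step = deformation_mask(roll=roll, length=15)
    invalid_bp = set(np.nonzero(~bp)[0] + 1)
    assert invalid_bp == set(range(4, 12))  # bp 7,8 plus 3-bp flanks
    assert not step[6]


def test_extreme_helix_twist_detected():
    helt = np.full(14, 35.0)
    helt[0] = 50.0
    bp, step = deformation_mask(helt=helt, length=15)
    assert not bp[0] and not step[0]
    assert bp[6:].all()


def test_flank_zero_reduces_to_pure_thresholding():
    mgw = np.full(15, 5.8)
    mgw[7] = 9.0
    bp, _ = deformation_mask(mgw=mgw, thresholds=DeformationThresholds(flank=0))
    assert list(np.nonzero(~bp)[0]) == [7]


def test_mask_monotone_in_thresholds():
    rng = np.random.default_rng(2)
    mgw = rng.uniform(1.0, 10.0, 30)
    roll = rng.uniform(-30, 30, 29)
    helt = rng.uniform(30, 55, 29)
    tight = DeformationThresholds()
    loose = DeformationThresholds(mgw_hi=10.5, mgw_lo=0.5, helt_hi=60, roll_abs=35)
    bp_t, st_t = deformation_mask(mgw=mgw, roll=roll, helt=helt, thresholds=tight)
    bp_l, st_l = deformation_mask(mgw=mgw, roll=roll, helt=helt, thresholds=loose)
    assert (bp_l | ~bp_t).all()  # loosening never invalidates a valid element
    assert (st_l | ~st_t).all()


# ---------------------------------------------------------------------------
# concatenation and Spearman
# ---------------------------------------------------------------------------

def test_concatenate_in_source_order():
    a = FeatureVector(np.arange(5.0))
    b = FeatureVector(np.arange(5.0) + 10)
    cat = concatenate([a, b])
    assert len(cat) == 10
    assert cat.mask.sum() == 10
    assert np.array_equal(cat.values[:5], a.values)


def test_masking_drops_matched_elements_from_both_sides():
    mask = np.array([True, False, True, True, False])
    x = FeatureVector(np.arange(5.0), mask=mask)
    y = FeatureVector(np.arange(5.0) * 2, mask=np.ones(5, bool))
    from pentashape.validation import paired_valid

    xv, yv = paired_valid(x, y)
    assert xv.size == yv.size == 3
    assert np.array_equal(xv * 2, yv)


def test_shuffling_source_order_leaves_rho_unchanged():
    rng = np.random.default_rng(3)
    parts_x = [FeatureVector(rng.normal(size=7)) for _ in range(4)]
    parts_y = [FeatureVector(rng.normal(size=7)) for _ in range(4)]
    rho1 = spearman(concatenate(parts_x), concatenate(parts_y))
    order = [2, 0, 3, 1]
    rho2 = spearman(
        concatenate([parts_x[i] for i in order]),
        concatenate([parts_y[i] for i in order]),
    )
    assert rho1 == pytest.approx(rho2)


def _naive_spearman(x, y):
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[order[j]] == v[order[i]]:
                j += 1
            r[order[i:j]] = np.mean(np.arange(i, j) + 1)  # fractional ranks
            i = j
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])


def test_spearman_monotone_transform_gives_one():
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
    assert spearman(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman(x, -x) == pytest.approx(-1.0)


def test_spearman_matches_naive_oracle_with_ties():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
    assert spearman(x, y) == pytest.approx(_naive_spearman(x, y), abs=1e-12)


def test_spearman_random_vectors_match_oracle():
    rng = np.random.default_rng(4)
    for _ in range(50):
        x = rng.integers(0, 8, size=20).astype(float)  # ties guaranteed
        y = rng.normal(size=20)
        assert spearman(x, y) == pytest.approx(_naive_spearman(x, y), abs=1e-12)


def test_spearman_undefined_cases_warn():
    with pytest.warns(UserWarning, match="valid pairs"):
        assert np.isnan(spearman([1.0, 2.0], [2.0, 1.0]))
    with pytest.warns(UserWarning, match="variance"):
        assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# dinucleotide summary
# ---------------------------------------------------------------------------

def test_constant_helix_twist_table_summarizes_to_constant(table):
    df = table.data.copy()
    for col in ("HelT1", "HelT2"):
        df[col] = 34.4
    const = QueryTable(data=df)
    per_class, grand = dinucleotide_summary(const)
    assert len(per_class) == 10
    assert np.allclose(per_class["HelT"], 34.4)
    assert grand["HelT"] == pytest.approx(34.4)


def test_dinucleotide_summary_matches_brute_force(table):
    per_class, grand = dinucleotide_summary(table)
    acc = {}
    for pent, row in table.data.iterrows():
        for d, rc, hc in ((pent[1:3], "Roll1", "HelT1"), (pent[2:4], "Roll2", "HelT2")):
            cls = min(d, revcomp(d))
            acc.setdefault(cls, []).append((row[rc], row[hc]))
    assert set(acc) == set(per_class.index)
    for cls, pairs in acc.items():
        assert per_class.loc[cls, "Roll"] == pytest.approx(np.mean([p[0] for p in pairs]))
        assert per_class.loc[cls, "n"] == len(pairs)
    assert grand["Roll"] == pytest.approx(per_class["Roll"].mean())


# ---------------------------------------------------------------------------
# LOOCV and filtered validation
# ---------------------------------------------------------------------------

def test_loocv_exact_on_noiseless_redundant_corpus(model, corpus):
    # duplicate the corpus so every pentamer survives any single removal
    res = loocv(corpus + corpus, trim=2)
    assert res.uncovered_positions == 0
    for f in ("mgw", "prot", "roll", "helt"):
        assert res.rho[f] == 1.0


def test_loocv_degrades_monotonically_with_noise():
    lo = make_model(21, noise_sd=FeatureNoise(mgw=0.05, prot=0.3, roll=0.3, helt=0.3))
    hi = make_model(21, noise_sd=FeatureNoise(mgw=1.0, prot=6.0, roll=6.0, helt=6.0))
    corpus_lo = make_corpus(lo, n_fragments=220, seed=5)
    corpus_hi = make_corpus(hi, n_fragments=220, seed=5)
    res_lo = loocv(corpus_lo + corpus_lo, trim=2)
    res_hi = loocv(corpus_hi + corpus_hi, trim=2)
    for f in ("mgw", "prot", "roll", "helt"):
        assert res_lo.rho[f] < 1.0
        assert res_hi.rho[f] < res_lo.rho[f]


def test_loocv_requires_two_records(corpus):
    with pytest.raises(ValueError):
        loocv(corpus[:1])


def test_validate_predictions_perfect_on_noiseless_data(table, corpus):
    report = validate_predictions(table, corpus[:60])
    for f in ("mgw", "prot", "roll", "helt"):
        assert report.rho[f] == pytest.approx(1.0)
        assert report.n_pairs[f] > 100
    assert report.removed == {"mgw_range": 0, "helt_hi": 0, "roll_abs": 0, "flank": 0}
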