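"""Mining structural records into the pentamer query table."""

import numpy as np
import pytest

from pentashape import (
    QueryTable,
    StructuralRecord,
    build_query_table,
    mgw_at_bp,
    table_coverage,
)
from pentashape.table_builder import mgw_profile


def _record(seq, levels=None, prot=None, roll=None, helt=None, rid="r"):
    L = len(seq)
    return StructuralRecord(
        sequence=seq,
        groove_levels=np.full((L, 2), 5.8) if levels is None else np.asarray(levels, float),
        prot=np.full(L, -10.0) if prot is None else np.asarray(prot, float),
        roll=np.zeros(L - 1) if roll is None else np.asarray(roll, float),
        helt=np.full(L - 1, 35.0) if helt is None else np.asarray(helt, float),
        record_id=rid,
    )


# ---------------------------------------------------------------------------
# three-level MGW
# ---------------------------------------------------------------------------

def test_mgw_constant_levels_give_bdna_average_everywhere():
    rec = _record("ACGTACGT")
    for i in range(2, 9):
        assert mgw_at_bp(rec, i) == pytest.approx(5.8)


def test_mgw_is_mean_of_three_surrounding_levels():
    # bp 2's window: (preceding nucleotide's last level, own first, own second)
    levels = np.array([[9.9, 4.0], [5.0, 6.0], [9.9, 9.9]])
    rec = _record("ACG", levels=levels)
    assert mgw_at_bp(rec, 2) == pytest.approx(5.0)


def test_mgw_profile_matches_hand_computation_on_six_nt_record():
    flat = np.array([5.0, 5.2, 5.4, 5.6, 6.0, 6.2, 5.9, 5.5, 5.1, 4.9, 5.3, 5.7])
    rec = _record("ACGTAC", levels=flat.reshape(6, 2))
    prof = mgw_profile(rec)
    assert np.isnan(prof[0])
    # independently computed three-level means, positions 2..6 (1-based)
    expected = [
        (5.2 + 5.4 + 5.6) / 3,
        (5.6 + 6.0 + 6.2) / 3,
        (6.2 + 5.9 + 5.5) / 3,
        (5.5 + 5.1 + 4.9) / 3,
        (4.9 + 5.3 + 5.7) / 3,
    ]
    assert prof[1:] == pytest.approx(expected)


@pytest.mark.parametrize("i", [0, 1, 9])
def test_mgw_rejects_out_of_range_positions(i):
    with pytest.raises(IndexError):
        mgw_at_bp(_record("ACGTACGT"), i)


def test_mgw_invariant_under_strand_reversal():
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 15))
    rec = _record(seq, levels=rng.uniform(4, 7, (15, 2)))
    rc = rec.reverse_complement()
    a, b = mgw_profile(rec), mgw_profile(rc)
    L = 15  # valid on both strands: positions 2..L-1
    assert np.array_equal(a[1 : L - 1], b[1 : L - 1][::-1])


def test_record_reverse_complement_is_an_involution():
    rng = np.random.default_rng(6)
    rec = _record(
        "ACGGTAGCTAAC",
        levels=rng.uniform(4, 7, (12, 2)),
        prot=rng.uniform(-15, 0, 12),
        roll=rng.uniform(-5, 5, 11),
        helt=rng.uniform(30, 40, 11),
    )
    back = rec.reverse_complement().reverse_complement()
    assert back.sequence == rec.sequence
    assert np.array_equal(back.groove_levels, rec.groove_levels)
    assert np.array_equal(back.prot, rec.prot)
    assert np.array_equal(back.roll, rec.roll)
    assert np.array_equal(back.helt, rec.helt)


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def test_homopolymer_record_yields_single_constant_class():
    rec = _record("AAAAAAAAAAAA", roll=np.full(11, 3.2), helt=np.full(11, 34.4))
    tab = build_query_table([rec], trim=2)
    assert list(tab.data.index) == ["AAAAA"]
    row = tab.data.loc["AAAAA"]
    assert row["MGW"] == pytest.approx(5.8)
    assert row["ProT"] == pytest.approx(-10.0)
    assert row["Roll1"] == row["Roll2"] == pytest.approx(3.2)
    assert row["HelT1"] == row["HelT2"] == pytest.approx(34.4)
    assert row["count"] == 12 - 4 - 4  # L - 4 windows minus 2 trimmed per end


def test_occurrence_conservation(corpus, table):
    total_windows = sum(len(r) - 4 - 4 for r in corpus)  # trim=2 each end
    assert int(table.data["count"].sum()) == total_windows


def test_strand_symmetry_of_mining_is_bitwise(corpus):
    fwd = build_query_table(corpus, trim=2)
    rev = build_query_table([r.reverse_complement() for r in corpus], trim=2)
    assert fwd.data.equals(rev.data)


def test_both_strands_doubles_counts_and_preserves_means(corpus):
    one = build_query_table(corpus[:50], trim=2)
    two = build_query_table(corpus[:50], trim=2, both_strands=True)
    common = one.data.index
    assert (two.data.loc[common, "count"] == 2 * one.data.loc[common, "count"]).all()
    for col in ("MGW", "ProT", "Roll1", "Roll2", "HelT1", "HelT2"):
        assert np.allclose(two.data.loc[common, col], one.data.loc[common, col])


def test_mgw_scales_linearly_with_groove_levels():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 20))
    levels = rng.uniform(4, 7, (20, 2))
    base = build_query_table([_record(seq, levels=levels)], trim=2)
    scaled = build_query_table([_record(seq, levels=2.0 * levels)], trim=2)
    assert np.allclose(scaled.data["MGW"], 2.0 * base.data["MGW"])


def test_empty_record_collection_rejected():
    with pytest.raises(ValueError):
        build_query_table([])


def test_too_short_records_contribute_nothing():
    short = _record("ACGTACG")  # 7 bp < 2*2 + 5 at trim 2... exactly 2*2+5=9
    long = _record("AAAAAAAAAAAA")
    tab = build_query_table([short, long], trim=2)
    assert list(tab.data.index) == ["AAAAA"]


def test_coverage_report(table):
    cov = table_coverage(table)
    assert cov["n_classes"] == 512
    assert cov["missing"] == []
    assert cov["mean_occurrences"] > 1


def test_coverage_counts_missing_classes():
    tab = build_query_table([_record("AAAAAAAAAAAA")], trim=2)
    cov = table_coverage(tab)
    assert cov["n_classes"] == 1
    assert len(cov["missing"]) == 511


def test_single_short_record_covers_few_classes():
    rng = np.random.default_rng(8)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 12))
    tab = build_query_table([_record(seq)], trim=2)
    assert len(tab) <= 8  # 12 - 4 windows, fewer after trimming


# ---------------------------------------------------------------------------
# serialization and lookup
# ---------------------------------------------------------------------------

def test_table_tsv_round_trip(table, tmp_path):
    path = tmp_path / "table.tsv"
    table.to_tsv(path)
    back = QueryTable.from_tsv(path)
    assert list(back.data.index) == list(table.data.index)
    assert np.allclose(back.data.to_numpy(float), table.data.to_numpy(float), rtol=1e-5)


def test_incomplete_table_load_warns(tmp_path):
    tab = build_query_table([_record("AAAAAAAAAAAA")], trim=2)
    path = tmp_path / "partial.tsv"
    tab.to_tsv(path)
    with pytest.warns(UserWarning, match="1/512"):
        QueryTable.from_tsv(path)


def test_entry_swaps_steps_for_reverse_complemented_member(table):
    fwd = table.entry("AACGT")
    rev = table.entry("ACGTT")  # revcomp of AACGT
    assert rev["MGW"] == fwd["MGW"]
    assert rev["ProT"] == fwd["ProT"]
    assert rev["Roll1"] == fwd["Roll2"]
    assert rev["Roll2"] == fwd["Roll1"]
    assert rev["HelT1"] == fwd["HelT2"]
    assert rev["HelT2"] == fwd["HelT1"]
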