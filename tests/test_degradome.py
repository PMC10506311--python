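"""Degradome profiles, query windows, pairing score and site categories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polymir as pm
from polymir.degradome import DegradomeProfile, TargetSite, WINDOW_LEN


def _profile(tags, length=100, tx="tx1"):
    return DegradomeProfile(tx, tags, length)


def _site(pos, tx="tx1"):
    return TargetSite(mirna_id="m", transcript_id=tx, cleavage_pos=pos,
                      anchor=10, score=0.0, alignment="")


# --- profiles --------------------------------------------------------------


def test_build_profiles_aggregates_and_rejects():
    transcripts = {"tx1": "A" * 100, "tx2": "A" * 50, "tx3": "A" * 50}
    tags = [("tx1", 51, 10), ("tx1", 51, 2), ("tx2", 7, 1), ("tx1", 999, 5)]
    profiles, rejected = pm.build_profiles(tags, transcripts)
    assert profiles["tx1"].tags == {51: 12}
    assert rejected == 1
    assert set(profiles) == {"tx1", "tx2"}  # 3 transcripts, tags on 2


def test_build_profiles_unknown_transcript():
    with pytest.raises(ValueError, match="unknown transcript"):
        pm.build_profiles([("nope", 1, 1)], {"tx1": "ACGU"})


# --- windows ---------------------------------------------------------------


@pytest.mark.parametrize(
    "pos,expected_start,expected_len",
    [(51, 38, 26), (14, 1, 26)],
)
def test_window_geometry(pos, expected_start, expected_len):
    seq = "".join("ACGU"[i % 4] for i in range(100))
    prof = _profile({pos: 3})
    (w,) = pm.extract_windows(prof, seq)
    assert w.start == expected_start
    assert len(w.sequence) == expected_len
    assert w.sequence == seq[expected_start - 1 : expected_start - 1 + 26]
    # the tagged nucleotide sits at window offset 14 (1-based)
    assert w.sequence[13] == seq[pos - 1]


def test_window_requires_full_support():
    seq = "A" * 100
    assert pm.extract_windows(_profile({5: 3}), seq) == []
    assert pm.extract_windows(_profile({89: 3}), seq) == []


# --- pairing score ---------------------------------------------------------


def _perfect_target(mirna):
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in reversed(mirna))


def test_perfect_complement_scores_zero():
    mir = "UGACAGAAGAGAGUGAGCACA"
    score, marks = pm.pairing_score(mir, _perfect_target(mir))
    assert score == 0.0
    assert marks == "|" * len(mir)


def test_single_wobble_in_doubled_region_scores_one():
    mir = "AGAAGGCAAUCGGUAAUCGGA"  # position 5 (1-based) is G
    assert mir[4] == "G"
    target = list(_perfect_target(mir))
    target[len(mir) - 5] = "U"  # C -> U opposite miRNA position 5: G:U wobble
    score, marks = pm.pairing_score(mir, "".join(target))
    assert score == 1.0  # 0.5 doubled
    assert marks[4] == "o"


def test_single_mismatch_at_position_one_scores_one():
    mir = "AGAAGGCAAUCGGUAAUCGGA"
    target = list(_perfect_target(mir))
    target[len(mir) - 1] = "C"  # opposite miRNA position 1 (A): mismatch
    score, marks = pm.pairing_score(mir, "".join(target))
    assert score == 1.0  # full penalty but outside the doubled region
    assert marks[0] == "x"


def test_pairing_score_rejects_bad_alphabet():
    with pytest.raises(ValueError, match="non-RNA"):
        pm.pairing_score("ACGN", "ACGU")


def test_score_agrees_with_bruteforce_enumeration(score_oracle):
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(18, 26))
        mir = "".join(rng.choice(list("ACGU"), n))
        tgt = "".join(rng.choice(list("ACGU"), n))
        score, _ = pm.pairing_score(mir, tgt)
        assert score == pytest.approx(score_oracle(mir, tgt))


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 10**6))
def test_mutation_never_decreases_score_and_seed_doubles(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(18, 26))
    mir = "".join(rng.choice(list("ACGU"), n))
    tgt = _perfect_target(mir)
    base, _ = pm.pairing_score(mir, tgt)
    pos = int(rng.integers(n))  # 0-based target index, pairs miRNA n-pos
    other = rng.choice([c for c in "ACGU" if c != tgt[pos]])
    mutated = tgt[:pos] + other + tgt[pos + 1 :]
    score, _ = pm.pairing_score(mir, mutated)
    assert score >= base
    # the identical defect inside miRNA positions 2..13 costs exactly double
    mir_pos = n - pos
    penalty = score - base
    if penalty > 0 and 2 <= mir_pos <= 13:
        assert penalty in (1.0, 2.0)


# --- categorization --------------------------------------------------------


@pytest.mark.parametrize(
    "tags,pos,expected",
    [
        ({51: 10, 20: 3}, 51, 0),              # unique maximum
        ({51: 10, 70: 10, 20: 3}, 51, 1),      # two maxima
        ({51: 5, 20: 8, 30: 2, 40: 2}, 51, 2),  # median 3.5 < 5 < 8
        ({51: 2, 20: 8, 30: 6, 40: 4}, 51, 3),  # 2 <= median 5
        ({51: 1, 20: 8}, 51, 4),                # single raw read
    ],
)
def test_categorize_site(tags, pos, expected):
    assert pm.categorize_site(_site(pos), _profile(tags)) == expected


def test_categorize_untagged_position_is_error():
    with pytest.raises(ValueError, match="no tag"):
        pm.categorize_site(_site(99), _profile({51: 10}))


def test_categories_rederivable_from_stored_stats(degradome_clean):
    transcripts, mirnas, profiles, _ = degradome_clean
    for site in pm.find_sites(mirnas, transcripts, profiles):
        assert site.category == pm.categorize_site(site, profiles[site.transcript_id])
        assert site.score <= 4.0
        assert site.count_at_site == profiles[site.transcript_id].tags[site.cleavage_pos]


# --- discovery -------------------------------------------------------------


def test_planted_sites_all_recovered(degradome_clean):
    transcripts, mirnas, profiles, truth = degradome_clean
    sites = pm.find_sites(mirnas, transcripts, profiles)
    found = {(s.mirna_id, s.transcript_id, s.cleavage_pos): s for s in sites}
    for planted in truth:
        key = (planted.mirna_id, planted.transcript_id, planted.position)
        assert key in found
        assert found[key].category == planted.category
        assert found[key].score == 0.0


def test_no_tags_no_sites():
    mirnas = {"m1": "UGACAGAAGAGAGUGAGCACA"}
    transcripts = {"tx1": "A" * 100}
    assert pm.find_sites(mirnas, transcripts, {}) == []


def test_heavily_mismatched_site_not_retained(degradome_clean):
    """Five defects inside positions 2-13 cost 10 > 4: site must drop."""
    transcripts, mirnas, profiles, truth = degradome_clean
    planted = truth[0]
    tx = planted.transcript_id
    seq = list(transcripts[tx])
    mir = mirnas[planted.mirna_id]
    flip = {"A": "C", "C": "A", "G": "U", "U": "G"}
    for i in range(3, 8):  # miRNA positions 3..7 pair transcript p+10-i
        t = planted.position + 10 - i
        seq[t - 1] = flip[seq[t - 1]]
    broken = dict(transcripts)
    broken[tx] = "".join(seq)
    sites = pm.find_sites({planted.mirna_id: mir}, broken, {tx: profiles[tx]})
    assert all(s.cleavage_pos != planted.position for s in sites)


def test_tag_anchored_subset_of_exhaustive_scan(degradome_clean, score_oracle):
    """Every retained site must reappear in a naive full-transcript scan."""
    transcripts, mirnas, profiles, _ = degradome_clean
    sites = pm.find_sites(mirnas, transcripts, profiles)
    exhaustive = set()
    for tx, seq in transcripts.items():
        for mid, mir in mirnas.items():
            L = len(mir)
            for p in range(1, len(seq) + 1):
                for anchor in (10, 11):
                    start, end = p - (L - anchor), p + (anchor - 1)
                    if start < 1 or end > len(seq):
                        continue
                    if score_oracle(mir, seq[start - 1 : end]) <= 4.0:
                        exhaustive.add((mid, tx, p, anchor))
    for s in sites:
        assert (s.mirna_id, s.transcript_id, s.cleavage_pos, s.anchor) in exhaustive


# --- t-plots and coverage --------------------------------------------------


def test_tplot_rows_sorted_single_flag():
    prof = _profile({51: 10, 20: 3})
    table = pm.tplot_table(prof, _site(51))
    assert list(table["position"]) == [20, 51]
    assert list(table["is_cleavage_site"]) == [False, True]
    assert table.loc[table["is_cleavage_site"], "position"].item() == 51


@settings(derandomize=True, max_examples=50)
@given(st.dictionaries(st.integers(1, 100), st.integers(1, 50), min_size=1,
                       max_size=20))
def test_tplot_flag_matches_cleavage_position(tags):
    prof = _profile(tags)
    pos = sorted(tags)[0]
    table = pm.tplot_table(prof, _site(pos))
    assert list(table["position"]) == sorted(tags)
    assert table["is_cleavage_site"].sum() == 1
    assert table.loc[table["is_cleavage_site"], "position"].item() == pos


@pytest.mark.parametrize(
    "n_input,n_covered,expected",
    [(103427, 81229, 78.54), (10, 10, 100.00), (10, 0, 0.00)],
)
def test_coverage_percent(n_input, n_covered, expected):
    ids = [f"t{i}" for i in range(n_input)]
    profiles = [DegradomeProfile(f"t{i}", {1: 1}, 10) for i in range(n_covered)]
    got = pm.coverage_stats(profiles, ids)
    assert got == (n_input, n_covered, expected)


def test_coverage_requires_transcripts():
    with pytest.raises(ValueError):
        pm.coverage_stats([], [])
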