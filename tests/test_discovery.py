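"""Mapping, window extraction, hairpin evaluation and novel discovery."""

import numpy as np
import pytest

from mirnaome.discovery import (Criteria, Hit, WindowScheme, discover,
                                evaluate_hairpin, extract_window_coords,
                                map_to_references)
from mirnaome.preprocess import SequenceTag
from mirnaome.seqs import revcomp
from mirnaome.structure import fold
from oracles import duplex_annotate


def _tag(seq, **counts):
    return SequenceTag(sequence=seq, counts=counts or {"libA": 10})


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# --- mapping ---------------------------------------------------------------

def test_map_finds_planted_coordinates(small_bundle, small_config):
    refs = small_bundle.transcript_reference + small_bundle.ncrna_reference
    for row in small_bundle.manifest["novel"]:
        tag = _tag(row["mature_sequence"])
        hits = [h for _, h in map_to_references([tag], refs)]
        sense = [h for h in hits if h.strand == "+"
                 and h.source_id == row["source_id"]]
        assert any(h.position == row["mature_interval"][0] for h in sense)


def test_map_no_hits_on_disjoint_alphabet():
    assert map_to_references([_tag("A" * 21)], [("ref", "C" * 200)]) == []


def test_map_reports_both_strands():
    rng = np.random.default_rng(9)
    tag_seq = _rand_seq(rng, 21)
    ref = _rand_seq(rng, 50) + tag_seq + _rand_seq(rng, 30) \
        + revcomp(tag_seq) + _rand_seq(rng, 50)
    hits = [h for _, h in map_to_references([_tag(tag_seq)], [("r", ref)])]
    assert {h.strand for h in hits} == {"+", "-"}
    assert hits[0].position == 50


def test_map_agrees_with_bruteforce_scan():
    rng = np.random.default_rng(17)
    refs = [(f"r{i}", _rand_seq(rng, 300)) for i in range(4)]
    tags = [_tag(refs[1][1][40:61]), _tag(revcomp(refs[2][1][100:122])),
            _tag(_rand_seq(rng, 21))]
    got = [(h.source_id, h.position, h.strand)
           for _, h in map_to_references(tags, refs)]
    expected = []
    for tag in tags:
        for name, ref in refs:
            per_ref = []
            for query, strand in ((tag.sequence, "+"),
                                  (revcomp(tag.sequence), "-")):
                for p in range(len(ref) - len(query) + 1):
                    if ref[p:p + len(query)] == query:
                        per_ref.append((p, strand))
            for p, strand in sorted(per_ref):
                expected.append((name, p, strand))
    assert got == expected


# --- windows ---------------------------------------------------------------

def test_windows_always_contain_the_mature_hit():
    rng = np.random.default_rng(2)
    scheme = WindowScheme()
    for _ in range(100):
        source_len = int(rng.integers(120, 2000))
        pos = int(rng.integers(0, source_len - 21))
        hit = Hit(tag_sequence="A" * 21, source_id="s", position=pos,
                  strand="+")
        wins = extract_window_coords(hit, 21, source_len, scheme)
        assert wins
        for s, e in wins:
            assert 0 <= s <= pos and pos + 21 <= e <= source_len
            assert e - s <= max(scheme.lengths)


def test_windows_clip_at_source_start():
    hit = Hit(tag_sequence="A" * 21, source_id="s", position=20, strand="+")
    wins = extract_window_coords(hit, 21, 5000)
    assert all(s >= 0 for s, _ in wins)
    assert any(s == 0 for s, _ in wins)  # clipped window still covers mature


def test_windows_offer_multiple_offsets_per_length():
    hit = Hit(tag_sequence="A" * 21, source_id="s", position=500, strand="+")
    wins = extract_window_coords(hit, 21, 2000,
                                 WindowScheme(lengths=(80,), grid=10))
    assert len(wins) >= 3


# --- hairpin evaluation ----------------------------------------------------

def _designed_hairpin(rng, mature_len=21):
    mature = _rand_seq(rng, mature_len)
    ext = _rand_seq(rng, 14)
    loop = "AC" * 5
    pre = mature + ext + loop + revcomp(ext) + revcomp(mature)
    return pre, (0, mature_len)


def test_perfect_designed_hairpin_passes():
    rng = np.random.default_rng(1)
    for _ in range(10):
        pre, m_iv = _designed_hairpin(rng)
        ev = evaluate_hairpin(fold(pre), m_iv)
        if ev.passed:
            assert ev.n_mismatch == 0
            assert ev.arm == "5p"
            assert ev.star_interval is not None
            return
    pytest.fail("no designed hairpin passed")


def test_five_engineered_unpaired_mature_bases_fail():
    rng = np.random.default_rng(8)
    pre, (m_s, m_e) = _designed_hairpin(rng)
    structure = fold(pre)
    # forge a structure with 5 mature bases forced unpaired
    pt = list(structure.pair_table)
    broken = 0
    for i in range(m_s, m_e):
        if pt[i] is not None and broken < 5:
            pt[pt[i]] = None
            pt[i] = None
            broken += 1
    from mirnaome.structure import render_dotbracket, structure_from_dotbracket

    forged = structure_from_dotbracket(pre, render_dotbracket(pt))
    ev = evaluate_hairpin(forged, (m_s, m_e))
    assert ev.n_mismatch >= 5
    assert not ev.passed


def test_mature_interval_outside_window_is_an_error():
    with pytest.raises(ValueError):
        evaluate_hairpin(fold("GGGAAACCC"), (5, 30))


def test_evaluation_agrees_with_pair_table_walk_oracle(small_bundle):
    """Implementation vs independent duplex annotator: all simulator
    hairpins plus random negatives must agree on the verdict."""
    crit = Criteria()
    cases = []
    for row in small_bundle.manifest["novel"]:
        src = dict(small_bundle.transcript_reference
                   + small_bundle.ncrna_reference)[row["source_id"]]
        ps, pe = row["precursor_interval"]
        ms, me = row["mature_interval"]
        structure = fold(src[ps:pe])
        cases.append((structure, (ms - ps, me - ps), True))
    rng = np.random.default_rng(33)
    for _ in range(200):
        window = _rand_seq(rng, 100)
        cases.append((fold(window), (40, 61), False))
    false_accepts = 0
    n_negative = 0
    for structure, m_iv, is_designed in cases:
        ev = evaluate_hairpin(structure, m_iv, crit)
        oracle = duplex_annotate(structure, m_iv)
        assert ev.passed == oracle["passed"]
        assert ev.n_mismatch == oracle["n_mismatch"]
        assert ev.n_asym_bulge_nt == oracle["asym"]
        if is_designed:
            assert ev.passed
        else:
            n_negative += 1
            false_accepts += ev.passed
    assert false_accepts / n_negative < 0.05


# --- discovery -------------------------------------------------------------

@pytest.fixture(scope="module")
def discovered(small_bundle, small_tags):
    from mirnaome.annotate import filter_ncrna, match_conserved

    res = filter_ncrna(small_tags, small_bundle.ncrna_reference)
    annotated = {a.tag.sequence
                 for a in match_conserved(res.retained,
                                          small_bundle.mature_reference)}
    unannotated = [t for t in res.retained if t.sequence not in annotated]
    rrna_tags = [t for t in res.discarded
                 if res.matched_reference[t.sequence].startswith("rRNA")]
    rrna_refs = [(n, s) for n, s in small_bundle.ncrna_reference
                 if n.startswith("rRNA")]
    return discover(unannotated + rrna_tags,
                    small_bundle.transcript_reference, rrna_refs)


def test_every_planted_hairpin_is_recovered(discovered, small_bundle):
    found = {r.mature_tag.sequence for r in discovered}
    for row in small_bundle.manifest["novel"]:
        assert row["mature_sequence"] in found


def test_rrna_embedded_hairpin_flagged_as_rrna(discovered, small_bundle):
    rrna_matures = {row["mature_sequence"]
                    for row in small_bundle.manifest["novel"]
                    if row["source_class"] == "rRNA"}
    assert rrna_matures
    for r in discovered:
        expected = "rRNA" if r.mature_tag.sequence in rrna_matures \
            else "transcript"
        assert r.precursor.source_class == expected


def test_arm_paired_matures_are_mutual_partners(discovered, small_bundle):
    paired = {row["mature_sequence"]: row
              for row in small_bundle.manifest["novel"]
              if row["partner"] is not None}
    assert len(paired) == 2
    recs = {r.mature_tag.sequence: r for r in discovered}
    a, b = [recs[s] for s in paired]
    assert a.partner_name == b.name and b.partner_name == a.name
    assert {a.arm, b.arm} == {"5p", "3p"}
    assert a.precursor.source_id == b.precursor.source_id
    assert a.precursor.window == b.precursor.window


def test_discovery_is_deterministic(small_bundle, small_tags):
    from mirnaome.annotate import filter_ncrna

    res = filter_ncrna(small_tags, small_bundle.ncrna_reference)
    rrna_refs = [(n, s) for n, s in small_bundle.ncrna_reference
                 if n.startswith("rRNA")]
    runs = []
    for _ in range(2):
        recs = discover(res.retained + res.discarded,
                        small_bundle.transcript_reference, rrna_refs)
        runs.append([(r.name, r.mature_tag.sequence, r.precursor.window,
                      r.partner_name) for r in recs])
    assert runs[0] == runs[1]


def test_names_follow_descending_summed_count(discovered):
    totals = [sum(r.mature_tag.counts.values()) for r in discovered]
    assert totals == sorted(totals, reverse=True)
    assert [r.name for r in discovered] == \
        [f"novel-{i + 1}" for i in range(len(discovered))]


def test_min_count_threshold_excludes_rare_tags(small_bundle):
    row = small_bundle.manifest["novel"][0]
    rare = _tag(row["mature_sequence"], libA=2, libB=4)
    rrna_refs = [(n, s) for n, s in small_bundle.ncrna_reference
                 if n.startswith("rRNA")]
    assert discover([rare], small_bundle.transcript_reference, rrna_refs) == []
    kept = discover([rare], small_bundle.transcript_reference, rrna_refs,
                    min_count=2)
    assert len(kept) == 1


def test_loosening_max_mismatch_never_removes_accepted_mirnas(
        small_bundle, small_tags):
    from mirnaome.annotate import filter_ncrna

    res = filter_ncrna(small_tags, small_bundle.ncrna_reference)
    rrna_refs = [(n, s) for n, s in small_bundle.ncrna_reference
                 if n.startswith("rRNA")]
    strict = discover(res.retained, small_bundle.transcript_reference,
                      rrna_refs, criteria=Criteria(max_mismatch=2))
    loose = discover(res.retained, small_bundle.transcript_reference,
                     rrna_refs, criteria=Criteria(max_mismatch=6))
    strict_seqs = {r.mature_tag.sequence for r in strict}
    loose_seqs = {r.mature_tag.sequence for r in loose}
    assert strict_seqs <= loose_seqs
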