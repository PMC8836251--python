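"""Beta-strand detection, barrel candidacy and alpha-anchor exclusion."""

import pytest

from comscan.barrel import StrandSet, Strand, beta_signal_features, detect_strands, exclude_barrel
from comscan.config import ThresholdConfig
from comscan.features import WW_INTERFACE, moment_profile
from comscan.io import ProteinRecord
from comscan.syndata import SyntheticSpec, generate_sequence
from comscan.tmd import HIGH, MODERATE, TMDSegment, detect_tmds


def oracle_strands(seq, config, scale=WW_INTERFACE):
    """Independent oracle: enumerate windows, greedy best-first disjoint."""
    cands = []
    for w in range(config.strand_len_min, config.strand_len_max + 1):
        for s in range(len(seq) - w + 1):
            m = float(moment_profile(seq[s : s + w], scale, w, config.beta_angle)[0])
            if m >= config.beta_moment_cutoff:
                cands.append((m, s, w))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken = set()
    chosen = []
    for m, s, w in cands:
        span = set(range(s, s + w))
        if span & taken:
            continue
        taken |= span
        chosen.append((s, s + w))
    return sorted(chosen)


def test_all_serine_has_no_strands(config):
    ss = detect_strands(ProteinRecord(id="s", sequence="S" * 200), config)
    assert ss.n_strands == 0 and not ss.is_barrel_candidate
    assert ss.beta_signal_region is None


def test_planted_barrel_matches_oracle(config):
    rec, ann = generate_sequence(SyntheticSpec(category="BETA_BARREL", n_strands=10, seed=2))
    ss = detect_strands(rec, config)
    assert ss.n_strands == 10 and ss.is_barrel_candidate
    assert [(s.start, s.end) for s in ss.strands] == oracle_strands(rec.sequence, config)
    # detected strands line up with planted coordinates
    for (ps, pe), st in zip(ann.strands, ss.strands):
        assert abs(st.start - ps) <= 2 and abs(st.end - pe) <= 2


def test_truncated_barrel_not_candidate(config):
    rec, _ = generate_sequence(SyntheticSpec(category="BETA_BARREL", n_strands=5, seed=2))
    ss = detect_strands(rec, config)
    assert ss.n_strands == 5 and not ss.is_barrel_candidate


@pytest.mark.parametrize("n,candidate", [(8, True), (12, True), (16, True), (24, True), (4, False), (6, False)])
def test_candidacy_across_strand_counts(n, candidate, config):
    rec, _ = generate_sequence(SyntheticSpec(category="BETA_BARREL", n_strands=n, seed=31))
    ss = detect_strands(rec, config)
    assert ss.n_strands == n
    assert ss.is_barrel_candidate is candidate


def test_strands_disjoint_sorted_lengths_in_range(config):
    rec, _ = generate_sequence(SyntheticSpec(category="BETA_BARREL", n_strands=14, seed=8))
    ss = detect_strands(rec, config)
    for a, b in zip(ss.strands, ss.strands[1:]):
        assert a.end <= b.start
    for st in ss.strands:
        assert config.strand_len_min <= len(st) <= config.strand_len_max


def test_raising_moment_cutoff_never_adds_strands(config):
    rec, _ = generate_sequence(SyntheticSpec(category="BETA_BARREL", n_strands=12, seed=5))
    counts = [
        detect_strands(rec, ThresholdConfig(beta_moment_cutoff=c)).n_strands
        for c in (0.4, 0.5, 0.6, 0.7, 0.9)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_greedy_tie_break_prefers_smaller_start(config):
    # two identical strands -> identical moments; selection must be deterministic
    strand = "FNFNFNFNFN"
    seq = "GG" + strand + "QQQQQQ" + strand + "GG"
    ss = detect_strands(ProteinRecord(id="t", sequence=seq), config)
    assert [(s.start, s.end) for s in ss.strands] == oracle_strands(seq, config)
    ss2 = detect_strands(ProteinRecord(id="t", sequence=seq), config)
    assert ss.strands == ss2.strands


def test_beta_signal_region_spans_last_two_strands(config):
    rec, _ = generate_sequence(SyntheticSpec(category="BETA_BARREL", n_strands=9, seed=12))
    ss = detect_strands(rec, config)
    assert ss.beta_signal_region == (ss.strands[-2].start, ss.strands[-1].end)


def test_beta_signal_hydrophilic_feature():
    strands = (Strand(0, 10, 1.0), Strand(20, 30, 1.0))
    ss = StrandSet(strands=strands, is_barrel_candidate=False, beta_signal_region=(0, 30))
    rec_k = ProteinRecord(id="k", sequence="GGGGGGVAVK" + "G" * 10 + "FNFNFNFNFN")
    rec_l = ProteinRecord(id="l", sequence="GGGGGGVAVL" + "G" * 10 + "FNFNFNFNFN")
    assert beta_signal_features(ss, rec_k).hydrophilic_at_penultimate_end is True
    assert beta_signal_features(ss, rec_l).hydrophilic_at_penultimate_end is False


def test_beta_signal_requires_two_strands():
    ss = StrandSet(strands=(Strand(0, 10, 1.0),), is_barrel_candidate=False, beta_signal_region=None)
    with pytest.raises(ValueError, match="penultimate"):
        beta_signal_features(ss, ProteinRecord(id="x", sequence="F" * 20))


# ------------------------------------------------------------- exclusion
def _strand_set(spans):
    strands = tuple(Strand(s, e, 1.0) for s, e in spans)
    return StrandSet(strands=strands, is_barrel_candidate=True,
                     beta_signal_region=(strands[-2].start, strands[-1].end))


def test_no_tmds_means_no_exclusion(config):
    ss = _strand_set([(i * 20, i * 20 + 10) for i in range(8)])
    out = exclude_barrel(ss, [], config)
    assert not out.excluded


def test_high_grade_anchor_covering_strands_excludes(config):
    ss = _strand_set([(0, 10), (12, 22)])
    tmd = TMDSegment(start=0, end=22, mean_hydrophobicity=0.8, grade=HIGH)
    out = exclude_barrel(ss, [tmd], config)
    assert out.excluded and out.exclusion_reason == "alpha-anchor"


def test_two_moderate_anchors_covering_strands_exclude(config):
    ss = _strand_set([(0, 10), (30, 40)])
    tmds = [
        TMDSegment(start=0, end=19, mean_hydrophobicity=0.3, grade=MODERATE),
        TMDSegment(start=28, end=47, mean_hydrophobicity=0.3, grade=MODERATE),
    ]
    out = exclude_barrel(ss, tmds, config)
    assert out.excluded


def test_single_moderate_nonoverlapping_anchor_keeps_candidate(config):
    ss = _strand_set([(100, 110), (120, 130)])
    tmd = TMDSegment(start=0, end=19, mean_hydrophobicity=0.3, grade=MODERATE)
    out = exclude_barrel(ss, [tmd], config)
    assert not out.excluded


def test_exclusion_respects_overlap_fraction(config):
    # one HIGH anchor covering exactly half of 20 strand residues: not more than 50%
    ss = _strand_set([(0, 10), (20, 30)])
    tmd = TMDSegment(start=0, end=10, mean_hydrophobicity=0.8, grade=HIGH)
    assert not exclude_barrel(ss, [tmd], config).excluded
    tmd_bigger = TMDSegment(start=0, end=21, mean_hydrophobicity=0.8, grade=HIGH)
    assert exclude_barrel(ss, [tmd_bigger], config).excluded
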