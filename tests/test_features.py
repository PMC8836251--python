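"""Feature primitives against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comscan.features import (
    AMINO_ACIDS,
    PKA_SIDECHAIN,
    ResidueScale,
    WW_INTERFACE,
    WW_OCTANOL,
    composition,
    isoelectric_point,
    net_charge,
    periodicity_moment,
    positive_count,
    sliding_hydropathy,
)

SEQS = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


# ---------------------------------------------------------------- oracles
def brute_window_means(seq, scale, window):
    return [
        sum(scale.values[aa] for aa in seq[i : i + window]) / window
        for i in range(len(seq) - window + 1)
    ]


def brute_moment(seq, scale, angle):
    delta = math.radians(angle)
    s = sum(scale.values[aa] * math.sin(i * delta) for i, aa in enumerate(seq))
    c = sum(scale.values[aa] * math.cos(i * delta) for i, aa in enumerate(seq))
    return math.sqrt(s * s + c * c) / len(seq)


def brute_charge(seq, pH):
    total = 0.0
    for aa in seq:
        if aa in PKA_SIDECHAIN:
            pka, sign = PKA_SIDECHAIN[aa]
            frac = 1.0 / (1.0 + 10.0 ** (sign * (pH - pka)))
            total += sign * frac
    return total


# ------------------------------------------------------- sliding hydropathy
def test_sliding_hydropathy_toy_scale(toy_scale):
    prof = sliding_hydropathy("AAGG", toy_scale, 2)
    assert prof.scores == pytest.approx([1.0, 0.5, 0.0])


def test_window_equal_to_length_gives_whole_mean(scale):
    seq = "MKWLFAVST"
    prof = sliding_hydropathy(seq, scale, len(seq))
    assert prof.scores == pytest.approx([np.mean([scale.values[aa] for aa in seq])])


def test_window_longer_than_sequence_raises(scale):
    with pytest.raises(ValueError, match="shorter than window"):
        sliding_hydropathy("MK", scale, 19)


@settings(max_examples=300, derandomize=True)
@given(seq=st.text(alphabet=AMINO_ACIDS, min_size=19, max_size=80))
def test_sliding_hydropathy_matches_bruteforce(seq):
    prof = sliding_hydropathy(seq, WW_INTERFACE, 19)
    assert prof.scores == pytest.approx(brute_window_means(seq, WW_INTERFACE, 19), rel=1e-9, abs=1e-12)


def test_profile_scores_within_scale_range(rng):
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=200))
    prof = sliding_hydropathy(seq, WW_INTERFACE, 19)
    lo, hi = min(WW_INTERFACE.values.values()), max(WW_INTERFACE.values.values())
    assert prof.scores.min() >= lo and prof.scores.max() <= hi
    assert len(prof.scores) == 200 - 19 + 1


# --------------------------------------------------------- periodicity moment
def test_perfect_alternation_maximizes_180_moment():
    values = {aa: 0.0 for aa in AMINO_ACIDS}
    values.update({"A": 1.0, "G": -1.0})
    sc = ResidueScale("pm", values)
    assert periodicity_moment("AGAG", sc, 180.0) == pytest.approx(1.0)
    assert periodicity_moment("AAAA", sc, 180.0) == pytest.approx(0.0)


@settings(max_examples=300, derandomize=True)
@given(seq=SEQS, angle=st.sampled_from([100.0, 160.0, 180.0]))
def test_moment_matches_bruteforce(seq, angle):
    assert periodicity_moment(seq, WW_INTERFACE, angle) == pytest.approx(
        brute_moment(seq, WW_INTERFACE, angle), rel=1e-9, abs=1e-12
    )


@settings(max_examples=100, derandomize=True)
@given(seq=SEQS)
def test_moment_invariant_under_scale_sign_flip(seq):
    assert periodicity_moment(seq, WW_INTERFACE, 180.0) == pytest.approx(
        periodicity_moment(seq, WW_INTERFACE.flipped(), 180.0), rel=1e-9, abs=1e-12
    )


def test_moment_requires_two_residues():
    with pytest.raises(ValueError):
        periodicity_moment("A", WW_INTERFACE, 180.0)


# ------------------------------------------------------------------ charge
@pytest.mark.parametrize(
    "seq,expected",
    [("RKR", 3), ("GGGG", 0), ("KASTRHK", 3)],  # His not counted as positive
)
def test_positive_count(seq, expected):
    assert positive_count(seq) == expected


def test_net_charge_examples():
    assert net_charge("GGG", 7.0) == pytest.approx(0.0)
    k = net_charge("K", 7.0)
    assert 0.99 < k < 1.0  # pKa(K) > 10, essentially fully protonated
    assert net_charge("DKE", 7.0) == pytest.approx(brute_charge("DKE", 7.0), rel=1e-9)


@settings(max_examples=200, derandomize=True)
@given(seq=SEQS, pH=st.floats(min_value=0.0, max_value=14.0))
def test_net_charge_matches_bruteforce(seq, pH):
    assert net_charge(seq, pH) == pytest.approx(brute_charge(seq, pH), rel=1e-9, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(seq=SEQS)
def test_net_charge_monotone_nonincreasing_in_pH(seq):
    charges = [net_charge(seq, pH) for pH in np.linspace(0, 14, 30)]
    assert all(a >= b - 1e-12 for a, b in zip(charges, charges[1:]))


# ---------------------------------------------------------------------- pI
def grid_pI(seq, steps=1000):
    """Independent oracle: grid scan for the sign change of net charge."""
    grid = np.linspace(0.0, 14.0, steps)
    charges = [brute_charge(seq, p) for p in grid]
    for i in range(len(grid) - 1):
        if charges[i] > 0 >= charges[i + 1]:
            return 0.5 * (grid[i] + grid[i + 1])
    return None


def test_pI_no_ionizable_returns_convention():
    pI, ionizable = isoelectric_point("GGGG")
    assert pI == 7.0 and not ionizable


def test_pI_basic_segment_above_7():
    pI, ionizable = isoelectric_point("KK")
    assert ionizable and pI > 7.0


@pytest.mark.parametrize("seq", ["DDKK", "DEKRH", "CYKR", "EEEKKK"])
def test_pI_matches_grid_oracle(seq):
    pI, ionizable = isoelectric_point(seq)
    assert ionizable
    assert pI == pytest.approx(grid_pI(seq), abs=2e-2)
    assert abs(net_charge(seq, pI)) < 1e-2


# -------------------------------------------------------------- composition
def test_composition_examples():
    c = composition("SSTT")
    assert c.hydroxylated_frac == 1.0 and c.acidic_frac == 0.0
    assert composition("DE").acidic_frac == 1.0
    c = composition("MKSSTPPKLS")
    assert c.hydroxylated_frac == pytest.approx(0.4)
    assert c.lysine_count == 2 and c.proline_count == 2
    assert c.arginine_count == 0 and c.acidic_frac == 0.0


def test_composition_excludes_X_from_denominator():
    c = composition("SXXX")
    assert c.hydroxylated_frac == 1.0  # over the single non-X residue


def test_packaged_scales_have_20_residues():
    for sc in (WW_INTERFACE, WW_OCTANOL):
        assert set(sc.values) == set(AMINO_ACIDS)
    # interface convention: Trp/Phe strongly hydrophobic, Glu strongly not
    assert WW_INTERFACE.values["W"] > WW_INTERFACE.values["A"]
    assert WW_INTERFACE.values["E"] < 0
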