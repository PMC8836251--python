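"""Physicochemical sequence primitives.

All downstream stages of the pipeline consume the quantities computed
here: windowed hydropathy on a named residue scale, periodicity
(hydrophobic-moment) profiles, segment charge, segment isoelectric
point, and residue-class composition.

Conventions
-----------
* Hydrophobicity scales are stored so that larger = more hydrophobic.
  The default is the Wimley-White water->bilayer-interface scale with
  the sign of the published transfer free energies flipped; on this
  convention the canonical 0.4 ceiling for "moderately hydrophobic"
  chloroplast anchor helices is an upper bound on the windowed mean.
* ``X`` (unknown residue) contributes hydrophobicity 0 and is excluded
  from the denominators of composition fractions and from charge sums.
* Charge calculations use side chains only (Henderson-Hasselbalch with
  a packaged pKa set); segments are treated as internal windows of a
  chain, so free termini never contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}

_POSITIVE = frozenset("KR")  # His excluded: side-chain pKa < physiological pH
_HYDROXYLATED = frozenset("ST")
_BASIC = frozenset("KRH")
_ACIDIC = frozenset("DE")


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue hydrophobicity scale (larger = more hydrophobic)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("scale name must be non-empty")
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError("scale must define exactly the 20 canonical residues")

    def of(self, seq: str) -> np.ndarray:
        """Per-residue values for *seq*; X maps to 0."""
        return np.array([self.values.get(aa, 0.0) for aa in seq], dtype=float)

    def flipped(self) -> "ResidueScale":
        return ResidueScale(self.name + "_flipped", {k: -v for k, v in self.values.items()})


def _read_table(resource: str) -> list[tuple[str, ...]]:
    text = resources.files("comscan.resources").joinpath(resource).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(tuple(line.split("\t")))
    return rows


def load_scale(name: str = "ww_interface") -> ResidueScale:
    """Load a packaged hydrophobicity scale (``ww_interface`` or ``ww_octanol``)."""
    rows = _read_table(f"{name}.tsv")
    return ResidueScale(name, {aa: float(v) for aa, v in rows})


def load_pka() -> dict[str, tuple[float, int]]:
    """Packaged side-chain pKa set: residue -> (pKa, charge sign when ionized)."""
    return {aa: (float(pka), int(sign)) for aa, pka, sign in _read_table("pka_sidechain.tsv")}


WW_INTERFACE = load_scale("ww_interface")
WW_OCTANOL = load_scale("ww_octanol")
PKA_SIDECHAIN = load_pka()


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed-mean hydropathy: ``scores[i]`` is the mean over ``seq[i:i+window]``."""

    window: int
    scores: np.ndarray


@dataclass(frozen=True)
class CompositionProfile:
    """Residue-class composition of a segment (fractions over non-X residues)."""

    length: int
    hydroxylated_frac: float
    basic_frac: float
    acidic_frac: float
    proline_count: int
    arginine_count: int
    lysine_count: int


def sliding_hydropathy(seq: str, scale: ResidueScale, window: int) -> HydropathyProfile:
    """Mean hydrophobicity over every length-*window* stretch of *seq*."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq):
        raise ValueError("sequence shorter than window")
    values = scale.of(seq)
    kernel = np.ones(window) / window
    return HydropathyProfile(window, np.convolve(values, kernel, mode="valid"))


def periodicity_moment(segment: str, scale: ResidueScale, angle: float) -> float:
    """Per-residue hydrophobic moment of *segment* at periodicity *angle* (degrees).

    mu = sqrt((sum_i h_i sin(i*delta))^2 + (sum_i h_i cos(i*delta))^2),
    i from 0; the return value is mu / len(segment). 100 degrees probes
    alpha-helical amphipathy, 180 degrees probes beta-strand alternation.
    """
    n = len(segment)
    if n < 2:
        raise ValueError("segment must have length >= 2")
    h = scale.of(segment)
    delta = math.radians(angle)
    idx = np.arange(n)
    mu = math.hypot(float(np.dot(h, np.sin(idx * delta))), float(np.dot(h, np.cos(idx * delta))))
    return mu / n


def moment_profile(seq: str, scale: ResidueScale, window: int, angle: float) -> np.ndarray:
    """Per-residue moments of every length-*window* stretch (vectorized)."""
    if window > len(seq):
        return np.empty(0)
    h = scale.of(seq)
    delta = math.radians(angle)
    phases = np.exp(1j * delta * np.arange(window))
    # correlation: window starting at s gets sum_j h[s+j] * e^{i j delta}
    sums = np.convolve(h, phases[::-1], mode="valid")
    return np.abs(sums) / window


def positive_count(segment: str) -> int:
    """Number of positively charged residues (K + R; His excluded)."""
    return sum(1 for aa in segment if aa in _POSITIVE)


def net_charge(segment: str, pH: float) -> float:
    """Henderson-Hasselbalch net side-chain charge of *segment* at *pH*.

    D, E, C, Y contribute negatively and K, R, H positively using the
    packaged pKa set; free termini are excluded (segments are internal
    windows of a chain).
    """
    if len(segment) < 1:
        raise ValueError("segment must be non-empty")
    total = 0.0
    for aa in segment:
        entry = PKA_SIDECHAIN.get(aa)
        if entry is None:
            continue
        pka, sign = entry
        if sign > 0:
            total += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            total -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return total


def isoelectric_point(segment: str, tol: float = 1e-4) -> tuple[float, bool]:
    """pH at which the side-chain net charge of *segment* crosses zero.

    Returns ``(pI, ionizable)``. Segments with no ionizable side chains
    return the convention value 7.0 with ``ionizable=False``. Segments
    whose charge never crosses zero inside [0, 14] (only basic or only
    acidic groups) return the boundary pH where |charge| is smallest.
    """
    if not any(aa in PKA_SIDECHAIN for aa in segment):
        return 7.0, False
    lo, hi = 0.0, 14.0
    f_lo, f_hi = net_charge(segment, lo), net_charge(segment, hi)
    if f_lo > 0 and f_hi > 0:
        return 14.0, True
    if f_lo < 0 and f_hi < 0:
        return 0.0, True
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(segment, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def composition(segment: str) -> CompositionProfile:
    """Residue-class composition of *segment* (fractions over non-X residues)."""
    if len(segment) < 1:
        raise ValueError("segment must be non-empty")
    n = sum(1 for aa in segment if aa != "X")
    denom = max(n, 1)
    counts = {aa: segment.count(aa) for aa in set(segment)}

    def frac(residues: Iterable[str]) -> float:
        return sum(counts.get(aa, 0) for aa in residues) / denom

    return CompositionProfile(
        length=len(segment),
        hydroxylated_frac=frac(_HYDROXYLATED),
        basic_frac=frac(_BASIC),
        acidic_frac=frac(_ACIDIC),
        proline_count=counts.get("P", 0),
        arginine_count=counts.get("R", 0),
        lysine_count=counts.get("K", 0),
    )
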