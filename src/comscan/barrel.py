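"""Membrane beta-strand and beta-barrel candidate detection.

Transmembrane beta-strands alternate hydrophobic (lipid-facing) and
hydrophilic (pore-facing) side chains; a 180-degree hydrophobic moment
quantifies that alternation. Candidate strands are all 9-11 residue
windows whose per-residue moment reaches ``beta_moment_cutoff``,
greedily selected best-moment-first into a disjoint set. A protein is
a barrel candidate when 8-24 strands are found. Candidates whose
"strands" are better explained by detected alpha-helical anchors are
excluded and fall back to the alpha-helical classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import ThresholdConfig, DEFAULT_CONFIG
from .features import ResidueScale, composition, load_scale, moment_profile
from .io import ProteinRecord
from .tmd import HIGH, TMDSegment

_HYDROPHILIC = frozenset("RNDQEHKSTY")


@dataclass(frozen=True)
class Strand:
    """One candidate membrane strand (0-based half-open)."""

    start: int
    end: int
    moment: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class StrandSet:
    """Detected strands and the barrel-candidacy verdict for one protein."""

    strands: tuple[Strand, ...]
    is_barrel_candidate: bool
    beta_signal_region: tuple[int, int] | None
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def n_strands(self) -> int:
        return len(self.strands)


@dataclass(frozen=True)
class BetaSignalFeatures:
    """Annotation-only features of the C-terminal strand pair."""

    hydrophilic_at_penultimate_end: bool
    penultimate_end_residue: str
    terminal_strand_composition: object


def detect_strands(
    record: ProteinRecord,
    config: ThresholdConfig = DEFAULT_CONFIG,
    scale: ResidueScale | None = None,
) -> StrandSet:
    """Scan *record* for amphiphilic beta-strand windows.

    All windows of length ``strand_len_min``..``strand_len_max`` are
    scored with the 180-degree moment; qualifying windows are picked
    greedily (highest moment first, ties broken by smaller start, then
    shorter window) into a disjoint strand set. The beta-signal region
    is the span of the two C-terminal strands when at least two exist.
    """
    scale = scale or load_scale(config.scale_name)
    seq = record.sequence
    candidates: list[tuple[float, int, int]] = []  # (moment, start, length)
    for w in range(config.strand_len_min, config.strand_len_max + 1):
        if w > len(seq):
            continue
        moments = moment_profile(seq, scale, w, config.beta_angle)
        for s, m in enumerate(moments):
            if m >= config.beta_moment_cutoff:
                candidates.append((float(m), s, w))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    occupied = [False] * len(seq)
    chosen: list[Strand] = []
    for m, s, w in candidates:
        if any(occupied[s : s + w]):
            continue
        for i in range(s, s + w):
            occupied[i] = True
        chosen.append(Strand(s, s + w, m))
    chosen.sort(key=lambda st: st.start)

    n = len(chosen)
    signal = (chosen[-2].start, chosen[-1].end) if n >= 2 else None
    return StrandSet(
        strands=tuple(chosen),
        is_barrel_candidate=config.strands_min <= n <= config.strands_max,
        beta_signal_region=signal,
    )


def beta_signal_features(strand_set: StrandSet, record: ProteinRecord) -> BetaSignalFeatures:
    """Annotate the C-terminal strand pair of a candidate barrel.

    In mitochondrial barrels a hydrophilic residue at the C-terminal
    end of the penultimate strand marks mitochondrial targeting; here
    the feature is reported for annotation only and never used to
    reject chloroplast candidates.
    """
    if strand_set.n_strands < 2:
        raise ValueError("no penultimate strand")
    penultimate = strand_set.strands[-2]
    terminal = strand_set.strands[-1]
    last_residue = record.sequence[penultimate.end - 1]
    return BetaSignalFeatures(
        hydrophilic_at_penultimate_end=last_residue in _HYDROPHILIC,
        penultimate_end_residue=last_residue,
        terminal_strand_composition=composition(record.sequence[terminal.start : terminal.end]),
    )


def exclude_barrel(
    strand_set: StrandSet,
    tmds: list[TMDSegment],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> StrandSet:
    """Void barrel candidacy when alpha-helical anchors explain the strands.

    A candidate is excluded (reason ``alpha-anchor``) when highly
    hydrophobic TMDs — or two or more TMDs of any grade — cover more
    than ``barrel_overlap_fraction`` of the total strand residues.
    Excluded candidates revert to the alpha-helical pathway rules.
    """
    total = sum(len(st) for st in strand_set.strands)
    if total == 0 or not tmds:
        return strand_set

    def covered(segments: list[TMDSegment]) -> int:
        return sum(seg.overlap(st.start, st.end) for seg in segments for st in strand_set.strands)

    high = [seg for seg in tmds if seg.grade == HIGH]
    threshold = config.barrel_overlap_fraction * total
    if covered(high) > threshold or (len(tmds) >= 2 and covered(tmds) > threshold):
        return replace(strand_set, excluded=True, exclusion_reason="alpha-anchor")
    return strand_set
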