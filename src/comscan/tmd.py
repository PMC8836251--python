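"""Alpha-helical transmembrane-domain (TMD) detection.

A membrane-spanning helix is roughly 20 residues long; detection slides
a 19-residue window over the hydropathy profile and merges every
qualifying window (mean hydrophobicity >= ``tmd_detect_cutoff``) into
maximal disjoint segments. Each segment is then placed (N-terminal,
C-terminal, or internal) and graded: MODERATE if its mean
hydrophobicity is below the 0.4 Wimley-White ceiling that separates
chloroplast/mitochondrial anchors from ER-directed ones, HIGH
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .config import ThresholdConfig, DEFAULT_CONFIG
from .features import ResidueScale, load_scale, sliding_hydropathy
from .io import ProteinRecord

N_TERMINAL = "N_TERMINAL"
C_TERMINAL = "C_TERMINAL"
INTERNAL = "INTERNAL"
MODERATE = "MODERATE"
HIGH = "HIGH"


@dataclass(frozen=True)
class TMDSegment:
    """A detected membrane-spanning stretch (0-based half-open coordinates)."""

    start: int
    end: int
    mean_hydrophobicity: float
    location: str = INTERNAL
    grade: str = MODERATE
    note: str = ""

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def _scale_for(config: ThresholdConfig) -> ResidueScale:
    return load_scale(config.scale_name)


def detect_tmds(
    record: ProteinRecord,
    config: ThresholdConfig = DEFAULT_CONFIG,
    scale: ResidueScale | None = None,
) -> list[TMDSegment]:
    """Find candidate membrane-spanning alpha-helices in *record*.

    Every window of ``tmd_window`` residues whose mean hydrophobicity
    reaches ``tmd_detect_cutoff`` is covered by a segment; overlapping
    or adjacent qualifying windows merge into maximal segments, so no
    two reported segments overlap. Segments come back sorted by start,
    located relative to the termini and graded MODERATE/HIGH against
    ``ww_moderate_cutoff``.
    """
    seq = record.sequence
    if len(seq) < config.tmd_window:
        warnings.warn(
            f"record {record.id!r}: sequence shorter than TMD window "
            f"({len(seq)} < {config.tmd_window}); no TMD scan performed",
            stacklevel=2,
        )
        return []
    scale = scale or _scale_for(config)
    profile = sliding_hydropathy(seq, scale, config.tmd_window)
    qualifying = np.flatnonzero(profile.scores >= config.tmd_detect_cutoff)
    if qualifying.size == 0:
        return []

    values = scale.of(seq)
    segments: list[TMDSegment] = []
    run_start = int(qualifying[0])
    prev = int(qualifying[0])
    for idx in list(qualifying[1:]) + [None]:  # type: ignore[list-item]
        # windows merge while they overlap or touch (gap <= window length)
        if idx is not None and int(idx) - prev <= config.tmd_window:
            prev = int(idx)
            continue
        start, end = run_start, prev + config.tmd_window
        mean_h = float(values[start:end].mean())
        segments.append(
            TMDSegment(
                start=start,
                end=end,
                mean_hydrophobicity=mean_h,
                grade=MODERATE if mean_h < config.ww_moderate_cutoff else HIGH,
            )
        )
        if idx is not None:
            run_start = prev = int(idx)
    return [locate_tmd(seg, len(seq), config) for seg in segments]


def locate_tmd(segment: TMDSegment, seq_length: int, config: ThresholdConfig = DEFAULT_CONFIG) -> TMDSegment:
    """Label *segment* as N-terminal, C-terminal or internal.

    On short proteins both positional tests can pass; the C-terminal
    label wins and a conflict note is attached.
    """
    if segment.start < 0 or segment.end > seq_length:
        raise ValueError("segment outside sequence bounds")
    is_n = segment.start < config.sa_nterm_limit
    is_c = (seq_length - segment.end) <= config.ta_cterm_limit
    if is_n and is_c:
        return replace(
            segment,
            location=C_TERMINAL,
            note="both N- and C-terminal positional tests passed; labelled C_TERMINAL",
        )
    if is_c:
        return replace(segment, location=C_TERMINAL)
    if is_n:
        return replace(segment, location=N_TERMINAL)
    return replace(segment, location=INTERNAL)
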