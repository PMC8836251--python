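"""Terminal transit-peptide character scoring.

Canonical chloroplast transit peptides (TPs) are rich in hydroxylated
(S/T) and basic residues, essentially devoid of acidic residues, often
contain several prolines, and are arginine-poor relative to
mitochondrial presequences. The scorer turns those composition rules
into a linear composite over a fixed-length terminal segment:

    score = w1*hydroxylated_frac + w2*lysine_frac - w3*acidic_frac
            - w4*arginine_frac + w5*min(proline_count, 3)/3

A terminus is flagged when the score reaches ``tp_score_cutoff`` AND
the acidic fraction stays within ``acidic_tolerance``. The C-terminus
is scored on the *reversed* last segment, so a reverse TP-like (rTP)
tail — a sequence sharing TP physicochemistry when read toward the
terminus — is detected by the very same scorer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .config import ThresholdConfig, DEFAULT_CONFIG
from .features import CompositionProfile, composition
from .io import ProteinRecord

N = "N"
C = "C"


@dataclass(frozen=True)
class TerminalSignalScore:
    """Composition-based evaluation of one terminus of a protein."""

    terminus: str  # "N" or "C"
    start: int  # segment coordinates, 0-based half-open, on the forward chain
    end: int
    profile: CompositionProfile
    score: float
    flag: bool
    truncated: bool = False  # sequence shorter than tp_segment_len


def score_transit_peptide(
    record: ProteinRecord,
    terminus: str,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> TerminalSignalScore:
    """Score the N-terminal (or reversed C-terminal) segment of *record*."""
    if terminus not in (N, C):
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")
    seq = record.sequence
    if not seq:
        raise ValueError("empty sequence")
    seg_len = config.tp_segment_len
    truncated = len(seq) < seg_len
    if truncated:
        warnings.warn(
            f"record {record.id!r}: sequence shorter than tp_segment_len; "
            "scoring the whole sequence",
            stacklevel=2,
        )
        seg_len = len(seq)
    if terminus == N:
        start, end = 0, seg_len
        segment = seq[:seg_len]
    else:
        start, end = len(seq) - seg_len, len(seq)
        segment = seq[start:][::-1]  # read toward the terminus

    prof = composition(segment)
    denom = max(sum(1 for aa in segment if aa != "X"), 1)
    score = (
        config.w_hydroxylated * prof.hydroxylated_frac
        + config.w_lysine * prof.lysine_count / denom
        - config.w_acidic * prof.acidic_frac
        - config.w_arginine * prof.arginine_count / denom
        + config.w_proline * min(prof.proline_count, 3) / 3
    )
    flag = score >= config.tp_score_cutoff and prof.acidic_frac <= config.acidic_tolerance
    return TerminalSignalScore(
        terminus=terminus,
        start=start,
        end=end,
        profile=prof,
        score=score,
        flag=flag,
        truncated=truncated,
    )


def assign_terminal_flags(
    n_score: TerminalSignalScore,
    c_score: TerminalSignalScore,
    category: str,
) -> tuple[bool, bool, list[str]]:
    """Copy terminal flags onto a classified protein.

    Flags are independent of *category*: TP and rTP character occurs in
    small numbers across every topology class. Both flags true is
    permitted but reported as a conflict note.
    """
    notes: list[str] = []
    if n_score.flag and c_score.flag:
        notes.append("both N-terminal TP and C-terminal rTP-like flags set")
    return n_score.flag, c_score.flag, notes


def detect_rkst_motif(
    cts_segment: str, window: int = DEFAULT_CONFIG.rkst_window
) -> tuple[bool, int | None]:
    """Find an RK/ST motif: basic (R/K) and hydroxylated (S/T) residues
    co-occurring within a short window of the C-terminal sequence.

    Returns ``(found, start)`` with the earliest qualifying window
    start (0-based). Annotation only; never gates TA classification.
    """
    if len(cts_segment) < 2:
        raise ValueError("segment must have length >= 2")
    for s in range(len(cts_segment)):
        chunk = cts_segment[s : s + window]
        if any(aa in "RK" for aa in chunk) and any(aa in "ST" for aa in chunk):
            return True, s
    return False, None


def poly_glycine_runs(sequence: str, min_len: int = 6) -> list[tuple[int, int]]:
    """0-based half-open coordinates of poly-G runs of at least *min_len*.

    Emitted as annotation only (a poly-glycine stretch downstream of a
    TP is part of the bipartite targeting signal of the TOC75 channel).
    """
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(sequence):
        if sequence[i] == "G":
            j = i
            while j < len(sequence) and sequence[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs
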