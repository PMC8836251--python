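"""Decision procedure assigning each protein one targeting-pathway category.

Stage order mirrors the screening pipeline: beta-barrel detection,
beta-barrel exclusion, alpha-helical TMD detection, then N-/C-terminal
transit-peptide detection. The decision tree:

1. barrel candidate, not excluded              -> BETA_BARREL
2. no TMDs                                     -> OTHER
3. two or more TMDs                            -> MULTI_PASS
4. exactly one TMD:
   N-terminal, MODERATE, CPR with >= 3 K/R     -> SA
   C-terminal                                  -> TA
   anything else                               -> OTHER_SINGLE_PASS
                                                  (+ note naming the
                                                  failed SA/TA criterion)

Terminal TP/rTP flags are attached independently of the category.
Conflicts are reported in notes, never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .barrel import StrandSet, detect_strands, exclude_barrel
from .config import ThresholdConfig, DEFAULT_CONFIG
from .features import load_scale, net_charge, positive_count
from .io import ProteinRecord
from .termsig import (
    TerminalSignalScore,
    assign_terminal_flags,
    detect_rkst_motif,
    score_transit_peptide,
)
from .tmd import C_TERMINAL, MODERATE, N_TERMINAL, TMDSegment, detect_tmds

SA = "SA"
TA = "TA"
OTHER_SINGLE_PASS = "OTHER_SINGLE_PASS"
MULTI_PASS = "MULTI_PASS"
BETA_BARREL = "BETA_BARREL"
OTHER = "OTHER"

CATEGORIES = (SA, TA, OTHER_SINGLE_PASS, MULTI_PASS, BETA_BARREL, OTHER)


@dataclass(frozen=True)
class ClassificationResult:
    """Final category for one protein, with flags and an evidence trail."""

    id: str
    category: str
    n_tp_flag: bool
    c_tp_like_flag: bool
    tmds: tuple[TMDSegment, ...]
    strand_set: StrandSet
    n_score: TerminalSignalScore
    c_score: TerminalSignalScore
    evidence: tuple[str, ...]
    conflict_notes: tuple[str, ...]

    @property
    def n_tmds(self) -> int:
        return len(self.tmds)


def classify_protein(
    record: ProteinRecord, config: ThresholdConfig = DEFAULT_CONFIG
) -> ClassificationResult:
    """Run the full stage pipeline on one record."""
    scale = load_scale(config.scale_name)
    evidence: list[str] = []
    conflicts: list[str] = []

    try:
        strand_set = detect_strands(record, config, scale)
        tmds = tuple(detect_tmds(record, config, scale))
        strand_set = exclude_barrel(strand_set, list(tmds), config)
    except Exception as exc:
        raise type(exc)(f"record {record.id!r}: {exc}") from exc

    evidence.append(f"strands={strand_set.n_strands}")
    evidence.append(f"tmds={len(tmds)}")
    for seg in tmds:
        if seg.note:
            conflicts.append(seg.note)

    seq = record.sequence
    if strand_set.is_barrel_candidate and not strand_set.excluded:
        category = BETA_BARREL
        evidence.append(
            f"barrel candidate: {strand_set.n_strands} strands within "
            f"[{config.strands_min}, {config.strands_max}]"
        )
    else:
        if strand_set.is_barrel_candidate and strand_set.excluded:
            evidence.append(f"barrel excluded ({strand_set.exclusion_reason})")
        if len(tmds) == 0:
            category = OTHER
            evidence.append("no predictable transmembrane elements")
        elif len(tmds) >= 2:
            category = MULTI_PASS
            evidence.append(f"{len(tmds)} membrane-spanning helices")
        else:
            seg = tmds[0]
            if seg.location == C_TERMINAL:
                category = TA
                cts = seq[seg.end :]
                evidence.append("single C-terminal anchor")
                if cts:
                    charge = net_charge(cts, 7.0)
                    evidence.append(f"CTS net charge at pH 7: {charge:+.2f}")
                    if charge <= 0:
                        conflicts.append("TA with non-positive CTS net charge")
                    found, pos = detect_rkst_motif(cts, config.rkst_window) if len(cts) >= 2 else (False, None)
                    if found:
                        evidence.append(f"RK/ST motif in CTS at offset {pos}")
            elif seg.location == N_TERMINAL:
                cpr = seq[seg.end : seg.end + config.cpr_window]
                positives = positive_count(cpr)
                moderate = seg.grade == MODERATE
                if moderate and positives >= config.cpr_min_positive:
                    category = SA
                    evidence.append(
                        f"single moderate N-terminal anchor; CPR has {positives} K/R"
                    )
                else:
                    category = OTHER_SINGLE_PASS
                    if not moderate:
                        conflicts.append(
                            "SA criterion failed: anchor hydrophobicity not MODERATE "
                            f"({seg.mean_hydrophobicity:.2f} >= {config.ww_moderate_cutoff})"
                        )
                    if positives < config.cpr_min_positive:
                        conflicts.append(
                            f"SA criterion failed: CPR has {positives} K/R "
                            f"(< {config.cpr_min_positive})"
                        )
            else:
                category = OTHER_SINGLE_PASS
                evidence.append("single internal anchor; not SA or TA")

    n_score = score_transit_peptide(record, "N", config)
    c_score = score_transit_peptide(record, "C", config)
    n_flag, c_flag, flag_notes = assign_terminal_flags(n_score, c_score, category)
    conflicts.extend(flag_notes)
    if n_flag:
        evidence.append(f"N-terminal TP character (score {n_score.score:.2f})")
    if c_flag:
        evidence.append(f"C-terminal reverse TP-like character (score {c_score.score:.2f})")

    return ClassificationResult(
        id=record.id,
        category=category,
        n_tp_flag=n_flag,
        c_tp_like_flag=c_flag,
        tmds=tmds,
        strand_set=strand_set,
        n_score=n_score,
        c_score=c_score,
        evidence=tuple(evidence),
        conflict_notes=tuple(conflicts),
    )


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer, ties away from zero (41/138 -> 30%)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class BatchSummary:
    """Category counts and integer percentages for one classified batch."""

    total: int
    counts: dict[str, int]
    percents: dict[str, int]
    single_pass_percent: int


def classify_batch(
    records: list[ProteinRecord], config: ThresholdConfig = DEFAULT_CONFIG
) -> tuple[list[ClassificationResult], BatchSummary]:
    """Classify every record (order preserved) and summarize the batch."""
    if not records:
        raise ValueError("empty batch")
    results = [classify_protein(rec, config) for rec in records]
    counts = {cat: 0 for cat in CATEGORIES}
    for res in results:
        counts[res.category] += 1
    total = len(results)
    percents = {cat: round_half_away_from_zero(100.0 * n / total) for cat, n in counts.items()}
    single = counts[SA] + counts[TA] + counts[OTHER_SINGLE_PASS]
    summary = BatchSummary(
        total=total,
        counts=counts,
        percents=percents,
        single_pass_percent=round_half_away_from_zero(100.0 * single / total),
    )
    return results, summary
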