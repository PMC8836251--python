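"""Pipeline thresholds with per-key provenance.

Every tunable the pipeline consumes lives in :class:`ThresholdConfig`.
Each key carries a provenance tag: ``PAPER`` for values taken from the
published rule set (the 0.4 Wimley-White ceiling for moderately
hydrophobic anchors, the ~20-residue anchor length, the >=3-positive
CPR rule, the 8-24 strand / 9-11 residue barrel architecture) and
``DECISION`` for values this package had to fix itself (detection
cutoffs, segment lengths, score weights). Configs serialize to a flat
``key<TAB>value<TAB>tag`` text format so every run is auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

PAPER = "PAPER"
DECISION = "DECISION"

#: provenance tag for every config key
PROVENANCE: dict[str, str] = {
    "scale_name": DECISION,
    "ww_moderate_cutoff": PAPER,
    "tmd_window": DECISION,
    "tmd_detect_cutoff": DECISION,
    "tmd_nominal_length": PAPER,
    "sa_nterm_limit": DECISION,
    "ta_cterm_limit": DECISION,
    "cpr_window": DECISION,
    "cpr_min_positive": PAPER,
    "strand_len_min": PAPER,
    "strand_len_max": PAPER,
    "strands_min": PAPER,
    "strands_max": PAPER,
    "beta_angle": DECISION,
    "beta_moment_cutoff": DECISION,
    "barrel_overlap_fraction": DECISION,
    "tp_segment_len": DECISION,
    "tp_score_cutoff": DECISION,
    "acidic_tolerance": DECISION,
    "w_hydroxylated": DECISION,
    "w_lysine": DECISION,
    "w_acidic": DECISION,
    "w_arginine": DECISION,
    "w_proline": DECISION,
    "rkst_window": DECISION,
    "percent_rounding": DECISION,
}


@dataclass(frozen=True)
class ThresholdConfig:
    """All thresholds consumed by the classification pipeline.

    Units: lengths and counts in residues; hydrophobicities and moments
    are dimensionless values on the active (sign-flipped, hydrophobic =
    positive) scale; ``beta_angle`` in degrees.
    """

    #: residue hydrophobicity scale ("ww_interface" or "ww_octanol")
    scale_name: str = "ww_interface"
    #: anchors with mean hydrophobicity below this are MODERATE (SA-like)
    ww_moderate_cutoff: float = 0.4
    #: sliding window for hydropathy profiles
    tmd_window: int = 19
    #: windowed mean at or above this counts as membrane-spanning
    tmd_detect_cutoff: float = 0.2
    #: nominal alpha-helical anchor length
    tmd_nominal_length: int = 20
    #: a TMD starting before this offset is N-terminal
    sa_nterm_limit: int = 40
    #: a TMD ending within this many residues of the C-terminus is C-terminal
    ta_cterm_limit: int = 30
    #: residues scanned after an N-terminal TMD for the CPR
    cpr_window: int = 15
    #: minimum K+R count in the CPR for SA classification
    cpr_min_positive: int = 3
    strand_len_min: int = 9
    strand_len_max: int = 11
    strands_min: int = 8
    strands_max: int = 24
    #: periodicity angle probing beta-strand alternation
    beta_angle: float = 180.0
    #: per-residue hydrophobic moment at or above this marks a strand
    beta_moment_cutoff: float = 0.5
    #: fraction of strand residues covered by alpha anchors that voids a barrel
    barrel_overlap_fraction: float = 0.5
    #: terminal segment length scored for transit-peptide character
    tp_segment_len: int = 60
    #: composite score at or above this flags a transit-peptide-like terminus
    tp_score_cutoff: float = 0.85
    #: maximum acidic fraction tolerated in a flagged terminus
    acidic_tolerance: float = 0.05
    w_hydroxylated: float = 1.0
    w_lysine: float = 1.0
    w_acidic: float = 2.0
    w_arginine: float = 1.0
    w_proline: float = 0.5
    #: RK/ST motif co-occurrence window
    rkst_window: int = 6
    percent_rounding: str = "half_away_from_zero"

    def __post_init__(self) -> None:
        for name in (
            "tmd_window",
            "tmd_nominal_length",
            "sa_nterm_limit",
            "ta_cterm_limit",
            "cpr_window",
            "cpr_min_positive",
            "strand_len_min",
            "strand_len_max",
            "strands_min",
            "strands_max",
            "tp_segment_len",
            "rkst_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.strand_len_min > self.strand_len_max:
            raise ValueError("strand_len_min > strand_len_max")
        if self.strands_min > self.strands_max:
            raise ValueError("strands_min > strands_max")

    def provenance(self, key: str) -> str:
        return PROVENANCE[key]

    def to_text(self) -> str:
        lines = ["# key\tvalue\tprovenance"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}\t{getattr(self, f.name)}\t{PROVENANCE[f.name]}")
        return "\n".join(lines) + "\n"

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "ThresholdConfig":
        kinds = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"malformed config line {lineno}: {raw!r}")
            key, value = parts[0], parts[1]
            if key not in kinds:
                raise ValueError(f"unknown config key {key!r} (line {lineno})")
            kind = str(kinds[key])
            if "int" in kind:
                kwargs[key] = int(value)
            elif "float" in kind:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)  # type: ignore[arg-type]

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ThresholdConfig":
        return cls.from_text(Path(path).read_text())


DEFAULT_CONFIG = ThresholdConfig()
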