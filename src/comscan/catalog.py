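"""The curated chloroplast outer membrane (COM) proteome catalog.

A packaged table of 138 Arabidopsis thaliana loci with their
literature-assigned targeting-pathway topology category, predicted
N-terminal transit-peptide and C-terminal reverse TP-like flags, a
marker for the 21 proteins added beyond the Inoue (2015) list of 117,
and functional categories where assigned. This is curated data, not
classifier output; :func:`summarize_catalog` computes the proteome-wide
summary statistics from it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

from .classify import (
    BETA_BARREL,
    CATEGORIES,
    MULTI_PASS,
    OTHER,
    OTHER_SINGLE_PASS,
    SA,
    TA,
    round_half_away_from_zero,
)
from .config import ThresholdConfig, DEFAULT_CONFIG

_AGI_RE = re.compile(r"^At[1-5CM]g\d{5}(\.\d+)?$")

FUNCTIONAL_CATEGORIES = (
    "solute and ion transport",
    "protein import",
    "protein turnover and modification",
    "lipid metabolism",
    "carbohydrate metabolism and regulation",
    "other metabolism and regulation",
    "intracellular communication",
    "organellar fission",
    "unknown",
    "unassigned",
)


@dataclass(frozen=True)
class CatalogEntry:
    """One catalogued COM protein."""

    agi: str
    name: str
    topology_category: str
    n_tp: bool
    c_tp_like: bool
    newly_identified: bool
    functional_category: str = "unassigned"

    def __post_init__(self) -> None:
        if not _AGI_RE.match(self.agi):
            raise ValueError(f"{self.agi!r} is not a valid AGI identifier")
        if self.topology_category not in CATEGORIES:
            raise ValueError(f"{self.agi}: unknown topology {self.topology_category!r}")


@dataclass(frozen=True)
class CatalogSummary:
    """Counts and integer percentages over one catalog."""

    total: int
    counts: dict[str, int]
    percents: dict[str, int]
    single_pass_percent: int
    new_count: int
    n_tp_in_other_percent: int
    c_tp_like_in_other_percent: int
    both_flags_count: int


def _parse_row(line: str, lineno: int) -> CatalogEntry:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 7:
        raise ValueError(f"malformed catalog row at line {lineno}: expected 7 fields, got {len(parts)}")
    agi, name, topo, n_tp, c_tp, new, func = parts
    try:
        return CatalogEntry(
            agi=agi,
            name=name,
            topology_category=topo,
            n_tp=bool(int(n_tp)),
            c_tp_like=bool(int(c_tp)),
            newly_identified=bool(int(new)),
            functional_category=func,
        )
    except ValueError as exc:
        raise ValueError(f"malformed catalog row at line {lineno}: {exc}") from exc


def load_catalog(source: Union[str, Path] = "builtin") -> list[CatalogEntry]:
    """Load the builtin catalog, or a user TSV with the same columns."""
    if source == "builtin":
        text = resources.files("comscan.resources").joinpath("com_catalog.tsv").read_text()
    else:
        text = Path(source).read_text()
    entries: list[CatalogEntry] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        entries.append(_parse_row(line, lineno))
    if not entries:
        raise ValueError(f"{source}: no catalog entries")
    seen: set[str] = set()
    for e in entries:
        if e.agi in seen:
            raise ValueError(f"duplicate catalog entry {e.agi}")
        seen.add(e.agi)
    return entries


def summarize_catalog(
    entries: list[CatalogEntry], config: ThresholdConfig = DEFAULT_CONFIG
) -> CatalogSummary:
    """Compute proteome-wide statistics from catalog *entries*.

    Percentages are rounded half-away-from-zero to integers. The TP and
    rTP percentages are computed over the OTHER topology group only,
    where those signals are the sole candidate targeting elements.
    """
    if not entries:
        raise ValueError("empty catalog")
    total = len(entries)
    counts = {cat: 0 for cat in CATEGORIES}
    for e in entries:
        counts[e.topology_category] += 1
    percents = {cat: round_half_away_from_zero(100.0 * n / total) for cat, n in counts.items()}
    single = counts[SA] + counts[TA] + counts[OTHER_SINGLE_PASS]
    other_entries = [e for e in entries if e.topology_category == OTHER]
    n_other = max(len(other_entries), 1)
    return CatalogSummary(
        total=total,
        counts=counts,
        percents=percents,
        single_pass_percent=round_half_away_from_zero(100.0 * single / total),
        new_count=sum(e.newly_identified for e in entries),
        n_tp_in_other_percent=round_half_away_from_zero(
            100.0 * sum(e.n_tp for e in other_entries) / n_other
        ),
        c_tp_like_in_other_percent=round_half_away_from_zero(
            100.0 * sum(e.c_tp_like for e in other_entries) / n_other
        ),
        both_flags_count=sum(e.n_tp and e.c_tp_like for e in entries),
    )


def summary_rows(summary: CatalogSummary) -> list[tuple[str, str]]:
    """Flatten a summary into (statistic, value) rows for TSV output."""
    rows: list[tuple[str, str]] = [("total", str(summary.total))]
    for cat in CATEGORIES:
        rows.append((f"count_{cat}", str(summary.counts[cat])))
        rows.append((f"percent_{cat}", str(summary.percents[cat])))
    rows += [
        ("single_pass_percent", str(summary.single_pass_percent)),
        ("newly_identified_count", str(summary.new_count)),
        ("n_tp_in_other_percent", str(summary.n_tp_in_other_percent)),
        ("c_tp_like_in_other_percent", str(summary.c_tp_like_in_other_percent)),
        ("both_flags_count", str(summary.both_flags_count)),
    ]
    return rows
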