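"""FASTA input and tab-separated result output.

Coordinates are 0-based half-open everywhere inside the package and
converted to 1-based inclusive only when written to report files.
Result files are byte-stable for a fixed input and config: no
timestamps or environment-dependent content in data lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Union

from Bio import SeqIO

from .features import ALPHABET

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ClassificationResult


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence entering the pipeline."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper()
    while seq.endswith("*"):  # stop characters stripped from the end only
        seq = seq[:-1]
    return seq


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord`\\ s.

    Sequences are upper-cased; trailing ``*`` stop characters are
    stripped. Raises on an empty file, on residues outside the accepted
    alphabet (20 canonical letters plus X) and on duplicate ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=_normalize(str(entry.seq), entry.id),
                description=entry.description,
            )
        )
    if not records:
        raise ValueError(f"{path}: no records")
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = sorted(rid for rid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"{path}: duplicate record ids: {', '.join(dupes)}")
    return records


def write_fasta(records: list[ProteinRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if not rec.description or rec.description.split()[0] == rec.id:
                header = rec.description or rec.id
            else:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


RESULT_COLUMNS = (
    "id",
    "category",
    "n_tp_flag",
    "c_tp_like_flag",
    "n_tmds",
    "tmd_coordinates",
    "evidence_notes",
)


def format_coordinates(tmds) -> str:
    """1-based inclusive ``start-end`` coordinates, semicolon-separated."""
    return ";".join(f"{seg.start + 1}-{seg.end}" for seg in tmds)


def write_results(results: list["ClassificationResult"], path: Union[str, Path]) -> None:
    """Write per-protein classification results as a TSV report."""
    if not results:
        raise ValueError("no results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            notes = list(res.evidence) + [f"conflict: {c}" for c in res.conflict_notes]
            fh.write(
                "\t".join(
                    (
                        res.id,
                        res.category,
                        str(int(res.n_tp_flag)),
                        str(int(res.c_tp_like_flag)),
                        str(res.n_tmds),
                        format_coordinates(res.tmds),
                        " | ".join(notes),
                    )
                )
                + "\n"
            )
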