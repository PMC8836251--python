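"""Seeded generator of labelled synthetic protein sequences.

Each construct carries the physicochemical signature of one targeting
category so that every pipeline stage can be tested without external
data:

* SA — a moderately hydrophobic ~20-residue N-terminal anchor placed at
  residues 5-24, followed by a C-terminal positively charged region
  (CPR) with a planted number of K/R residues;
* TA — the same kind of anchor ending a few residues from the
  C-terminus, flanked by a net-positive C-terminal sequence (CTS);
* OTHER_SINGLE_PASS — a single internal anchor far from both termini;
* MULTI_PASS — two or more anchors separated by long soluble linkers;
* BETA_BARREL — 8-24 strands of 9-11 residues with strict
  hydrophobic/polar alternation, joined by short polar loops;
* OTHER — featureless soluble background.

Optional modifiers plant an N-terminal transit-peptide-like prefix
(60-mer: S/T >= 30%, K >= 10%, no D/E/R, >= 2 P) or its reversed
C-terminal counterpart.

Soluble background draws uniformly from the polar/small residue pool
{G,S,T,N,Q,A,D,E,K,P}. Barrel loops and flanks draw from the same pool
minus D/E and are emitted as doubled pairs (e.g. ``GGSSNN``), which
suppresses accidental 180-degree alternation next to planted strands.
Anchors and strands are rejection-sampled until their measured windowed
hydrophobicity / periodicity moment meets the planted target
(tolerance +-0.05 on anchor mean; hard cap 10000 attempts).

Labels are generative ground truth, not biological claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ThresholdConfig, DEFAULT_CONFIG
from .features import load_scale, periodicity_moment
from .io import ProteinRecord
from .classify import BETA_BARREL, CATEGORIES, MULTI_PASS, OTHER, OTHER_SINGLE_PASS, SA, TA

BACKGROUND_POOL = "GSTNQADEKP"
ANCHOR_POOL = "FWLIVMACYG"
LOOP_POOL = "GSTNQAKP"  # background minus D/E, used in doubled pairs
CPR_FILLER_POOL = "GSTNQAP"  # K/R-free so planted CPR counts are exact
STRAND_HYDRO = ("FLIM", (0.5, 0.3, 0.1, 0.1))
STRAND_POLAR = ("NQST", (0.5, 0.3, 0.1, 0.1))

MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one labelled construct. ``seed`` is mandatory."""

    category: str
    seed: int
    tp_prefix: bool = False
    rtp_suffix: bool = False
    anchor_mean_hydrophobicity: Optional[float] = None
    cpr_positives: Optional[int] = None
    n_strands: Optional[int] = None
    n_anchors: Optional[int] = None
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == SA and self.tp_prefix:
            raise ValueError("tp_prefix conflicts with SA: the N-terminus holds the anchor")
        if self.category == TA and self.rtp_suffix:
            raise ValueError("rtp_suffix conflicts with TA: the C-terminus holds the anchor")
        if self.n_strands is not None and self.category != BETA_BARREL:
            raise ValueError("n_strands is only meaningful for BETA_BARREL")
        if self.cpr_positives is not None and self.category != SA:
            raise ValueError("cpr_positives is only meaningful for SA")
        if self.n_anchors is not None and self.category != MULTI_PASS:
            raise ValueError("n_anchors is only meaningful for MULTI_PASS")


@dataclass(frozen=True)
class PlantedAnnotation:
    """Ground-truth coordinates (0-based half-open) of planted features."""

    category: str
    tp_prefix: bool
    rtp_suffix: bool
    anchors: tuple[tuple[int, int], ...] = ()
    strands: tuple[tuple[int, int], ...] = ()
    cpr_positives: int = 0
    anchor_mean: float = 0.0


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_POOL), size=n))


def _paired(rng: np.random.Generator, n: int) -> str:
    """Doubled-pair polar filler: each drawn residue written twice."""
    out = "".join(aa * 2 for aa in rng.choice(list(LOOP_POOL), size=(n + 1) // 2))
    return out[:n]


def _tp_segment(rng: np.random.Generator) -> str:
    """A 60-mer with canonical transit-peptide composition."""
    s = int(rng.integers(10, 15))
    k = int(rng.integers(7, 10))
    p = int(rng.integers(3, 5))
    counts = {"S": s, "T": 20 - s, "K": k, "P": p, "L": 3}
    rest = 60 - sum(counts.values())
    for aa in "AGNQ":
        counts[aa] = rest // 4
    counts["A"] += rest - 4 * (rest // 4)
    letters = [aa for aa, c in counts.items() for _ in range(c)]
    rng.shuffle(letters)
    return "".join(letters)


def _anchor(
    rng: np.random.Generator,
    target: float,
    config: ThresholdConfig,
    tol: float = 0.05,
) -> tuple[str, float]:
    """A 20-mer hydrophobic helix whose mean hits *target* within *tol*.

    Also requires every full sliding window inside the anchor to clear
    the detection cutoff, so the planted helix is guaranteed visible to
    the hydropathy scan.
    """
    scale = load_scale(config.scale_name)
    n = config.tmd_nominal_length
    w = config.tmd_window
    pool = list(ANCHOR_POOL)
    for _ in range(MAX_ATTEMPTS):
        seq = "".join(rng.choice(pool, size=n))
        vals = scale.of(seq)
        mean = float(vals.mean())
        if abs(mean - target) > tol:
            continue
        window_means = np.convolve(vals, np.ones(w) / w, mode="valid")
        if window_means.min() >= config.tmd_detect_cutoff + 0.01:
            return seq, mean
    raise RuntimeError(
        f"could not sample an anchor with mean {target}+-{tol} "
        f"in {MAX_ATTEMPTS} attempts"
    )


def _strand(rng: np.random.Generator, length: int, config: ThresholdConfig) -> str:
    """A strictly alternating hydrophobic/polar strand clearing the
    moment cutoff with margin."""
    scale = load_scale(config.scale_name)
    hydro, p_h = STRAND_HYDRO
    polar, p_p = STRAND_POLAR
    for _ in range(MAX_ATTEMPTS):
        seq = "".join(
            str(rng.choice(list(hydro), p=p_h))
            if i % 2 == 0
            else str(rng.choice(list(polar), p=p_p))
            for i in range(length)
        )
        if periodicity_moment(seq, scale, config.beta_angle) >= config.beta_moment_cutoff + 0.05:
            return seq
    raise RuntimeError(f"could not sample a strand of length {length}")


def _cpr(rng: np.random.Generator, positives: int, config: ThresholdConfig) -> str:
    """A K/R-free buffer after the anchor with *positives* K/R planted
    at offsets 5-12, so the planted count survives detection-boundary
    shifts of up to +5 residues."""
    length = config.cpr_window + 6
    residues = list(rng.choice(list(CPR_FILLER_POOL), size=length))
    slots = rng.choice(np.arange(5, 13), size=positives, replace=False)
    for s in slots:
        residues[int(s)] = str(rng.choice(["K", "R"]))
    return "".join(residues)


def generate_sequence(
    spec: SyntheticSpec, config: ThresholdConfig = DEFAULT_CONFIG
) -> tuple[ProteinRecord, PlantedAnnotation]:
    """Build one construct from *spec*; deterministic given (spec, config)."""
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    anchors: list[tuple[int, int]] = []
    strands: list[tuple[int, int]] = []
    anchor_mean = 0.0
    pos = 0

    def emit(chunk: str) -> None:
        nonlocal pos
        parts.append(chunk)
        pos += len(chunk)

    if spec.tp_prefix:
        emit(_tp_segment(rng))

    cat = spec.category
    if cat == SA:
        target = spec.anchor_mean_hydrophobicity
        if target is None:
            target = float(rng.uniform(0.26, 0.34))
        if not (config.tmd_detect_cutoff + 0.05 <= target <= config.ww_moderate_cutoff - 0.06):
            raise ValueError(
                f"SA anchor target {target} conflicts with the moderate band "
                f"({config.tmd_detect_cutoff}+0.05 .. {config.ww_moderate_cutoff}-0.06)"
            )
        positives = 4 if spec.cpr_positives is None else spec.cpr_positives
        lead = _bg(rng, 5)
        scale = load_scale(config.scale_name)
        w = config.tmd_window
        for _ in range(MAX_ATTEMPTS):
            anchor, anchor_mean = _anchor(rng, target, config)
            cpr = _cpr(rng, positives, config)
            # reject anchors whose hydrophobic tail drags the detected
            # segment end more than 5 residues into the CPR buffer
            vals = scale.of(lead + anchor + cpr)
            means = np.convolve(vals, np.ones(w) / w, mode="valid")
            qual = np.flatnonzero(means >= config.tmd_detect_cutoff)
            detected_end = int(qual.max()) + w if qual.size else 0
            if detected_end - (len(lead) + len(anchor)) <= 5:
                break
        else:
            raise RuntimeError("could not sample an SA anchor/CPR pair")
        emit(lead)
        anchors.append((pos, pos + len(anchor)))
        emit(anchor)
        emit(cpr)
        tail = spec.length - pos if spec.length else int(rng.integers(100, 200))
        emit(_bg(rng, max(tail, 40)))
    elif cat == TA:
        target = spec.anchor_mean_hydrophobicity or float(rng.uniform(0.30, 0.60))
        body = spec.length - 28 if spec.length else int(rng.integers(120, 220))
        emit(_bg(rng, max(body, 60)))
        anchor, anchor_mean = _anchor(rng, target, config)
        anchors.append((pos, pos + len(anchor)))
        emit(anchor)
        cts = list(rng.choice(list(CPR_FILLER_POOL), size=8))
        for s in rng.choice(np.arange(8), size=int(rng.integers(2, 5)), replace=False):
            cts[int(s)] = str(rng.choice(["K", "R"]))
        emit("".join(cts))
    elif cat == OTHER_SINGLE_PASS:
        target = spec.anchor_mean_hydrophobicity or float(rng.uniform(0.30, 0.60))
        emit(_bg(rng, int(rng.integers(50, 120))))
        anchor, anchor_mean = _anchor(rng, target, config)
        anchors.append((pos, pos + len(anchor)))
        emit(anchor)
        emit(_bg(rng, int(rng.integers(50, 150))))
    elif cat == MULTI_PASS:
        k = spec.n_anchors or int(rng.integers(2, 5))
        if k < 2:
            raise ValueError("MULTI_PASS needs at least 2 anchors")
        emit(_bg(rng, int(rng.integers(40, 60))))
        for i in range(k):
            target = spec.anchor_mean_hydrophobicity or float(rng.uniform(0.30, 0.60))
            anchor, anchor_mean = _anchor(rng, target, config)
            anchors.append((pos, pos + len(anchor)))
            emit(anchor)
            if i < k - 1:
                emit(_bg(rng, int(rng.integers(40, 60))))
        emit(_bg(rng, int(rng.integers(40, 60))))
    elif cat == BETA_BARREL:
        n = spec.n_strands if spec.n_strands is not None else int(rng.integers(8, 21))
        emit(_paired(rng, 15))
        for i in range(n):
            length = int(rng.integers(config.strand_len_min, config.strand_len_max + 1))
            strand = _strand(rng, length, config)
            strands.append((pos, pos + len(strand)))
            emit(strand)
            if i < n - 1:
                emit(_paired(rng, int(rng.choice([6, 8]))))
        emit(_paired(rng, 15))
    elif cat == OTHER:
        n = spec.length or int(rng.integers(180, 300))
        emit(_bg(rng, n))
    else:  # pragma: no cover
        raise ValueError(f"unknown category {cat!r}")

    if spec.rtp_suffix:
        emit(_tp_segment(rng)[::-1])

    seq = "".join(parts)
    record = ProteinRecord(id=f"syn_{cat}_{spec.seed}", sequence=seq, description=f"synthetic {cat}")
    annotation = PlantedAnnotation(
        category=cat,
        tp_prefix=spec.tp_prefix,
        rtp_suffix=spec.rtp_suffix,
        anchors=tuple(anchors),
        strands=tuple(strands),
        cpr_positives=spec.cpr_positives if cat == SA and spec.cpr_positives is not None else (4 if cat == SA else 0),
        anchor_mean=anchor_mean,
    )
    return record, annotation


#: per-category probability that a terminal signal is planted
_TP_PROB = {SA: 0.0, TA: 0.2, OTHER_SINGLE_PASS: 0.15, MULTI_PASS: 0.15, BETA_BARREL: 0.2, OTHER: 0.35}
_RTP_PROB = {SA: 0.2, TA: 0.0, OTHER_SINGLE_PASS: 0.15, MULTI_PASS: 0.15, BETA_BARREL: 0.15, OTHER: 0.35}


def generate_benchmark(
    n_per_category: int, seed: int, config: ThresholdConfig = DEFAULT_CONFIG
) -> tuple[list[ProteinRecord], list[PlantedAnnotation]]:
    """A labelled benchmark: *n_per_category* constructs per category.

    Within-spec parameters (lengths, anchor targets, strand counts,
    terminal-signal modifiers) are randomized per construct; terminal
    signals are planted at per-category rates, never both termini at
    once. Fully reproducible from *seed*.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    master = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    annotations: list[PlantedAnnotation] = []
    for cat in CATEGORIES:
        for i in range(n_per_category):
            child_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(child_seed)
            tp = bool(rng.random() < _TP_PROB[cat])
            rtp = (not tp) and bool(rng.random() < _RTP_PROB[cat])
            spec = SyntheticSpec(category=cat, seed=child_seed, tp_prefix=tp, rtp_suffix=rtp)
            record, annotation = generate_sequence(spec, config)
            record = ProteinRecord(
                id=f"syn_{cat}_{i:04d}",
                sequence=record.sequence,
                description=f"synthetic {cat} tp={int(tp)} rtp={int(rtp)}",
            )
            records.append(record)
            annotations.append(annotation)
    return records, annotations


TRUTH_COLUMNS = ("id", "category", "tp_prefix", "rtp_suffix", "anchor_coordinates", "n_strands")


def write_truth_table(records, annotations, path) -> None:
    """TSV of planted labels and coordinates (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for rec, ann in zip(records, annotations):
            coords = ";".join(f"{s + 1}-{e}" for s, e in ann.anchors)
            fh.write(
                f"{rec.id}\t{ann.category}\t{int(ann.tp_prefix)}\t{int(ann.rtp_suffix)}"
                f"\t{coords}\t{len(ann.strands)}\n"
            )
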