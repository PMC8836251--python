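# Methods

## Model

`comscan` treats targeting-pathway assignment for chloroplast outer
membrane (COM) proteins as a sequence of explicit physicochemical
rules rather than a learned predictor. The stages run in a fixed
order — β-barrel detection, β-barrel exclusion, α-helical TMD
detection, terminal transit-peptide detection — and feed one decision
tree:

1. a barrel candidate that survives exclusion is **BETA_BARREL**;
2. otherwise, zero detected TMDs is **OTHER**;
3. two or more TMDs is **MULTI_PASS**;
4. exactly one TMD: an N-terminal, MODERATE-hydrophobicity anchor
   followed by a positively charged region (CPR) with ≥ 3 K/R is
   **SA**; a C-terminal anchor is **TA**; anything else is
   **OTHER_SINGLE_PASS** with a conflict note naming the failed
   criterion.

Conflicts (dual terminal flags, a TA-like anchor with non-positive
CTS charge, an anchor passing both positional tests on a short chain)
are always reported in the evidence trail, never silently resolved.

### Hydrophobicity

The default residue scale is the Wimley–White water→POPC-interface
scale, stored sign-flipped so that larger = more hydrophobic. On this
convention the published 0.4 ceiling for "moderately hydrophobic"
chloroplast/mitochondrial anchor helices is an upper bound on the
19-residue windowed mean, and the MODERATE/HIGH grade of a detected
segment falls directly out of its mean value. The water→octanol scale
ships as an alternative (`scale_name = ww_octanol`); the interface
scale is the default because it is the scale used in the
signal-anchor literature the 0.4 threshold comes from. Which exact
quantity the original threshold was compared against (per-residue
windowed mean vs. summed transfer free energy; interface vs. octanol)
is not fully specified in the source literature; the choice here is
tagged DECISION in the config provenance.

### TMD detection

Windows of `tmd_window = 19` residues (nominal anchor length 20) with
mean hydrophobicity ≥ `tmd_detect_cutoff = 0.2` are merged — while
they overlap or touch — into maximal disjoint segments. The merge
means a detected segment can be longer than the planted anchor by a
few residues on either side; detection is calibrated so that the
synthetic generator's moderate anchors (target means 0.26–0.34) are
always found while its soluble background (uniform over
{G,S,T,N,Q,A,D,E,K,P}, every value non-positive on the flipped
interface scale) can never produce a qualifying window. Positional
labels: N-terminal if the segment starts before residue 40, C-terminal
if it ends within 30 residues of the C-terminus (both limits are
conventions from the SA/TA literature, exposed in config); C wins on a
tie, with a note.

### β-strands and barrels

Strand candidacy uses the 180° per-residue hydrophobic moment — the
natural statistic for the alternating lipid-facing/pore-facing
side-chain pattern of membrane β-strands. All windows of 9–11 residues
with moment ≥ `beta_moment_cutoff = 0.5` are selected greedily,
best-moment-first (ties: smaller start, then shorter window), into a
disjoint strand set; 8–24 selected strands make a barrel candidate.
The cutoff is calibrated so generator strands (strict
hydrophobic/polar alternation, F/L/I/M vs N/Q/S/T) score above ~0.55
while random soluble windows essentially never reach 0.5. The
β-signal region is annotated as the span of the two C-terminal
strands, with the mitochondrial-style "hydrophilic residue at the end
of the penultimate strand" feature reported but never used to reject
chloroplast candidates (no chloroplast β-signal consensus exists; the
known sequences are highly divergent). A candidate is *excluded* —
reverting to the α-helical rules — when a HIGH-grade TMD, or two or
more TMDs of any grade, cover more than 50% of its strand residues;
the overlap fraction is a DECISION operationalizing an otherwise
unspecified exclusion step.

### Terminal transit-peptide scoring

Canonical chloroplast transit peptides are S/T-rich, basic,
essentially devoid of acidic residues, proline-containing, and
arginine-poor (arginine richness is the mark of mitochondrial
presequences, hence the explicit R penalty). The composite score over
the first `tp_segment_len = 60` residues is

    w1·f(S,T) + w2·f(K) − w3·f(D,E) − w4·f(R) + w5·min(nP,3)/3

with default weights (1, 1, 2, 1, 0.5). A terminus is flagged when the
score reaches `tp_score_cutoff = 0.85` *and* the acidic fraction is at
most `acidic_tolerance = 0.05`; the hard acidic gate enforces the
void-of-acidic-residues rule independently of the linear trade-off.
The C-terminus is scored on the reversed last 60 residues, so the
reverse TP-like (rTP) tail implicated in TOC159-family targeting is
detected by scorer symmetry: score(record, C) = score(reversed record,
N). The cutoff was calibrated on the synthetic generator: planted
TP/rTP segments score ≥ 0.95 by construction, while unplanted termini
of anchor and barrel constructs (which can be acid-free by
construction and so pass the gate) stay below 0.85 in ≈ 99% of cases.
Flags are attached to every category independently; both flags on one
protein is permitted and reported as a conflict. The RK/ST motif
(basic + hydroxylated residue within a 6-residue window of the CTS)
and poly-glycine runs ≥ 6 are annotation only.

### Charge and pI

Net charge is the Henderson–Hasselbalch sum over side chains (D, E, C,
Y negative; K, R, H positive) with a packaged Lehninger-style pKa set;
segments are internal windows of a chain, so free termini are
excluded. Histidine (pKa 6.0) contributes to pH-dependent charge but
is *not* counted by the CPR rule, which concerns charge at
physiological pH. The isoelectric point is found by bisection on
[0, 14] to 1e-4; segments with no ionizable side chain return the
convention 7.0 with a flag, and one-signed segments (charge never
crossing zero) return the boundary pH where |charge| is smallest.

## Synthetic data

The generator emulates exactly the signal definitions the rules
encode: moderately hydrophobic 20-mer anchors with flanking charged
regions, alternating-amphiphilicity strand architectures, TP-like
terminal segments (S/T ≥ 30%, K ≥ 10%, no D/E/R, ≥ 3 P), and
featureless soluble backgrounds. Design points worth knowing:

* Anchors are rejection-sampled (cap 10 000 attempts) until the 20-mer
  mean is within ±0.05 of target *and* every interior 19-window clears
  the detection cutoff, so planted anchors are detectable by
  construction. SA constructs additionally reject anchor/CPR pairs
  whose detected segment end would extend more than 5 residues into
  the CPR buffer; planted K/R sit at offsets 5–12 of a K/R-free
  21-residue buffer, so the planted CPR count is exactly what the
  classifier sees.
* Barrel loops and flanks are emitted as doubled residue pairs
  (e.g. ``GGNNSS``), which cancels the 180° alternating sum pairwise
  and prevents accidental strands bordering planted ones; loop pools
  exclude D/E.
* Benchmark constructs (`generate_benchmark`) randomize lengths,
  anchor targets, strand counts (8–20) and terminal-signal modifiers
  per construct from a spawned per-record seed; TP and rTP are never
  planted on the same construct.

What the generator does **not** emulate: real proteome residue
statistics, homology, cleavage sites, lipid anchors, or borderline
signals (anchors straddling 0.4, TPs near the composition limits).
Passing the recovery benchmark therefore demonstrates the internal
consistency of rules and generator and the correctness of the
implementation — not predictive accuracy on real sequences, which the
source analysis itself could not validate proteome-wide.

## Numerical choices

Windowed means use exact convolution; moment profiles use a complex
convolution kernel, both checked against brute-force re-summation to
1e-9 relative tolerance. Greedy strand selection is deterministic with
a documented tie-break. Percentages are integers, rounded
half-away-from-zero (verified compatible with every published catalog
percentage, e.g. 41/138 → 30, 16/138 → 12). Sequences shorter than a
window warn and yield empty detections rather than erroring; `X`
residues get hydrophobicity 0 and are excluded from composition and
charge denominators. All randomness flows from a single user seed;
spawned child seeds stay below 2³¹.

## Problem sizes

The default validation benchmark is 84 constructs per category (504
total, sequences ~150–400 residues), which gives stable recovery
percentages (100% label recovery across tested seeds) in about a
second of compute; the oracle-equivalence checks run ≥ 1000 random
instances per primitive.

## Known limitations

* The catalog's per-protein calls are curated data; the classifier is
  a from-rules re-implementation, not a clone of the original
  tool chain, and is not expected to reproduce every catalog row from
  raw sequence.
* The catalog lists TIC236 with both an N-terminal TP and a C-terminal
  rTP flag; the accompanying narrative claims no dual-flagged protein
  exists. The package transcribes the table faithfully, so its
  both-flags count is 1.
* Strand detection is sequence-only: strand register, membrane tilt
  and 3D barrel closure are out of scope, as is any
  chloroplast-vs-mitochondrion discrimination.
* The TP scorer is a linear composite with calibrated weights, not a
  cleavage-site model; it flags composition, not processing.
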