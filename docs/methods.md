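# Methods

## The reference model and coordinate system

All numbering is anchored to *E. coli* CheY (UniProt P0AE67; the
BeF₃⁻-activated structure 1FQW), the canonical receiver domain: 129 residues
folding into (βα)₅ — a five-stranded parallel β sheet (β1–β5) flanked by five
helices (α1–α5). The five catalytic landmarks are stored as 1-based indices:
the acidic pair dd1=12/dd2=13 at the C-terminal end of β1, the
phosphorylatable Asp d=57 at the end of β3, Thr t=87 at the end of β4 and
Lys k=109 within β5. All landmark-relative offsets for the DD pair anchor on
**dd2**; with that convention DD+17 (residue 30) falls in the α1β2 loop,
D+4 (Pro61) in the β3α3 loop and D+8 (Gly65) at the start of α3, matching
the structural roles those positions are known for.

The secondary-structure intervals shipped in
`src/recprofiler/data/chey_elements.tsv` are an approximate 1FQW-based
assignment. Published DSSP boundaries vary by a residue or two between
structures; the packaged intervals were fixed once so that each landmark sits
at its expected strand position. Users can substitute their own model
directory (`--reference`); small boundary shifts move individual residues
between "loop" and "element" and therefore slightly shift loop-delta
attribution, which is the main reason the intervals are data, not code.

The β-strand heuristic (`detect_hydrophobic_strands`, runs of ≥4 consecutive
residues from {A,V,I,L,M,F,W,C}) is a locator, not a predictor: on CheY it
recovers β1 (8–11) and β4 (83–86) plus a helical run in α4 (95–99), while β2
contains no hydrophobic run at all and β3's run is only three long. It is
exposed because it is a useful quick check on candidate sequences, with the
run length and residue set configurable; it plays no role in the pipeline's
landmark assignment.

## Alignment and landmark assignment

Queries are pre-excised receiver domains, so alignment is global
(end-to-end), BLOSUM62, affine gaps: a gap of length L costs
`open + (L−1)·extend` with open 11 and extend 1. Terminal gaps are charged at
half weight (5.5 / 0.5) — enough to tolerate ragged domain boundaries without
letting the alignment float. `X` scores 0 against everything and never
satisfies a landmark class. The alignment itself is delegated to
Biopython's `PairwiseAligner`; among co-optimal alignments the aligner's
first traceback is used, which is deterministic for fixed inputs, so all
outputs are bit-stable. The test suite cross-checks scores against an
independent, pure-Python Gotoh dynamic program written directly from the
recurrence (`tests/helpers_oracle.py`).

Landmark assignment reads the query residue aligned to each reference
landmark column. Expected classes: DD requires both residues acidic (D/E —
Asp-Asp and Glu-Asp pairs both support metal binding), D strictly Asp, T
Ser or Thr, K strictly Lys. A domain missing any class is **atypical**
(a pseudo-receiver domain). A per-landmark confidence flag reports
`anchored` (no gap within two alignment columns), `shifted` (a nearby gap
may have displaced the landmark) or `absent` (landmark column gapped).

Named positions are resolved in the query's own residue coordinates
(anchor index + offset), not in alignment columns. This keeps names such as
DD+17 well-defined across insertions N-terminal of the anchor, and means an
insertion landing between K and the expected K−3 location shifts which
residue is called K−3 — the intended behavior of the convention.

## Frequency matrices, display filter and bins

Per type × named position, the frequency matrix reports the fraction of
domains carrying each residue. Domains whose anchor is missing at a position
are tallied under an explicit missing category, keeping every denominator
equal to the type's record count (fractions sum to 1 per cell); a
`drop_missing` switch restores defined-only denominators. The DD pair is
tallied as an ordered two-letter category ("DD", "ED", …).

For display, a residue is retained at a position iff at least one type shows
it at ≥20% there; the missing category is never displayed. Retained cells
get a color bin: 0% → ZERO, 100% → FULL, otherwise quintiles on half-open
intervals ((0,0.2] → Q1 … (0.8,1.0) → Q5). Heatmap rows are ordered response
regulators, then HHKs, then Unclassified, each sorted by decreasing
Glu-Asp ("ED") fraction at DD with alphabetical tie-break; columns follow
N→C order of the positions in reference coordinates. D+2/T+2 pair tables
rank complete pairs only (domains missing either member leave the
denominator), ties broken lexicographically.

## Element and loop deltas; insertion calls

Each reference interval (element, loop, terminal tail) receives the count of
query residues mapped to it; the delta versus the reference length is the
net measure, so a 12-insertion plus 2-deletion in one loop reads +10.
Insertion runs (query residues aligned to reference gaps) are attributed to
the interval containing the reference position immediately preceding the
run; runs before the first reference column go to the N-terminal tail. One
amendment handles alignment jitter: when the preceding position falls inside
a secondary-structure element, the run is reattached to the nearer flanking
loop/tail. The (βα)₅ elements are fixed-length structural cores — an
insertion "inside" β4 is an artifact of the gap opening a column or two past
the loop boundary, not biology. With this rule, planted per-loop insertion
lengths are recovered exactly in 1000/1000 stress trials at 15% background
substitution.

Loop insertions are flagged at delta ≥ 10 residues (inclusive) in the α2β3
and α3β4 loops by default; the flagged segments' Pro and Ser fractions are
reported as the intrinsic-disorder proxy. No disorder predictor is used.

## Summary statistics

All census statistics are plain descriptive fractions over the
characteristics table and are order-invariant. Conventions worth noting:
the atypical rate excludes the two Rim15 types by default (the Ascomycota
Rim15 signature replaces the phosphorylation-site Asp with Glu by design;
a flag restores inclusion); "lacking Ser/Thr at D+10" counts an undefined
D+10 as lacking; the Unclassified share of response regulators uses all
RR-category domains (named types plus Unclassified) as denominator; the
Ssk1 insert statistics are the mean and sample SD (ddof=1) of the α3β4
delta; TM percentages exclude records without a TM annotation from the
denominator, with a warning. Reported percentages are rounded to whole
points; full precision is kept in the tables.

## Synthetic data

The generator starts from the CheY scaffold and, per record: applies
background substitutions at a configurable rate outside the landmarks and
named key positions, drawing replacements from each residue's three
highest-scoring BLOSUM62 neighbors (keeping mutated sequences alignable);
samples planted residues at profiled named positions; optionally degrades
landmarks to non-class residues (a scalar rate degrades one uniformly chosen
landmark per affected record, so the atypical fraction estimates the planted
rate directly; a dict applies independent per-landmark probabilities);
optionally shortens α4 (the Rim15 signature); and splices loop insertions —
Bernoulli occurrence, rounded-normal length truncated at a minimum (and
optional maximum), composition sampled with configurable Pro/Ser weights
(default 0.3/0.3, remainder uniform). Insertions splice at the loop
midpoint. Ground truth records every choice, including the true landmark
indices after all indels. All sampling flows through one seeded
`numpy` generator; fixed seed ⇒ byte-identical output files.

The census-scale bundle (`paper_like_specs`) fixes the study conditions:
670 domains from 51 species across 9 phyla — Skn7 50, Ssk1 50, Rim15 50
(35 Ascomycota + 15 non-Ascomycota), Srr1 38, Unclassified 50, and 432 HHK
domains across 20 types. Its rates are the quantities the analysis is meant
to recover: Skn7 Cys at DD+17 with p=0.98 and Ser/Thr at D+10 with p=0.91;
Ssk1 α3β4 insertions always present, N(38, 16) truncated at 10, Pro/Ser
0.3/0.3; Srr1 K−3 Thr always, K−4 aromatic/His at 0.74; per-group HHK
insertion probabilities of 0.85 (groups VII, VIII, XI, XV), 0.47 (I, II,
XII-Rec2, XIII, XIV, XVIII) and 0 elsewhere, pooling to 31%; TM probability
0.5 in groups VI, XIII, XVI–XIX, pooling to 15%; group XII single-domain
probability 0.26; landmark degradation 0.27 for Unclassified and 0.01 for
other non-Rim15 types, giving a ≈3% non-Rim15 atypical rate; and a fixed
Unclassified species allocation under which 24% of Ascomycota+Basidiomycota
species versus 64% of other-phyla species carry at least one Unclassified
domain, with two hotspot species holding 36% of them.

What the generator does **not** emulate: phylogenetic covariance between
sequences (records are i.i.d. given their type), HHK regions outside the
receiver domain, genuinely divergent non-CheY-like folds, sequencing errors
beyond `X`, and correlated residue choices across positions. Passing the
recovery tests therefore shows the pipeline is correct under the stated
noise model, not that pairwise alignment matches a curated MSA on deeply
divergent natural sequences — near-degenerate real domains can plausibly be
assigned differently by the two approaches.

## Problem sizes and numerical conventions

The test suite exercises 500-domain datasets for landmark and frequency
recovery (3-binomial-SE bounds) and 25–120-domain sets for insertion
fidelity. `scripts/acceptance.py` runs the full 670-domain census ten times
with distinct sub-seeds and averages the percentage statistics: the fixed
per-type denominators (e.g. 38 Srr1 domains) make a single census a visibly
noisy binomial draw, and averaging reports the expected rates while leaving
every generation parameter untouched. Exact counts (670, 51) are invariant
across replicates. Floats are written at 4 decimals, missing values as
`NA`; all orderings and tie-breaks are fixed, so identical inputs and seeds
yield byte-identical outputs end to end.
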