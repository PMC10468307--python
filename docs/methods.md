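# Methods

`paleogene` dates the emergence of genes on a dated species phylogeny from
alignment-based presence/absence evidence and relates the resulting emergence
times to local warming periods in a paleotemperature record. This note
documents the model, its parameters, the synthetic data generator, and the
numerical and design choices the implementation makes where the procedure is
genuinely open.

## The dating model

**Inputs.** A rooted ultrametric timetree with node heights in millions of
years ago (MYA), tabular protein-vs-CDS alignment hits (TBLASTN-style:
protein queries, nucleotide subject coordinates), and an irregularly sampled
global surface temperature series Ts(t) over the same time span.

**Presence calling.** A gene g is *detected* in species s iff at least one
hit (g → any CDS of s) has percent identity ≥ `min_identity` (default 80%)
and subject coverage ≥ `min_subject_coverage` (default 80%), where coverage
is (|send − sstart| + 1) / slen on the nucleotide subject. Both thresholds
are inclusive, the common convention for BLAST post-filters. No HSP chaining
or merging is attempted: one sufficient HSP is evidence of presence, and
basic local alignment output does not support sliced alignment anyway.
Detection is collapsed to a per-species boolean; multiple isoform hits count
once, which is the only granularity the downstream steps use.

**Clade status.** Every node of the tree defines a clade. For each gene and
clade with n species of which k are detected:

- *existent* iff k/n > f,
- *absent* iff (n − k)/n > f,
- *unknown* otherwise,

with majority fraction f = 0.8, strict inequality, configurable in
[0.5, 1). The strictness matters at small n: a 4-of-5 clade is unknown
(0.8 ≯ 0.8), so clades of ≤ 5 species are existent only when unanimous and
absent (at n = 5) only when empty. The >-majority rather than all-or-none
rule absorbs sporadic detection failures in individual genomes. Presence is
treated as a reversible character (Wagner-style): loss and re-gain patterns
produce ordinary contrasts and are never suppressed, in contrast to a
Dollo-style single-origin constraint.

**Emergence node.** Candidate nodes are the internal nodes with at least one
unordered child pair in which one child clade is existent and the other
absent; pairs involving an unknown status contribute nothing (no
imputation). At polytomies all child pairs are examined and a node
contributes at most one candidate. The gene's emergence is dated at the
**maximum-age** (earliest) candidate; equal-age ties go to the candidate
whose clade ordering key (descending age, then lexicographically smallest
member taxon) is smallest, so output is deterministic. A gene with no
candidate is classified *pre_root* if existent at the root clade (it
predates the tree), *undetected* if detected nowhere, and *no_signal*
otherwise.

**Known bias: emergence ages are never too young, sometimes too old.** The
earliest-candidate rule guarantees the dated age dominates every alternative
reading, and with the strict majority rule it creates a systematic upward
bias: if a gene's true clade covers more than 80% of a larger enclosing
clade (e.g. 5 of 6, or 11 of 12 species), the enclosing clade is also
existent and its parent becomes an older candidate which the rule then
prefers. On noiseless synthetic histories at the default scale this
relocates up to roughly 8% of dated genes (seed-dependent) one or more nodes
rootward of the branch that actually gained the gene, while the dated age is
≥ the true gain age for 100% of genes. This is an intrinsic property of the
majority + earliest-time method, not an implementation artifact — the
acceptance script reports the measured node accuracy
(`recovery_node_accuracy_pct`) rather than asserting it away.

## Warming-period detection

A *local warming period* (LWP) is operationalized as a maximal rising
segment of the (optionally smoothed) series, scanning from the oldest sample
toward the present: from a local minimum to the following local maximum,
emitted iff

- net rise > `min_delta_t` (default 0.5 °C, strict), and
- duration ≥ `min_duration` (default 0.25 MY, inclusive, with 1e-9 MY float
  slop).

The 0.5 °C criterion is read as *net rise over the rising segment* —
alternatives (peak-to-trough, deviation from trend) are not silently
substituted; the segmentation parameters are all exposed in `LwpConfig` so
sensitivity can be probed. Additional knobs, both off by default so the
irregular sampling of real compilations is honored unchanged:

- `smoothing_window` (MY): centered moving median over that time span,
  robust against single-sample spikes;
- `dip_tolerance` (°C): interior dips no deeper than this are bridged, so
  one noisy sample does not split a sustained rise. At tolerance 0 only
  exact plateaus are bridged.

Runs are built from strictly increasing steps so that flat stretches never
inflate a segment's duration: a rise that follows a plateau starts at the
last plateau sample (the local minimum nearest the rise). Detected intervals
are pairwise disjoint, ordered oldest first, and carry inclusive boundaries;
point ages and [min, max] age ranges can both be classified against them.

## Association summaries

Emergence counts are histogrammed on node ages themselves — markers sit at
divergence times, no arbitrary binning — and reduced to: counts inside
analysis windows (defaults: the recent 10 and 13 MY), inside/outside-LWP
tallies (by point age, or by age-range overlap when ranges are available),
and top-k peak nodes per gene set with ties broken toward the older age.
Gene sets (conventionally `de_novo`, `cancer`, `random`) may not share genes
unless explicitly allowed, mirroring study designs whose control sets are
drawn disjoint. No significance test is attached to the in/out-LWP
comparison; the package reports counts.

## Synthetic data generator

The generator produces every input with known ground truth, at a default
scale mirroring the study conditions: 32 species, root at 74 MYA, 145 query
genes (labelled 45 de novo + 100 cancer), and a 66-MY temperature span.

- **Trees**: Yule (pure-birth) topologies with node times rescaled so the
  root sits at the requested age; leaves at 0.
- **Gene histories**: exactly one gain per gene (a single dated emergence
  has no unique truth under multiple independent gains), placed uniformly
  over total branch length — the location of one homogeneous Poisson event
  conditioned on a single occurrence, so branch choice is proportional to
  branch duration. Losses thin the gained subtree with per-MY rate
  `loss_rate` (first-event per branch; lost lineages stay lost to keep the
  truth identifiable). The recorded truth is the gain branch's parent node
  and the gain age.
- **Hit tables**: true-present cells emit a passing hit with probability
  1 − `fn_rate` (identity and coverage drawn from clipped normals above the
  thresholds), otherwise a sub-threshold hit; true-absent cells emit a
  passing hit with probability `fp_rate` and otherwise a sub-threshold decoy
  with probability `decoy_rate` (default 0.1), so filter sweeps have
  non-trivial material on both sides of 80/80. About half the hits are
  written minus-strand. With fp = fn = 0 the filter reconstructs the input
  matrix exactly.
- **Temperature**: a linear cooling trend (defaults 26 → 14 °C over 66 MY,
  the order of magnitude of Cenozoic surface cooling) plus injected
  excursions and optional Gaussian noise, sampled with density
  ∝ (age + ε)^(−`density_power`) so spacing tightens toward the present as
  in real proxy compilations. `ExcursionSpec.duration` is the duration of
  the **rising limb**: the bump climbs from age center + duration to its
  peak at center and decays symmetrically, because the detector's duration
  threshold is measured on rises. Limb endpoints and peak are always
  included among the samples so no excursion can fall between points; the
  returned truth is the set of limbs qualifying under the active
  `LwpConfig`, with the net rise corrected for the trend slope.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no sequence-level simulation (alignment identity
is drawn, not computed from evolved sequences), no isotope-proxy noise
structure (noise is white Gaussian), no correlation between gene gain and
temperature (unless planted explicitly), no multiple independent gains, and
no tree-inference uncertainty (the tree is known). Recovery results
therefore validate the pipeline's logic, not the upstream detection power of
any alignment tool.

## Numerical choices

- Ultrametricity tolerance on newick input: 1e-6 MY spread across tip
  depths, configurable; violating trees are rejected rather than corrected.
- Newick round-trips preserve node ages to < 1e-9 MY (branch lengths written
  with 12 significant digits).
- Duplicate ages in temperature input are collapsed by the mean; rows may be
  in either orientation and are sorted oldest first.
- The grafting operation inserts the new node on the sister's pendant edge
  and requires 0 < age < parent age strictly; all other node ages are
  untouched.
- All tie-breaks (clade enumeration, candidate ordering, peak ranking) are
  deterministic and documented above; reruns with one seed are
  byte-identical on every TSV artifact.
- Randomness is funneled through explicit integer seeds; sub-generators are
  derived with `numpy.random.SeedSequence`.

## Problem sizes used by the test and acceptance runs

Tests run at the defaults the generator mirrors from the study — 32 species,
145 genes, 66-MY series (~400 samples) — with smaller trees (n ≤ 12–16) for
the brute-force oracle comparisons, 200 random trees for the candidate-scan
equivalence, and 50 hit tables for the filter monotonicity sweep. These
sizes keep every oracle exhaustive while exercising the full pipeline at the
study's own scale.

## Limitations

- The dating resolution is the node set of the input tree; genes emerging
  on a branch are assigned the branch's older endpoint at best, and the
  majority-rule propagation can push them further rootward (see the bias
  note above).
- The LWP definition names only a magnitude and a duration; the
  extrema-to-extrema segmentation here is one reasonable operationalization
  and is parameterized rather than canonical.
- Nodes with recognized taxonomic names are flagged (their labels are
  carried through) but not weighted: no numerical reliability scheme is
  attached to named vs unnamed divergences.
- Upstream steps — running the alignment search, converting isotope proxies
  to surface temperature, curating gene lists — are out of scope; the
  package consumes their tabular outputs.
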