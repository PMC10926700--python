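# Methods

## Overview

spikequant implements spike-in calibration for quantitative mNGS as four
cooperating pieces: a panel designer, a ground-truth simulator, a
read classifier, and the quantification/evaluation core. This note
records the model, its assumptions, the defaults and why they were
chosen, and what the synthetic experiments do and do not demonstrate.

## Panel design

**Constraints.** Inserts are 1000 bp; the PCR-amplifiable core (the
"amplicon") is the insert minus a fixed 15-bp primer flank on each side,
i.e. 970 bp. Both insert and amplicon must have GC in [0.35, 0.70] and
no homopolymer run longer than 3. Specificity is enforced exactly: no
50-mer of an accepted insert (either strand, stride 1) may occur in the
user-supplied screening references or in any previously accepted
molecule. Exact k-mer screening replaces a database-wide homology
search; it is deterministic, has no network dependence, and its
guarantee (zero shared 50-mers) is directly testable. The zero-shared-
50-mer rule is this package's operationalisation of "minimal homology";
a remote-database cutoff would be neither reproducible nor testable
offline.

**Candidate generation.** Bases are drawn i.i.d. uniform; positions that
extend a homopolymer run beyond 3 are iteratively redrawn uniformly from
the other three bases until no violation remains. A pure
accept/reject loop over whole sequences would be astronomically slow for
the run constraint — a random 1000-mer contains ≈ 1000/4³ ≈ 15.6
runs of length ≥ 4 in expectation, so whole-sequence acceptance is
≈ e⁻¹⁵'⁶ — while the GC window alone accepts > 99 % of 1000-bp
candidates and stays a plain rejection step. Local resampling keeps the
marginal base composition uniform.

**Gradient assignment.** Accepted molecules are assigned to the 5
gradient levels round-robin in acceptance order. Molecules are
exchangeable by construction, so any assignment rule is equivalent; the
round-robin is deterministic and keeps level membership balanced at
every prefix.

**Failure mode.** The designer tracks rejection reasons and, if the
panel is not filled within the attempt budget (default 200 × panel
size), raises an error naming the binding constraint (e.g. `gc_content`
for an unsatisfiable GC window).

## Simulator

**Count model.** Reads are proportional to *mass* fraction, not copy
fraction: shotgun sequencing samples nucleotides, so a genome's read
share scales with copies × genome length. This is exactly the assumption
under which the IS mass law holds with a single constant. Per-category
expected fractions are recovery-weighted masses over their total; counts
are drawn multinomially at fixed total depth (matching a fixed per-run
data amount), with independent-Poisson, exact-expectation
(`expected`, real-valued, noise off) and largest-remainder
(`expected_rounded`) modes as options. Fragment-length and GC biases are
deliberately not modelled; the calibration model assumes their absence,
and the simulator defines the regime in which the model is exact.

**IS masses.** Each molecule contributes concentration × spike volume
(default 2 µL) of mass; a gradient level's total input C_is is the sum
over its three molecules (the `per_molecule` convention, so
C_is = 3 · conc · volume = 1.2, 0.12, … ng at 2 µL). Whether a printed
gradient concentration refers to each molecule or to the pooled level is
genuinely ambiguous in assay descriptions of this kind; the alternative
`pool` convention (C_is = conc · volume) is a configuration switch and
rescales every inferred mass and copy number by exactly the number of
molecules per level (3). The switch is surfaced rather than silently
absorbed because the two conventions are indistinguishable from
sequencing data alone.

**Recovery efficiencies.** A per-category (or per-category-type)
recovery factor in (0, 1] multiplies the effective mass. Depressing IS
recovery alone by a factor *e* inflates every downstream copy estimate
by exactly 1/*e* (verified by test) — the mechanism by which spiking
before nucleic-acid extraction corrupts calibration.

**Presets.** `mock10` is a ten-organism bacterial mock community with
true copies log-spaced over 10–10⁶ and typical genome lengths
(1.9–6.3 Mbp); the commercial material it emulates does not publish
per-species copies, so these are configurable stand-ins. `low_host` and
`high_host` mix that community at 1.1 ng and 0.01 ng total microbial
mass under 5.5 ng and 5.0 ng of host DNA respectively — the stated
bench compositions for the low/high host-background experiments.
`clinical_like` is a CSF-like specimen: 10 ng host plus four pathogens
at modest load, host ≥ 95 % of specimen DNA. Note that under the
mass-proportional model the `high_host` preset yields a host *read*
fraction of ≈ 79 %, not ≥ 85 %: its stated composition contains less
total DNA than the low-host mixture, so the IS (fixed mass) takes a
larger share. The composition masses, being the controlled inputs, are
treated as the defining conditions.

**Read level.** `simulate_reads` realises a count table as single-end
FASTQ (default 75 nt): uniform start positions, either strand,
i.i.d. substitution errors, true category recorded in each header as a
classification oracle. Fixture genomes are random sequences screened to
share no 50-mer with the panel; they are deliberately much shorter than
the real genomes they stand for (default 20 kb) because read
classification depends only on sequence content, while the quantifier
uses the *nominal* genome length — the two are decoupled by design.

## Read classification

A k-mer index (default k = 25, both strands) maps each k-mer to its
unique source or flags it ambiguous. k = 25 gives three non-overlapping
k-mers per 75-nt read — specific at this scale and tolerant of a single
substitution. Classification is host-first: any k-mer mapping uniquely
to a host source assigns the read to host, mirroring the
filter-host-then-annotate order of production pipelines; otherwise
unique-mapping k-mers vote and ties or no-hits fall to `unassigned`
(no fractional assignment — near-identical references should surface as
ambiguity, not be split arbitrarily). On error-free reads from mutually
50-mer-disjoint references, classification is exact (tested against the
header oracle). Count tables from an external pipeline can be ingested
from TSV with full validation instead.

## Quantification

The IS curve is fitted by ordinary least squares of log10 R_is on
log10 C_is. Log-log space is the default because the ladder spans four
orders of magnitude: a linear-space fit would be dominated entirely by
the top gradient (linear space is available as an option). Zero-read
levels are dropped with a warning rather than pseudo-counted —
pseudo-counts bias the intercept; fewer than two usable levels, or
reads constant across levels, abort loudly. r² is the squared Pearson
correlation of the fitted variables.

Inversion is `curve` mode (through the fitted line) by default, with
`ratio` mode (pooled Σ C_is / Σ R_is) as an option; the two coincide
exactly when the fit is a perfect slope-1 line. Copies follow from
COPY = C / (L · DNA_c) with DNA_c = 650 g·mol⁻¹·bp⁻¹ / N_A =
1.0794 × 10⁻¹² ng/bp (configurable). Taxa under the minimum-read
threshold (default 3) are reported but flagged `low_evidence`; a missing
genome length produces a per-taxon error entry, never a global abort.

With sampling noise off the whole chain is an identity: simulate →
count → quantify recovers true copies to float precision, which is the
package's core correctness oracle. Estimates are depth-invariant in
expectation and invariant to the IS spike amount (more IS depresses
microbial reads and shifts the intercept by the same factor).

## Evaluation

**Depth sweep.** Replicate subsamples are drawn *without replacement*
(multivariate hypergeometric) from one deep count table, matching what
`seqkit sample` does to real read sets; the difference from binomial
sampling is material when the target depth approaches the source total.
Defaults follow the standard protocol: depths 1, 5, 20, 35, 50 M reads,
20 replicates each, the source being a 180 M-read run. Stability is
summarised per adjacent gradient pair as CV% (sample s.d./mean × 100) of
the read ratio R_is(n)/R_is(n−1) across replicates; pairs with a zero
denominator are flagged undefined. Under the simulator the CV of every
pair scales ≈ depth⁻⁰·⁵ with a finite-population correction — with a
180 M source the fitted log-CV/log-depth slope is ≈ −0.53 to −0.55;
a much shallower source steepens it, so the source total is part of the
protocol, not a free parameter.

**Reference comparison.** Estimates are compared with reference copies
as the pooled Pearson correlation of log10 copies over all
(taxon, replicate) pairs, plus a per-taxon two-sided one-sample t-test
of replicate log10 estimates against the log10 reference, flagged at
P < 0.05 and P < 0.01. Exact matches short-circuit to r = 1, P = 1
(zero-variance inputs are otherwise undefined); non-positive estimates
are excluded from the log scale with a warning. A Welch two-sample test
is the natural extension when reference replicates exist but is out of
scope here.

## Pipeline and reproducibility

One YAML config drives stages `design → simulate → count → quantify →
evaluate`. All configuration and stage inputs are validated before any
file is written, so validation failures never leave partial outputs.
Every artifact has a JSON provenance sidecar (stage, parameters, inputs,
derived seed, package version). Randomness flows from a single global
seed via `SeedSequence([seed, stage_index])`, so any stage rerun in
isolation is byte-reproducible. Exit codes: 0 success, 2 validation
error, 1 runtime failure.

## Problem sizes

The test suite and acceptance script run at count-level depth (20 M–180 M
reads) where simulation is a cheap multinomial draw, and at small read
level (thousands of reads over kb-scale fixtures) where per-read
classification is exercised end to end. The survey used for the pooled
correlation is 36 samples × 2–4 taxa (E ≈ 83 detected fragments), with
per-sample taxon counts drawn (2, 3, 4) with probabilities
(0.75, 0.20, 0.05).

## Known limitations

- No fragment-length, GC or PCR bias; no quality profiles, adapters,
  duplicates or paired ends. Passing tests demonstrate correctness of
  the calibration algebra and its sampling behaviour, not robustness to
  real-library artefacts.
- Exact k-mer classification has no tolerance for indels and no
  lowest-common-ancestor logic; it stands in for an aligner plus
  taxonomic annotation at desk scale.
- Fixture genomes are random sequences; they carry none of the repeat
  structure or inter-species similarity that makes real read assignment
  hard.
- Copies are genome copies, not colony-forming units; no clinical
  interpretation thresholds are provided.
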