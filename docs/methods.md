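# Methods

This note documents the models, parameter choices and known limitations of
the genome-reduction toolkit.

## Sequence comparison

Protein pairs are compared by exact Smith–Waterman local alignment under
affine gap costs: a gap of length *k* costs `gap_open + k·gap_extend`
(defaults 11/1) with BLOSUM62 substitution scores.  Raw scores *S* are
converted to bit scores with gapped Karlin–Altschul statistics,
`S' = (λS − ln K)/ln 2` with λ = 0.267 and K = 0.041, and E-values are
`E = m·n·2^(−S')` over the plain product search space (no edge correction;
E-values are only thresholded, never reported as significances).

The backend is Biopython's `PairwiseAligner`; the test suite checks it
against an independently written Gotoh dynamic program on exhaustive small
cases, so the scoring convention cannot silently drift.  Precomputed hit
tables in 12-column tabular format are accepted as an alternative input, so
an external BLASTP run can substitute for the built-in aligner on large
genomes.

## Gene classification

*Conservation* follows in-silico subtractive hybridization: for the best
reference hit of each query, the homology value is

    H = (identity / 100) · min(1, aln_len / qlen),

and the gene is conserved iff H ≥ 0.42 and E < 1e-5.  Coverage is measured
on the query by default (switchable to the subject).

*Essentiality* is a consensus vote over 15 essential-gene panels: a panel
votes for a gene iff its best hit has ≥ 35 % identity and E ≤ 1e-10, and a
gene is called essential iff it collects at least 8 votes.  The vote
histogram is exported for inspection; genes without a protein product never
collect votes.

## Deletion-region selection

Candidates are maximal runs of consecutive strain-specific, non-essential
genes.  A run qualifies when its snapped span is ≥ 15 kb and it contains
≥ 11 genes; curated cluster definitions (e.g. known secondary-metabolite
operons) bypass the size filters but never the no-essential-gene rule, which
is a hard error rather than a silent drop.  Endpoints are snapped to the
midpoint of the flanking intergenic gaps; if a neighboring gene overlaps the
terminal gene, the endpoint retracts to the neighbor's boundary, so a
deletion never cuts a retained gene.  Accepted regions are ordered
secondary-metabolite clusters first, then metabolism/transport, then
hypothetical, and by genomic position within a class.

## Deletion ledger

Deletions are applied sequentially.  Cumulative percentages are computed as
exact decimals of the parent genome length and rounded half-up to two
decimals, which is what reproduces every cell of the published 22-step
series (floating-point round-half-even does not).  Coordinate liftover maps
parent positions onto the reduced genome and returns an explicit `Deleted`
marker, naming the region, for positions inside a deletion.

## Construct design

Markerless (suicide-vector) deletion constructs consist of two homology arms
(400–800 bp, target 600 bp) abutting the deletion endpoints.  Primers:

- F1/R2 carry restriction-site tags; the two enzymes are the first in a
  fixed preference order (EcoRI, BamHI, HindIII, PstI, SalI, XbaI) whose
  sites are absent from the joined insert, both strands.
- R1/F2 form the junction: F2 carries a 5' tail equal to the last 18–20 nt
  of the upstream arm, so overlap-extension PCR fuses the arms scarlessly.
  The simulated assembly is checked to be exactly the concatenated arms.
- NF/NR amplify a 300–600 bp product strictly inside the deleted interval,
  so a successful deletion abolishes the product; the design search slides
  their positions until both primers are Tm-feasible.

Annealing lengths are fit greedily from 20 nt outward within 18–30 nt so
the melting temperature lands in 55–65 °C.  Because the annealing ends of
the four arm primers are pinned (junction primers to the deletion endpoint,
outer primers to the arm terminus), an in-window length need not exist for
extreme base compositions; in that case the design falls back to the length
whose Tm is closest to the window rather than failing, and the reported Tm
makes the compromise visible.

Melting temperatures use nearest-neighbor thermodynamics with the unified
parameter set, the `0.368·(N−1)·ln[Na+]` entropic salt correction at
50 mM Na⁺, and a CT/4 concentration term at 500 nM strand concentration;
sequences under 14 nt fall back to the Wallace rule.  The implementation is
cross-checked against Biopython's `Tm_NN` under identical conventions.

## Fermentation kinetics

Over a production window [t₁, t₂] (default 14–24 h):

- specific growth rate μ = ln(X₂/X₁)/(t₂−t₁);
- molar specific production rate q = ΔC/M/(X̄·Δt) in mmol·g⁻¹·h⁻¹, with
  ΔC in mg/L and M the analyte's molar mass (PCA 224.22, 2-OH-PCA 240.21,
  2-OH-PHZ 196.20 g/mol);
- mass-basis total rate Σ qᵢ·Mᵢ/1000 in g·g⁻¹·h⁻¹, reported to two
  significant figures (half-up), which is the right way to pool phenazines
  of different molecular weight.

X̄ is the logarithmic mean of the endpoint biomasses by default.  The log
mean is the exact time-average of exponentially growing biomass, which
makes the estimator recover planted parameters exactly on noise-free
simulated courses; the arithmetic endpoint mean (available via a flag)
overestimates the average biomass by ~11 % over a 10 h window at
μ ≈ 0.12 h⁻¹ and biases q low by the same factor.

## Synthetic validation data

The genome-pair generator plants known truth: lognormal gene lengths
(median 900 bp), a configurable conserved fraction whose reference copies
are mutated to ~80 % identity, essential genes planted into 10 of 15 panels
at ~60 % identity, and deletable regions as runs of strain-specific,
non-essential genes with conserved guard genes at both flanks.  Background
runs of strain-specific genes are capped below the qualifying run length so
region recovery has a unique right answer.  The fermentation simulator
draws from closed-form solutions of the growth-coupled production ODEs
(including first-order PCA → 2-OH-PCA → 2-OH-PHZ conversion), verified
against a Runge–Kutta integrator, with optional mean-unbiased lognormal
measurement noise.

## Limitations

- The aligner is exact but O(mn) per pair; genome-scale runs should supply
  precomputed hit tables from a heuristic search instead.
- E-value statistics use fixed gapped-BLOSUM62 (λ, K) without edge or
  length corrections, adequate for thresholding only.
- Essentiality is inferred by homology consensus, not by experiment;
  conditionally essential genes under fermentation conditions are out of
  scope.
- Primer design considers Tm, overlap and site content but not secondary
  structure, primer-dimer formation or off-target annealing elsewhere in
  the genome.
- The kinetic model treats μ and q as constant over the analysis window;
  it does not model substrate limitation, product inhibition, or the
  stationary phase.
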