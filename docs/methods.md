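# Methods

This note records the models, parameter choices and numerical conventions
behind `panscreen`, and what the synthetic benchmarks do and do not
demonstrate about real campaign data.

## Panning selection model

A panning round is modeled as weighted multinomial resampling. Clone $i$
with count $n_i$ and dissociation constant $K_{D,i}$ receives selection
weight

$$w_i = n_i\left[\frac{C}{C + K_{D,i}} + r_\text{wash}\right]$$

at free antigen concentration $C$ (molar), and the next round's counts are
a multinomial draw of `reads_per_round` with probabilities $w_i/\sum_j w_j$.
The first term is equilibrium Langmuir occupancy — the simplest physically
grounded expression of "higher-affinity clones survive lower antigen" —
and $r_\text{wash} \in (0,1]$ is the probability of non-specific retention
through the washes. The model deliberately omits avidity, expression bias,
phage display level and PCR amplification bias; it is a selection-pressure
model, not a phage-biology model.

Defaults (the simulated study conditions): 4 rounds; $C$ = 100, 50, 25,
10 nM; $r_\text{wash}$ geometric from $10^{-2}$ to $10^{-4}$; 50,000 reads
per round for benchmark campaigns. These produce clearly visible enrichment
at desktop scale while leaving round-3/round-4 frequencies close enough
that ranking is a meaningful test.

## Library generator and ground truth

The library is combinatorial over a fixed scaffold: humanized FR1/FR3/FR4
with a camelid FR2 (the standard stabilization choice for heavy-chain-only
domains), with CDR1/CDR2 pools of 24 variants (8 aa each) and a CDR3 pool
of 120 variants (12–16 aa). Nucleotide sequences use one fixed codon per
residue, chosen to avoid creating liability motifs at codon junctions.

Two couplings give the simulation its testable truth:

* **Affinity–sequence coupling.** 10% of the CDR3 pool carries a fixed
  4-mer affinity motif (`HRHW`); a clone is a true binder iff its CDR3
  comes from that sub-pool. Binder $K_D$ is log-uniform in 0.1–10 nM,
  background clones log-uniform in 1–100 µM (binder cutoff 100 nM). The
  motif's histidines are excluded from the rest of the CDR alphabet, so
  binder status is recoverable both by composition descriptors (KNN route)
  and by motif detection (convolutional route). This emulates convergent
  selection onto a paratope chemistry; real campaigns are messier, so
  classifier scores here are upper bounds on real-data performance, and the
  benchmark's contract is *recovery of a planted signal*, not a
  performance claim about any particular campaign.
* **Liability coupling.** A configurable fraction of clones receives
  exactly one planted liability motif inside CDR2 (deamidation `NG`,
  isomerization `DG`, sequon `NAS`, a lone cysteine, or a codon-aligned
  SfiI-site block). Candidate pool variants are themselves screened against
  the full default registry *in framework context* at design time — the
  same curation a synthetic-library designer applies — which is why the
  filter's precision and recall against planted truth are exactly 1: the
  only liabilities present are the planted ones. On real libraries,
  incidental motifs make "precision against intent" unmeasurable; the
  benchmark verifies the scanner, not the world.

Sequencing is emulated as per-copy reads with i.i.d. substitution errors
and constant Q40 quality; a configurable fraction of anchor-less random
reads stands in for a sequencing-diversity spike-in and exercises anchor
filtering. No indels, chimeras or quality-score realism (the annotation
stage is substitution-tolerant, not indel-tolerant, by scope).

## Repertoire processing

The VHH payload starts immediately after the first exact occurrence of the
30-nt PhiS4 anchor, searched on the forward strand then the reverse
complement. Translation is frame-0 standard code; internal stops,
non-triplet remainders and ambiguous bases are flagged, never dropped
silently. Frameworks are located left-to-right by exact match, then by a
*unique* minimal-Hamming match within 2 substitutions (tolerating ~1%
sequencing error over 11–32 aa frameworks); ties or misses produce a
flagged annotation-failure record. Regions must tile the sequence with
non-empty CDR gaps. All coordinates are 0-based half-open.

ELISA hits use signal / max(background, floor) ≥ fold with fold = 3
(boundary inclusive — "three-fold over background" read as at-least) and
floor = 0.05 a.u. to keep blank wells finite. Raw rather than
blank-subtracted OD is assumed.

## Liability registry

Default protein motifs: deamidation NG/NS/NT, isomerization DG/DS/DT,
N-glycosylation sequon `N[^P][ST]`, unpaired cysteine (CDR cysteines are
reported when their total count across CDRs is odd), N-terminal E/Q
pyroglutamate precursor (advisory only — it shifts mass, it does not
disqualify). Nucleotide motifs: splice donors GGTAAG/GGTGAG, a
polypyrimidine acceptor `YYYYYYNCAG`, SfiI `GGCCNNNNNGGCC` (the cloning
enzyme), EcoRI and NotI. Protein scanning is CDR-restricted by default
(frameworks are constants, not screened diversity — the scaffold's own
FR3 contains NT/NS hotspots by design); nucleotide scanning always covers
the whole cassette. Scanning is overlap-complete (regex lookahead). The
registry is a documented stand-in for proprietary screen sets; a
position-weight-matrix splice scorer is out of scope.

## Enrichment

Clonotype = exact CDR3 amino-acid identity (with one fixed framework there
is no V-gene component to the key). Enrichment is the log2 ratio of
round-4 to round-3 clonotype frequencies with additive pseudo-frequency
$p = \text{pseudocount}/\sqrt{T_3 T_4}$ (pseudocount 1), which keeps
scores finite and exactly antisymmetric under round swap. Frequencies are
computed over all clonotypes (they sum to 1 per round), but clonotypes
with fewer than 10 round-3 reads are not *ranked* — a ratio on a handful
of reads is sampling noise, the same floor the affinity-correlation
benchmark applies. Candidate selection takes the top 20 clonotypes by
score (ties: higher round-4 frequency, then lexicographic key) and up to
3 variants per clonotype by round-4 count (ties lexicographic);
"most abundant" is interpreted as round-4 read count, with ratio-vs-
abundance ranking left as a config choice. Aggregation across workflows is
a union by exact sequence with provenance labels retained.

## KNN triage

Descriptors (25): the 20 amino-acid frequencies, length, mean
Kyte–Doolittle hydropathy, approximate net charge at pH 7 (D/E −1, K/R +1,
H +0.1), aromaticity, and CDR3 length when annotation is supplied. Columns
are z-scored with population SD; constant columns map to 0 and are
flagged. PCA uses a full SVD with a deterministic sign convention (largest-
magnitude loading positive). The grid — components ∈ {2,5,10,15} ×
k ∈ {3,5,7,9}, k odd for tie avoidance — is scored by mean stratified
5-fold cross-validated F-beta computed inside the fold (normalization and
projection fit on the training fold only); ties resolve to fewer
components, then smaller k; the winner is refit on all data. β defaults to
1.0 (the objective's β is campaign-specific and not fixed by convention;
it is exposed as a parameter).

Training sets combine binding-assay (SPR-style) labels, optional round-4
enriched supplements for the positive class (default: the top-20
clonotypes' variants) and a seeded random library draw for the negative
class; label conflicts resolve to binder and are counted.

## Convolutional triage

One-hot encoding (20 × L, right-padded to the training maximum length);
two 1-D conv layers (kernel 5 × 32 filters, kernel 3 × 64), ReLU, global
max pooling, a 64-unit hidden layer, sigmoid output — the smallest
architecture that reliably solves motif-separable fixtures, fully
configurable. Training: binary cross-entropy, Adam (lr 3 × 10⁻³, batch 32 —
chosen so that few-hundred-sequence training sets, not only the benchmark
scale, escape the all-negative plateau), seeded stratified validation
split, and per-epoch checkpoint selection by validation F1 (ties: earliest
epoch). The network is plain numpy with manual backpropagation: exactly
reproducible given a seed, dependency-free, and fast at triage scale
(~2 s for 1,600 × 112-residue sequences × 10 epochs on one CPU).
Predicted binders are sequences with probability ≥ threshold (0.5
default); diversification runs PAM-style k-medoids on pairwise normalized
edit distance and returns each cluster's highest-probability member (ties
lexicographic).

## Assay analyses

*Binning*: relative responses below 0.30 of the no-competitor control
(threshold configurable; instrument thresholds are adjusted per campaign)
are "blocked"; the matrix is restricted to antibodies present as both
ligand and analyte, symmetrized by OR of the two orientations, and
antibodies with identical symmetrized rows share a bin. Bins are numbered
by size descending, then lexicographic smallest member. Near-identical
(Hamming ≤ 1) grouping is deliberately not the default: exact-pattern
grouping is order- and permutation-invariant and transitive, which a
similarity threshold is not. Missing cells stay masked and must match
masked.

*Footprinting*: modification fraction = modified/total XIC area; percent
fold-change is the signed difference over the unbound baseline (a ratio
× 100 variant is exposed via `fold_change_mode`); significance is a
two-sided two-sample Student's t with pooled variance (equal variances
assumed, per the classical test; Welch is not used). No multiple-testing
correction by default — FDR control in the upstream peptide identification
is a vendor-software concern — with Benjamini–Hochberg available as an
option. Calls: protected (negative, p < α), deprotected (positive,
p < α), else unchanged. Four replicates per state is the expected design;
two is the enforced minimum.

*TGI*: the printed formula exactly, undefined when the control arm does
not change; volumes must be positive. It is affine-invariant under common
rescaling of all four volumes.

## Benchmark problem sizes

The recovery benchmarks (`panscreen.benchmarks`, exercised by the test
suite and `scripts/acceptance.py`) use: 20 campaigns of 2,000 clones /
50,000 reads per round for enrichment recovery; 3 campaigns of 2,000
clones (1,200 noisy-labeled training, 800 clean-truth held-out, 3% label
noise) for each classifier; 20 label permutations over a 120-sequence
compositional fixture for the F-beta null; 500 clones at a 0.2 planted
fraction for screen exactness. These sizes give stable medians in tens of
seconds on one CPU; all randomness flows from explicit seeds.

## Known limitations

* The selection model ignores amplification bias, display-level variation
  and inter-round bottlenecks; enrichment–affinity correlation on real
  data will be weaker than the simulated ≈0.87 Spearman.
* Annotation is substitution-tolerant but not indel-tolerant; indel-heavy
  platforms need an aligner-based annotation stage.
* The liability registry is a standard developability set, not a validated
  proprietary screen; the splice-site consensus is literal, not a scoring
  model.
* Classifier benchmarks certify planted-signal recovery and reproducibility,
  not real-campaign generalization; the descriptor set and architecture
  are interchangeable defaults, not tuned recommendations.
* Epitope binning assumes a binarizable, mostly complete competition
  matrix; graded partial competition collapses to the threshold decision.
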