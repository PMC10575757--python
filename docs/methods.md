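# Methods

`vhhmine` implements an integrated VHH (nanobody) hit-discovery workflow
over multi-round display-selection NGS data. This note documents the models
and procedures, the parameters that matter, the synthetic data the package
validates itself on, and the numerical choices made where the design was
genuinely open.

## Data model

All analyses operate on *annotated* sequences: CDR1/CDR2/CDR3 amino-acid
triplets with per-round read counts. The workflow targets fixed-framework
libraries (a single humanized scaffold diversified only in the CDRs), so
the CDR triplet is the identity key; duplicate rows merge on read with
counts summed, and round totals are conserved by construction. CDRs can be
cut out of full-length sequences by exact framework-anchor matching
(FR1–FR4 must occur exactly once, in order); because the framework is
constant this is exact and needs no numbering scheme. A repeated anchor is
treated as corrupt input rather than resolved silently. Raw read counts are
used throughout; no cross-round normalization is applied beyond the
relative-abundance ratios described below.

## CDR3 clustering

Sequences are partitioned into CDR3 families by greedy, abundance-ordered
centroid clustering (CD-HIT style) at a configurable identity threshold
(default 0.5, the conventional cutoff for assuming a shared binding mode
while retaining within-family diversity). Candidates are visited in
descending total read count, ties broken by lexicographic CDR3 then
sequence id; a candidate joins the first cluster whose *centroid* identity
is ≥ the threshold, else founds a new cluster. The procedure is
deterministic and scales linearly in clusters × sequences.

Identity between two CDR3s is defined as the number of identical aligned
positions in the optimal global alignment (match 1, mismatch 0, linear gap
−1), divided by the longer sequence length; among score-co-optimal
alignments the one with the most identical positions is taken, which makes
the value well defined. Dividing by the longer length penalizes length
mismatch, which is appropriate for CDR3 loops where indels usually imply a
different loop conformation. Note that the greedy result can depend on
centroid choice for borderline pairs sitting exactly at the threshold;
`partition_deviations` reports disagreements with any reference grouping
instead of hiding them.

## Enrichment statistics

The cluster enrichment factor between a baseline round (b) and a selected
round (s) is the pseudocount-stabilized fold change

    EF = ((n_s + 1) / (t_s + 1)) / ((n_b + 1) / (t_b + 1)),

with n the cluster's reads and t the round total. The +1 pseudocounts keep
EF finite for clusters absent from the baseline — exactly the
rare-but-improving binders the statistic exists to surface. A reporting
variant rounds to the nearest integer; the unrounded value is always kept.
Clusters can be ranked by EF or by selected-round frequency; the pipeline
progresses the union of the top-k of both rankings (default k = 5 each,
deduplicated), mirroring the two complementary selection routes
(frequency ≈ what colony picking would find; enrichment finds rare
improvers).

Per-residue matrices summarize a cluster's sequence space: the
count-weighted residue frequency at each position of a region (rows sum
to 1), or the ratio of such frequencies between two rounds,
(f_sel + ε)/(f_base + ε). No standard per-residue enrichment formula
exists, so the package declares one: the pseudocount ε defaults to
1/(smaller round's total reads), which shrinks ratios that low coverage
cannot support, and is configurable. Because matrix columns are positional,
only sequences whose region length equals the count-weighted modal length
enter the matrix; the excluded read fraction is reported. A full per-cluster
multiple alignment was deliberately left out — within a fixed-framework
library, same-length CDRs dominate each family.

## Generative model

Within one cluster, concatenated CDR1+CDR2+CDR3 strings from the final
selection round are modeled autoregressively over a 23-token vocabulary
(20 residues, start, end, pad) by a stacked LSTM — default two layers of 64
units with 0.2 dropout on each layer output, one-hot inputs, and a softmax
over the vocabulary, trained with Adam under teacher forcing. The
implementation is pure numpy (forward, backpropagation through time,
gradient-norm clipping at 5, Adam with cosine learning-rate decay); it is
exact (gradient-checked against finite differences) and fully
deterministic given a seed.

Read redundancy is part of the signal: a sequence observed c times in the
training round contributes c replicated training examples (capped at
`replication_cap`, default 20,000 total, with proportional rescaling), so
the model learns the FACS-selected abundance distribution rather than the
unique-sequence support. Replication, rather than fractional loss weights,
also scales the number of optimizer steps with read depth, which is what
makes deeply redundant pools train to convergence.

The training epoch is chosen by k-fold cross-validation (default 5) over
*unique* sequences — replicas of one sequence never straddle folds — taking
the epoch with the lowest mean held-out per-token loss, then refitting on
all data for exactly that many epochs. `cv_folds=1` disables
cross-validation (the model trains for `max_epochs`); this is the intended
setting for degenerate inputs such as single-sequence memorization checks,
where cross-validation is undefined.

Sampling is autoregressive from the start token with a softmax temperature
(default 1.0); a sampled sequence terminates at the end token or at the
maximum training length. Sequences whose total length was never observed
in training are discarded and resampled (default budget: 10 rounds), any
shortfall being reported, and CDR boundaries are re-imposed from the
cluster's modal CDR1/CDR2 lengths — within a cluster the library design
fixes those lengths, so the total-length constraint determines the CDR3
split. The temperature → 0 limit reproduces explicit greedy argmax
decoding.

Sequences are scored by the negative log-likelihood

    NLL(x) = − Σ_k ln p(x_k),

summed over the residues and the end token, with probabilities floored at
1e-12 so the score is always finite. Lower NLL means more typical of the
enriched pool; NLL is a selection prior, not an affinity predictor.
Observed and sampled sequences are ranked together after deduplication on
the CDR triplet (a sequence present in both pools keeps its observed
origin), sorted ascending by NLL with lexicographic tie-breaks.

Defaults that matter: `learning_rate` 0.03 with cosine decay to zero,
`batch_size` 8. Small batches give enough optimizer steps per epoch that
reduced-scale models (32 hidden units, 30 epochs, ~1,000 training
sequences) train to convergence, and the annealing is what makes the
sampled per-position frequencies settle on calibrated values instead of
oscillating with the last minibatches; without decay the sampled marginals
drift several percentage points off the training distribution. At full
scale (64 units, 200 epochs, deep pools) the same settings are slower than
a GPU framework would be, but the architecture is small and CPU-only
operation was a design requirement.

## Developability triage

The package computes sequence-level descriptors that stand in for
structure-based developability scores while preserving their filtering
role; the surrogate status is visible in the API names and here.

* **Liability flags.** Every CDR Asn (deamidation), Asp (isomerization),
  Met (oxidation) and Cys (unpaired cysteine) is flagged; the following
  residue sets the severity tier: NG, DG, Met, Cys and the N-X-S/T sequon
  (X ≠ P, glycosylation) are high; NS/NT/NN/ND/NH and DS/DT/DD moderate;
  everything else low. Weak motifs are flagged rather than ignored —
  non-canonical motifs such as Asn-Tyr do degrade measurably — and all
  motif tables are overridable.
* **Isoelectric point.** Henderson–Hasselbalch net charge (N/C termini plus
  D, E, C, Y, H, K, R side chains) with an EMBOSS-style pKa table shipped
  as a data file; the pI is found by bisection on [0, 14] to 1e-4 (the net
  charge is strictly decreasing in pH, so bisection is exact).
* **CDR hydropathy.** Maximum sliding-window mean (default window 5) of
  Kyte–Doolittle residue hydropathy across the three CDRs, windows never
  spanning CDR boundaries; a CDR shorter than the window contributes its
  full-length mean. This is the aggregation-propensity surrogate: it finds
  the most hydrophobic contiguous patch the CDRs expose.
* **CDR positive charge.** #R + #K + 0.1·#H over the CDRs, the
  positive-patch surrogate at pH ~7.4 (histidine mostly uncharged).
* **Framework human-likeness.** Percent identical positions over the
  global alignment length versus a user-supplied germline; no germline is
  bundled.

Descriptors are traffic-lit against a user-supplied reference set (mean and
SD per descriptor): green within mean + 1 SD, yellow within mean + 2 SD,
red above, for descriptors where low is good (hydropathy, positive charge).
pI carries no light — it is a diversity axis, not a cutoff. Missing
reference statistics omit the lights but never the values.

## Candidate nomination

From an NLL-ascending, profiled pool the selector applies, in fixed order:
(1) best-NLL sequences passing all hard descriptor cutoffs until at least
`min_from_top100` (default 3) come from the top-100 ranks; (2) the passing
sequences nearest each tercile boundary of the pool's NLL range, so
synthesized sets span the score axis for later score–affinity correlation;
(3) coverage of empty pI bins (default boundaries 6.5/7.5/8.5); (4) if
every chosen sequence carries some moderate/low liability category, the
best passing sequence free of it (a liability-free backup); (5)
representation of both origins (observed and model-sampled), swapping out
the worst non-essential choice if the set is full. Selection stops at
`max_per_cluster` (default 10); every inclusion carries rationale tags and
every exclusion a reason. The priority order is a declared convention: the
underlying criteria do not define a total order, and a fixed order is what
makes the selection reproducible. Note that the spread rule is
parameterized by the pool's NLL range, so the range endpoints are not
"irrelevant alternatives" — removing them may legitimately change step (2).

## Synthetic campaigns

The simulator emulates what a display-selection campaign hands to the
analysis: round 0 is an i.i.d. draw from per-cluster PWMs over CDR1/2/3
(default: four families, CDR lengths 10/8/18, consensus residues at
probability 0.7 with two alternates at 0.15 at a few variable positions,
mutually < 50%-identical CDR3 consensus sequences so the families are
separable); each later round is a multinomial resample of the previous one
with weight proportional to count × exp(fitness). Fitness is log-linear: a
per-cluster base term (default gap 1.0 between adjacent clusters) plus
per-position residue bonuses (default 0.5 at two variable CDR3 positions),
giving both between-cluster enrichment ordering and within-cluster SAR.
Per-round totals are exact (default 10,000 reads), and every sequence
carries its generating cluster and hidden fitness.

What the simulator does *not* model: sequencing error, PCR amplification
bias, nucleotide-level effects, epistasis beyond additive residue bonuses,
and new sequences arising after round 0. Passing tests on this generator
therefore demonstrate that the statistics and models recover planted
structure under idealized sampling noise — not that they are robust to
platform artifacts in real NGS data.

## Scales used in the test suite

Everything is sized for a single CPU: reference-scale model checks use 32
hidden units, 30 epochs, ~1,000 training sequences and 2,000 samples;
simulator checks use 1,500–10,000 reads per round with 20 seeded replicates
where a claim is statistical; the end-to-end pipeline test runs a
three-cluster campaign with a 16-unit model. The full-scale defaults (64
units, 200 epochs, 10,000 samples per cluster) are exercised for
correctness through these reduced configurations, which differ only in
size.

## Known limitations

* The identity definition and the greedy clustering algorithm are declared
  conventions; other reasonable choices (identity over alignment length,
  average-linkage clustering) can split borderline pairs differently.
* The per-residue enrichment pseudocount has no canonical value; ratios for
  low-coverage residues should be read qualitatively.
* Sequence-level developability surrogates ignore conformation: a
  hydrophobic window buried by the fold still scores high, and CDR charge
  ignores framework context.
* NLL ranks within a cluster are comparable; across clusters they are not,
  because each cluster has its own model and length set.
* The LSTM interpolates within the training support (one-hot encoding has
  no notion of residue similarity); it will not propose chemistry outside
  the observed sequence space.
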