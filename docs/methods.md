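# Methods

## Problem and model

`hostscope` predicts, for each query virus, the genus of its bacterial or
archaeal host, together with a calibrated confidence. The underlying model
is a two-stage supervised ensemble over heterogeneous virus→host-genome
evidence ("tools"): alignment hits (`blast`), CRISPR spacer matches
(`crispr`), and three alignment-free similarity signals (`kmer_model`,
`s2star_like`, `php_like`), optionally complemented by a phage-based
predictor that labels the virus by similarity to reference phages.

The key representation is the **hit matrix**: for one virus, one tool and
one candidate host genome, the number of hits is tallied over
(phylogenetic-distance bin × score bin), where distance is the patristic
distance on the host reference tree between the hit's genome and the
candidate. This makes "many strong hits, all phylogenetically close to the
candidate" — the signature of a trustworthy prediction — learnable by a
classifier, and conversely penalizes strong hits scattered across the tree.

## Host reference frame

A `HostFrame` couples a rooted branch-length tree over host genome
representatives (newick) with a lineage table (GTDB-style strings or seven
rank columns). Patristic distances are computed once into a dense matrix.
Distances are discretized by half-open bins with default edges
[0, 0.1, 0.5, 1, 1.5, 2, 2.5, 3]; everything at or beyond the last edge
falls in the final open-ended bin, giving 8 bins. Bin 0 is effectively the
candidate's own hit (identical genome or a very close conspecific), so the
same binning must be used at training and prediction time; fitted models
carry their binning configuration for this reason.

## Hit providers

* **blast**: 12-column tabular alignments filtered at e-value ≤ 1e-3,
  identity ≥ 80%, aligned length ≥ 500 nt, then aggregated per
  (virus, genome) into match count, unweighted mean identity and total
  aligned length.
* **crispr**: hits of host spacers on the virus, retained when the spacer
  is ≥ 25 nt, has < 8 mismatches over the entire spacer, and has a
  complexity score < 0.6. The complexity score is `(CWF − 2) · 2` unless
  the AT-skew statistic exceeds 0.65, in which case it is `skew + 0.1`;
  CWF is computed as the Shannon entropy (base 2) of mononucleotide
  frequencies. Because the entropy branch as written is always ≤ 0 (making
  AT skew the only active filter), an `inverted` variant `(2 − CWF) · 2`
  is selectable; the default keeps the formula as stated. "AT skew"
  defaults to |nA − nT| / (nA + nT) with an `at_content` alternative, the
  phrase being ambiguous. The built-in matcher is an ungapped Hamming scan
  of each spacer over both strands; every placement within the mismatch
  budget is reported once, with the minimum-mismatch strand (+ preferred
  on ties), N never matching anything. Coordinates are 0-based on the +
  strand of the virus.
* **kmer_model**: an order-k Markov model (default k = 2, additive
  pseudocount) trained per host genome; a virus is scored by its mean
  log-likelihood per base, converted to a one-sided p-value under a
  Gaussian null fitted to scores of shuffled copies of the training
  sequence. Hits with p > 0.2 are discarded. This is a self-contained
  alignment-free scorer in the WIsH family of methods.
* **generic score tables** for the remaining alignment-free tools: TSVs of
  (virus, genome, score) with a recorded orientation (p-values and
  mismatch counts are lower-better); duplicated pairs keep the best score.
* **phage-based predictions**: (virus, free-text host label, score in
  [0, 1]). Labels are mapped to host genera through a genome tally per
  label: a genus inherits the label if it covers ≥ 50% of the tally when
  the tally holds < 10 genomes, ≥ 20% for 10–100, ≥ 10% above 100
  (boundaries inclusive on the 10–100 bucket).

## Encoding and classifiers

Per tool, a virus's hits are truncated to the top 50 (blast) or top 30
(other tools), ties broken by genome id; each genome with a retained hit is
a candidate host. Score bins are oriented so a larger index is always
better: blast uses a 4×3 grid (identity {[80,85), [85,90), [90,95),
[95,100]} × matches {1, 2–4, ≥ 5}), CRISPR uses the mismatch count
reversed (bin 7 = perfect), the k-mer model bins −log10 p at {2, 5}, and
generic tools use four quantile bins fitted on training scores and frozen
into the model bundle. These bin definitions are package defaults chosen
to respect each tool's reporting cutoffs; they are configurable.

Training instances are (virus, candidate) pairs labelled by whether the
candidate's genus equals the virus's true host genus. Sampling enforces
60–85% incorrect pairs and 45–70% "known" viruses (a boolean novelty flag
supplied with the labels, in practice thresholded at 70% amino-acid
identity to the closest reference); the sampler solves a small 2×2
transportation problem over the (label × known) strata and shrinks the
target size until an integer allocation exists, raising an explicit error
with the achievable fractions otherwise. Each sampled pair contributes
three variants emulating uneven database coverage: all hits; a random
subset (each hit kept with one uniform per-instance probability); and a
sparse-close variant keeping one random hit among those within distance
bin ≤ 4 plus all more distant hits. The "≤ 4" is interpreted on the bin
index scale, the same discrete axis the matrices use.

Three classifier families share one contract (probability that the
candidate is the correct genus): `dense_net` (multilayer perceptron on the
flattened matrix, standardized inputs), `conv_net` (the same preceded by
fixed sliding-window sums along the distance axis — a local feature map
capturing "mass of nearby hits" at each depth), and `random_forest` (on
the flattened matrix plus three summary features: best score bin at
distance 0, hit count within the three closest bins, total hits). Training
uses an 80/20 stratified split; hyperparameters are drawn by seeded random
search within fixed ranges (forests: 100–1,000 trees, depth 4–32, 2–10
examples per node; nets: 1–2 hidden layers of 16–64 units, log-uniform L2).
Trials are drawn sequentially from one seeded stream so longer searches
extend shorter ones.

Classifier subset selection works on *non-ambiguous* cases — viruses with
at least one hit passing a stringent raw cutoff (blast total ≥ 10 kb,
CRISPR 0 mismatches, k-mer p ≤ 1e-5, s2*-like ≥ 0.8, PHP-like ≥ 1450). For
each candidate classifier the cutoff is the 10th percentile of its scores
on correctly-predicted non-ambiguous cases and the error rate is the
number of incorrect predictions above that cutoff. Selection starts from
the lowest-error classifier and adds another while it contributes ≥ 5%
more correct non-ambiguous predictions or gives a correct above-cutoff
prediction for ≥ 10% of the current false positives ("correcting" them).
Both gains are computed over non-ambiguous cases.

## Combined forest, calibration, composite

The combined-hosts random forest sees, per virus–candidate pair, three
features per selected classifier (score; rank among the virus's
candidates, ties sharing the minimum rank; difference to the virus's best
score). Pairs unscored by a classifier are imputed as (0, n_candidates,
best − 0) — an explicit package decision. Its training set is balanced by
evidence type (up to 700 viruses each with both blast and CRISPR hits,
either, and neither; up to 10 correct and 5 incorrect pairs per virus);
among the five most accurate random-search trials, the forest with the
highest recall at 5% FDR on the held-out 20% split is kept.

Calibration curves map each method score to an empirical PPV on a 0→1
grid of step 0.001, with sliding windows of width 0.05 (single-tool
classifier scores) or 0.01 (combined forest, phage-based, final
composite). The smooth fit is a penalized binomial spline on the logit
scale (10 basis functions, second-difference penalty α = 50, IRLS), so
constant or log-linear PPV trends are recovered without bias, projected
onto the monotone cone by isotonic regression weighted by window support
and clamped to [0, 1]. Degenerate all-correct/all-wrong inputs
short-circuit to the exact constant curve. Curves are fitted on **all**
scored (virus, genus) pairs of a calibration split disjoint from the
training split — never on training viruses — so the reported FDR is an
out-of-sample estimate.

For one (virus, genus) pair, methods with PPV < 0.5 are discarded; the
remaining method with the highest PPV supplies the main FDR and each other
agreeing method multiplies it by its doubled FDR (doubling rescales an FDR
≤ 0.5 onto [0, 1]); the composite is one minus the product, hence never
below the main PPV. Genome-level scores reduce to genus level by the max
over member genomes (recording the contributing genome); where several
selected classifiers back one method family, the pair keeps the best
calibrated PPV among them. A final empirical curve (window 0.01) fitted on
the calibration split's composites yields the reported confidence
(100 × PPV); predictions below 75 are dropped and the summary output
defaults to ≥ 90. Within a virus, rows sort by confidence, then composite
(the curve can saturate), then genus name.

## Synthetic benchmark

`simulate_world` generates the study conditions used by the tests and the
acceptance run: 60 genera × 2–4 genomes (mean 3) on a random binary tree
with within-genus branch lengths U(0.02, 0.10) and backbone lengths
U(0.20, 0.60) — so within-genus patristic distances are stochastically
well below between-genus ones — and 800 viruses, each assigned a true host
genome uniformly and flagged "known" with probability 0.55. Per tool, the
true host receives a signal hit with probability p_fire (0.70 blast, 0.50
crispr, 0.85 alignment-free), genus siblings receive weaker hits with
probability 0.25–0.60, and Poisson background hits (rate 0.8–3.0) land on
uniformly random genomes. Signal and background score distributions
overlap realistically (e.g. blast identities U(88, 99.5) vs U(80, 88);
CRISPR mismatches mostly 0–2 vs 4–7; PHP-like scores N(1500, 60) vs
N(1150, 100)) and are placed on each tool's native scale so the
non-ambiguous cutoffs select a meaningful subset. A phage-based predictor
emits a label for 60% of viruses, correct 80% of the time with
Beta(6, 2)-distributed scores (wrong labels Beta(2, 4)). These parameters
were fixed once as a plausible mid-difficulty regime; two degenerate
modes — `noiseless` (signal always fires with score ranges disjoint from
background) and `noise_only` (scores independent of truth) — exercise the
limiting behaviour.

`simulate_sequences` adds toy FASTA data (hosts 4 kb, viruses 1.5 kb,
genus-specific AT fraction U(0.30, 0.70) shared between a virus and its
host's genus; spacers copied verbatim from virus substrings with lengths
drawn widely and filtered to 10–100 nt, mirroring database-construction
practice) so the sequence-level providers can be validated against the
parametric truth. It emulates compositional signal only — no gene content,
GC realism or genuine CRISPR array structure — so sequence-level tests
demonstrate correct mechanics, not field performance.

`run_benchmark` splits viruses 50/25/25 into train/calibration/test
(seeded shuffle, disjointness asserted), runs the full workflow and
reports recall and FDR of the best-per-virus predictions at cutoffs 75,
90, 95. The pooled acceptance run uses five consecutive seeds. Benchmark
fitting defaults are sized for a desk-scale run: ~1,500 sampled pairs per
tool (×3 variants), two random-search trials per classifier kind (forests
plus nets for blast/CRISPR, nets for the alignment-free tools), eight
trials for the combined forest; these are `FitConfig` fields, and larger
searches only sharpen the classifiers.

## Numerical and design notes

* All randomness flows from one seed through `numpy` `SeedSequence`
  spawning; per-stage seeds stay below 2^31. Sorts use mergesort with
  explicit tie-break columns, so outputs are byte-identical across reruns.
* Ties in top-k truncation, candidate ranking and best-per-virus selection
  break deterministically by genome id / genus name.
* The spacer matcher reports all qualifying placements; downstream, one
  best placement per (virus, genome, spacer) is kept (min mismatches, +
  strand, smallest position).
* Empty calibration windows inherit the smooth trend with nominal weight
  0.1 rather than a neighbour's raw value.
* Viruses whose every method PPV is below 0.5 yield no prediction at all;
  an empty prediction table is a valid pipeline outcome (the pure-noise
  world produces one).
* Known limitations: the phage-based score must already live on [0, 1];
  genus aggregation is a plain max (no multi-genome pooling); strain- or
  species-level prediction and broad-host-range modelling are out of
  scope; the synthetic worlds do not emulate database incompleteness
  beyond the hit-subsampling variants, so absolute recall numbers on
  synthetic data say nothing about recall on real viromes — the quantity
  the benchmark validates is the *calibration* of the confidence score
  (observed FDR at confidence ≥ 90 staying within its nominal 10%).
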