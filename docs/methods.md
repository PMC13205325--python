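# Methods

`anomod` detects nucleic-acid base modifications from nanopore raw current
without modification labels.  It learns a *reference model* of unmodified
signal — a CNN–Transformer variational autoencoder trained on windows from
an unmodified corpus (WGA DNA, IVT RNA, or unmodified synthetic oligos) —
and flags nucleotide instances whose signal the model cannot reconstruct.
This note records the model, the design decisions behind the
implementation, the synthetic data generator, and what the shipped
benchmarks do and do not demonstrate.

## 1. Model and scoring

**Instances.** For a read *r* aligned over reference site *j*, the instance
is a fixed-size feature matrix `x ∈ R^{L×C}` built from the read's
re-squiggled signal: L consecutive read bases centered on the base aligned
to *j* (default L = 7), C = 11 channels per base — one-hot base identity
(4), winsorized mean of the base's samples (1), the three quartiles (3),
the central sample (1), RMS energy (1), and the basecaller quality (1).
Signal features are computed after per-read z-normalization (population
statistics over the whole read), which removes per-read amplitude offset
and scale.  Window positions that fall off the read are zero-filled and
recorded in a validity mask; losses and scores ignore them.

Channel layout is the only decomposition of the stated ingredient list
consistent with C = 11.  Winsorization clips at the 5th/95th percentile of
the base's own samples; quantiles use linear interpolation; the central
value is the left-middle raw sample on even-length segments; quality is
Phred/40 clipped to [0, 1].  These conventions are fixed so tests can
assert exact values.

**Reference model.**  The encoder applies two same-padding Conv1d blocks
(C→64→64, kernel 3), adds fixed sinusoidal positional encodings, runs two
pre-LayerNorm Transformer blocks (4 heads, feed-forward 2×), mean-pools
over positions, and maps to the mean and log-variance of a diagonal
Gaussian posterior over a latent z (H = 16).  The decoder projects z to
L×64 tokens, runs two Transformer blocks, and reconstructs the window with
a two-layer convolutional head.  Training minimizes the β-weighted negative
ELBO

    L(x) = MSE_masked(x, x̂) + β · KL(q(z|x) ‖ N(0, I)),

with AdamW (weight decay 1e-4), a linear β warm-up from 0 to β_max = 0.01
over the first 3 epochs, a half-cosine learning-rate decay (3e-3 → 3e-4),
and early stopping on an unmodified validation split held out **by read**
(never by instance) so no read leaks between splits.  Validation loss is
always computed at β_max so epochs are comparable across the warm-up.

**Scoring.**  The anomaly score of an instance is its masked reconstruction
MSE, with x̂ decoded from the posterior *mean* — no sampling at inference,
so scores are deterministic given a checkpoint.  Site-level evidence is the
mean (optionally median) of instance scores across the reads covering the
site, reported with coverage n, sd (ddof = 1; 0 when n = 1), unscaled MAD,
and sem = sd/√n.  Sites are keyed by (contig, position, strand); an
optional differential track subtracts a matched control (e.g. native minus
unmodified-proxy).

**Soft k-mer balancing.**  During streaming training, a candidate instance
with reference k-mer context u (default k = 7, strand-oriented) is accepted
with probability `min(1, C_max / (N_seen(u) + 1))`, where N_seen counts
*accepted* instances of that context.  Acceptance therefore decays
hyperbolically for over-represented contexts while rare contexts are always
kept.  Counters persist across epochs by default and can be reset per
epoch; contexts containing non-ACGT characters are rejected outright.
Rejected candidates are not revisited (single-pass streaming).

## 2. Why training dynamics matter for reconstruction scoring

Anomaly detection by reconstruction error only works if the model
reconstructs *in-distribution structure* well while being unable to
reproduce out-of-distribution deviations.  Because every bit of decoder
conditioning flows through z, an under-trained or over-capacitated model
simply passes the observed signal levels through the latent — including a
modification-induced shift — and scores anomalies at chance.  Two levers
decide the outcome:

* **β sets the information budget.**  With too small a β relative to
  training progress the latent transmits raw amplitudes (anomalies
  reconstruct perfectly); with too large a β the posterior collapses and
  the decoder emits a global mean pattern (everything is equally
  anomalous).  The default β_max = 0.01 keeps reconstruction dominant, as
  required for an informative error signal.
* **Training must reach the conditional regime.**  Discrimination emerges
  late: validation reconstruction error keeps falling well after total
  loss has visibly flattened, and instance AUROC in the shipped benchmark
  rises from near-chance at ~20 epochs through ≈0.88 at 35 to ≈0.92–0.98
  at 60.  The default schedule (60 epochs, cosine-decayed learning rate)
  sits at the top of that curve; stopping much earlier leaves the scorer
  blind even though the loss looks converged.

The ReLU activation in the convolutional and feed-forward sublayers (GELU
available via `activation="gelu"`) converges measurably faster per unit
wall-time on CPU and is the default for that reason.

The neural-network layer itself is implemented in this package on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`anomod.nn`), with fused convolution, attention and layer-norm primitives;
every primitive's gradient is checked against central finite differences in
the test suite, and AdamW is implemented from its update equations.

## 3. The synthetic squiggle generator

The simulator provides complete, label-rich datasets with the statistical
structure the method assumes, so the entire pipeline is testable without
downloads.

* **Pore model**: a full 4^k table (default k = 7) of per-context current
  level means (Normal, mean 90, sd 12 pA-like units), within-context spreads
  (Uniform 1.5–3.0), and expected dwells (Uniform 6–12 samples/base).
  Levels are i.i.d. across contexts — deliberately structureless, so
  nothing about a context's level can be inferred from similar contexts.
* **Reads**: a read cut from the reference carries, per base, an integer
  dwell (1 + negative-binomial excess; dispersion 1 makes the excess
  geometric) and `dwell` raw samples of `offset + scale × (level +
  N(0, noise_sd))` with noise_sd = 2.  Per-read `offset ~ N(0, j·σ_levels)`
  and `scale ~ LogNormal(0, j)` with jitter j = 0.15 emulate run-to-run
  amplitude variation — exactly what per-read z-normalization removes.  The
  offset is scaled by the pore table's cross-context level sd so one knob
  yields comparable relative offset and scale jitter.
* **Modifications**: an IUPAC motif with a marked offset (default CpG
  cytosines) defines candidate sites on both strands; a site-selection rate
  and per-site occupancy set which sites and which molecules are modified;
  an optional region confines selection to an interval (island-like
  clustering).  A modified base shifts the level of *every* k-mer window
  containing it by `level_shift × level_sd(u)` of the affected context —
  the perturbation bleeds into neighbouring positions, as it does
  physically — and can scale the modified base's dwell.
* **Truth**: instance labels y ∈ {0,1} for every (read, motif-site) pair on
  the site's strand, and per-site occupancy equal, exactly, to the mean of
  that site's instance labels.  Training never sees these labels.

What the generator does **not** emulate: basecalling errors and indels
(alignments are exact by construction; deletions are supported in the data
model and exercised in tests but not generated), sequence-dependent error
profiles, homopolymer compression, RNA 3'→5' translocation, inter-run
chemistry differences, and mappability artifacts.  Passing benchmarks on
this generator therefore demonstrates the *mechanism* — reconstruction
error responds to level perturbations and aggregation sharpens it — not
performance on real flow-cell data.

## 4. Benchmark study conditions

The shipped benchmark (`anomod.benchmark`, run by `scripts/acceptance.py`
and the acceptance tests) is a scaled-down analog of a controlled-oligo
experiment: train on unmodified molecules, test on fully-modified versus
unmodified molecules of the same sequences.

* Reference: one 300 bp random contig (the short-oligo regime: the same
  sequences appear in training and test, as in oligo benchmarks).
* Training corpus: 70 unmodified full-length reads ≈ 21k instance windows;
  ≤ 18k used for optimization after the read-level validation split (15%),
  60 epochs with the default cosine schedule in float32 (≈6 minutes on one
  CPU).
* Test sets: 20 modified and 20 unmodified reads → ≈10 same-strand reads
  per CpG site; modification = CpG, level_shift 2σ, occupancy 1.0.
* Evaluation: instances at CpG sites, modified sample vs unmodified sample
  (within-molecule negatives are avoided because the level shift bleeds
  into neighbouring windows); site scores are per-sample means at coverage
  ≥ 4.

These sizes were chosen to fit a desk-scale single-CPU run while leaving
the learning problem honest (≈600 distinct strand-specific window
patterns).  The null control re-runs the identical pipeline with
level_shift = 0.  The regional analysis plants a 90%-occupancy CpG block
in positions 100–200 of the reference, scores a deeper read set with the
already-trained model, and sweeps truth cutoffs over the resulting site
track (see `scripts/acceptance.py` for the exact calls).

## 5. Numerical and convention choices

* Coordinates are 0-based half-open everywhere; bedMethyl-like outputs are
  0-based (BED convention).  Sites are strand-specific.
* Signal BAM dialect: float-array tag `sg` (samples, time order), uint
  array `dw` (per-base sample counts, read order), int `so` (sample offset
  of base 0).  SEQ/QUAL follow SAM orientation conventions; tags do not.
  No compatibility with other tools' embedding schemes is claimed.
* Insertions contribute no reference-anchored instance; a site falling in a
  deletion is reported "not covered" and filtered by callers.
* AUROC uses midrank tie handling (Mann–Whitney); average precision uses
  step-wise interpolation over distinct thresholds.  Both match brute-force
  definitions exactly, which the tests assert to 1e-12.
* MAD is reported unscaled (no 1.4826 factor).
* Smoothing for regional correlation: centered rolling mean over 11 sites;
  a rolling-median smoother is available for track denoising.
* Checkpoints store parameters, full config and a feature-schema hash;
  scoring refuses windows built under a different schema.
* The balancer's `C_max` defaults to ∞ (off) in the library; the CLI and
  benchmark document their choices where balancing is on.  A guideline: set
  `C_max` so the most common context contributes ≲1% of accepted instances
  for your corpus size.

## 6. Known limitations

* The model must be *converged* before scores are informative (§2); the
  training history TSV and validation reconstruction error are the
  diagnostics to watch.
* Site-level AUROC compares across sites, so residual per-site baseline
  reconstruction differences put a ceiling on it that coverage cannot fix;
  the matched differential track is the robust alternative when a control
  sample exists.
* Scores are uncalibrated: they rank candidates but are not modification
  probabilities or stoichiometry estimates.
* The engineered fully-occupied CpG layout of the benchmark is easier than
  heterogeneous native methylation; biological-regime performance is
  expected to be materially lower, consistent with the gap between
  controlled-oligo and whole-genome regimes reported for this class of
  methods.
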