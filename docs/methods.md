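# Methods

## Model

mintruls scores miRNA × target-site pairs with regularized least squares
over the Kronecker product of two similarity kernels.  Let `Y ∈ {0,1}^{k×l}`
be the adjacency of known associations, `S_m` a symmetric PSD kernel over
miRNAs and `S_t` one over sites.  The pair kernel is `K = S_m ⊗ S_t`, and
the fitted scores are `F = reshape(K α)` with `(K + λI) α = vec(Y)`
(row-major vec, so `vec(A X Bᵀ) = (A ⊗ B) vec(X)`).  The implementation
never forms `K`: both kernels are eigendecomposed and the spectral filter
`λ_a λ_b / (λ_a λ_b + λ)` is applied to `Q_mᵀ Y Q_t`.  A dense solver
(`direct_solve`) materializes `K` for problems up to `kl ≤ 2000` and is
used in tests as the independent oracle; a unit test pins the vec
convention by requiring exact (1e−8) agreement between the two routes.

`λ = 0` is accepted only when the Kronecker spectrum is numerically
nonsingular (relative floor 1e−12), in which case the fit interpolates
`Y`; otherwise the error message carries a condition estimate.
Eigenvalue products below machine noise pass through the same filter
formula — for `λ > 0` the denominator keeps everything finite, so no
special-casing is needed.

## Kernels

Per miRNA: free energy (FE), Gaussian interaction profile (GP),
Needleman–Wunsch sequence similarity (NW), and SSR-profile similarity,
integrated as a weighted entrywise average with weights `α₁..α₄`
(defaults uniform).  Per site: FE, accessibility (TA), AU fraction (AU),
SSR, and the interaction-profile kernel on adjacency columns, weights
`β₁..β₅` (defaults uniform at 0.2).

The fifth site component is a deliberate design choice.  A site-side
feature-only integration leaves the model no pathway for the second half
of its own structural hypothesis ("similar sites are bound by the same
miRNAs"): site columns become nearly exchangeable, per-row scores nearly
constant, and recovery of planted structure collapses to chance
(measured LOOCV AUC ≈ 0.55 even on noise-free planted data, at every λ
tried).  The Gaussian interaction-profile construction this package uses
for miRNAs was introduced in the bipartite link-prediction literature
for *both* entity sets, and including it on the site side restores
recovery (AUC 1.0 noise-free, ≈ 0.93 at the default noise).  Setting
`site_weights[4] = 0` reproduces the strict four-feature site kernel.

All Gaussian kernels use the profile bandwidth rule
`φ = φ′ / mean(‖v‖²)` with `φ′ = 1` by default; for scalar features the
same rule reads `γ = 1/mean(x²)`.  Degenerate inputs are handled
explicitly: all-equal values give the all-ones kernel; an all-zero
feature column falls back to unit bandwidth with a warning (the kernel
is still all-ones, which is the correct limit for indistinguishable
entities); all-zero profile vectors in the public profile-kernel op are
an error.

NW alignment parameters default to match +1 / mismatch −1 / gap −1
(configurable); raw global scores are normalized by the geometric mean
of self-scores and clipped at 0 so the kernel stays in [0, 1].  The
clipping can make the NW kernel indefinite, so the integrated miRNA
kernel is passed through a PSD projection (eigenvalue clipping at 0,
reconstruction, rescale to unit diagonal).  The site kernel is a convex
combination of Gaussian kernels — PSD by construction — so the
projection, a provable fixed point there, is skipped to save an
eigendecomposition per cross-validation refit.

## Features

Folding is provided through an interface with two engines.  The bundled
default is a self-contained energy-minimizing maximum-pairing dynamic
program (pair energies GC −3, AU −2, GU −1 kcal/mol, minimum hairpin
loop 3; N never pairs); accessibility is the unpaired fraction of the
MFE structure.  An optional engine shells out to RNAfold/RNAplfold when
ViennaRNA is on PATH.  The kernels consume only pairwise differences of
these scalars, so any internally consistent engine preserves the
method's structure; a panel test checks sign agreement between the two
engines on stem-containing sequences.  The per-pair energies are
deliberately simple constants — the point of the bundled engine is
determinism and self-containment, not thermodynamic accuracy.

SSR extraction scans each motif length (2–4 nt) independently with a
greedy left-to-right search for maximal tandem runs; a run of
`r ≥ min_repeats` (default 3) copies of motif M adds `r` under key M.
Only primitive motifs count: homopolymers and phase-redundant motifs
(e.g. ACAC as a 4-mer) are excluded since their runs are already
reported at the shorter period.  Counts are used by default;
`ssr_binary` thresholds them to presence/absence.

Sites longer than the configured length (default 40 nt; 30 is the other
commonly used value) are trimmed to a centered window, left-biased on an
odd overhang — the binding-site position within the provided sequence is
unknown to the data model, and flanks on both ends carry signal, so
symmetric retention is the neutral choice.  AU content ignores N
positions in the denominator; miRNAs with any N and sites with more than
50% N are filtered out before feature computation, and residual N in
retained sites is treated as unpairable.

## Cross-validation and metrics

LOOCV treats one association as test and the rest as training: the test
cell is zeroed, both interaction-profile kernels are rebuilt from the
masked matrix, the model refitted, and the cell scored.  Masking a
negative cell leaves the training matrix unchanged, so negative cells
are scored by the base fit — bitwise identical to mask-and-refit, which
is verified by an exact-equality test.  Because the full negative set is
quadratic in the data, the evaluated set is a seeded subsample:
`neg_per_pos` negatives per positive (default 5; `None` evaluates all)
and an optional `max_positives` cap.  LmiTOCV holds out
`ceil(fraction · l)` random site columns (default 10%), zeroes them in
the training matrix — and hence in the interaction profiles — fits once,
and scores all held-out cells, repeated over seeded iterations with
per-iteration and pooled metrics.

Held-out sites in LmiTOCV have empty interaction profiles, so their
ranking rests entirely on the sequence-feature kernels.  On the planted
datasets those are weak by construction, and pooled LmiTOCV AUC sits
near chance — an honest reflection of what this model family can say
about sites with no training interactions, and the reason the LOOCV
recovery numbers are the headline result here.

AUC is the rank statistic `P(s⁺ > s⁻) + ½P(tie)`.  Accuracy,
sensitivity, specificity and MCC (0 when a marginal is empty) are
computed at a Youden-optimal threshold chosen on training-model scores,
never on the cross-validated test scores, and reported alongside the
threshold.  Scores are normalized per miRNA (unity rescaling; a constant
row becomes 0.5 with a warning) and classified by linear-interpolation
quartiles of the whole report population — strict `<` at Q25 and `>` at
Q75, everything between inclusive is Moderate; a per-miRNA quartile mode
is available behind a flag.

## Synthetic data

The generator plants the structure the method assumes.  Each family
draws a 7-nt seed; its miRNAs (22 nt) embed the seed at a random
position in uniform-random background with per-base mutation (default
5%); its sites (40 nt) embed the reverse complement in AU-enriched
background (A/U 0.35 each vs G/C 0.15), making the AU feature mildly
informative.  Positives are all within-family pairs; a fraction
(default 10%) is rewired to random out-of-family cells as label noise.
Wobble pairing, thermodynamically realistic duplexes and expression
effects are not simulated, so passing tests demonstrate recovery of
combinatorial interaction structure — not binding-energy realism or
performance on experimental data, where feature noise, extreme sparsity
and ascertainment bias are all harsher.  The default condition is
5 families × 20 miRNAs × 60 sites per family, seed 1.

## Problem sizes and defaults

λ defaults to 35, site length to 40 nt, accessibility window to 10 nt,
kernel weights to uniform.  Evaluation runs in the test-suite and the
acceptance script use seeded subsamples of a few hundred positive cells
with 5:1 negatives (a few thousand scored pairs), which keeps the
recovery experiments at AUC standard errors near 0.01 while a full run
over all positives remains available via `max_positives=None`.  The
permutation null uses 20 label shuffles with 40 positives each.
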