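# Methods

`fcdyn` analyses the *intrinsic dynamics* of time-resolved functional
connectivity: instead of asking which networks are active, it asks how a
subject's connectivity pattern moves through its own state space, and
whether summary measures of that movement scale with an ordered arousal
(consciousness-level) axis. This note documents the model, the
parameters that matter, the synthetic cohort generator, the numerical
choices, and the known limitations.

## Time-resolved connectivity

Parcellated BOLD (T timepoints x R regions, TR in seconds) is converted
to a sequence of connectivity matrices with a tapered sliding window:
window length W = 24 timepoints, step 1 timepoint, giving
N = floor((T - W)/step) + 1 matrices (122 for T = 145). Within each
window, correlation is the weighted Pearson coefficient under a Gaussian
taper centred in the window. The taper width defaults to sigma = W/6
(about 4 for W = 24), so the extremities of the window are strongly
de-weighted; sigma is configurable because only the taper's existence,
not its width, is pinned down by common practice. A window containing a
zero-variance region is flagged and rejected downstream rather than
silently zeroed.

An alternative estimator, instantaneous phase synchrony, band-passes
the signals (0.03-0.07 Hz, zero-phase second-order-sections Butterworth),
takes analytic-signal phases, and scores pairs by 1 - |sin(dtheta/2)|,
one matrix per timepoint. Ten timepoints per edge are trimmed by default
at the pipeline level to suppress filter transients; the trim length is
an artifact decision.

## The meta-matrix and temporal decay models

Each window's connectivity matrix is vectorised (strict upper triangle,
row-major) and all pairs are compared, by Pearson correlation (primary)
or Manhattan/cosine distance (alternatives), giving the N x N
**meta-matrix** (MM) — the similarity of every connectivity state to
every other, windows ordered in time. Distances are stored with an
orientation tag and negated wherever a "higher = more similar" reading
is required, so all directional measures are uniform across metrics.

The **temporal decay of similarity model** (TDSM) is a synthetic MM in
which similarity depends only on lag and decays monotonically: lag
profile u with u[n-1] = 1 at zero lag, either linear (u_i = i/(n-1)) or
exponential, u = exp(linspace(log(1e-4), log(1), n)/c) with c = 3
(slow) or c = 1.5 (fast). The model matrix is M[i,j] = u[(n-1)-|i-j|].
A subject's TDSM fit is the Pearson correlation between the strict upper
triangles of the MM and the model matrix. The trivially-1 diagonal is
excluded; whether to include it is not dictated by the construction, and
excluding it avoids an N-cell constant block that can only inflate fits.
High fit means the dynamics never revisit past states — similarity
falls off predictably with temporal distance.

For cohorts with heterogeneous scan lengths, every subject's
connectivity series is truncated to the cohort-wide minimum N (from the
start of the series) before MM construction.

The 2-D state-space embedding is classical (Torgerson) metric MDS of the
Euclidean distances between MM columns: double-centre the squared
distance matrix and keep the top eigenvector pair, coordinates centred
at the origin.

## Proximal and distal profiles

The first sub-diagonal of the MM is the similarity of consecutive
connectivity states (1 window step = 1 TR = 2 s at default); its
temporal series describes the local rate of state change. Multi-lag
variants average sub-diagonals 1..L aligned on their start index
(series length N - L); L in {1, 6, 13} covers transitions up to 26 s.

The **distal meta-matrix** (dMM) removes the k nearest lags and mirrors
the remaining off-diagonal triangle into a symmetric (N-k) x (N-k)
matrix: D[a,b] = MM[min(a,b), max(a,b)+k], diagonal undefined (left as
NaN, never back-filled). k defaults to 13 (just over half the window)
with 24 (a full window, no shared data) as a sensitivity setting. Each
dMM column is one state's profile of similarity to temporally distant
states; note that under the literal mirror construction a "column"
combines window c's distal past with window c+k's distal future. The
per-window full-profile reading is available by summarising the
vectorised cell set instead (`mode="vectorized"`).

Series are summarised by mean, median, standard deviation (population,
ddof=0), Shannon entropy, sample entropy, normalised effort-to-compress,
and the mean absolute first difference. dMM measures are computed per
column (cells ordered by row index, i.e. temporal order of the partner
windows; columns with fewer than 4 defined cells are skipped and logged)
and averaged across columns, plus the mean of each column's maximum
("how familiar is each state's closest distal neighbour").

## Complexity kernels

**Shannon entropy**: histogram over 10 equal-width bins spanning the
observed range, -sum p log2 p over occupied bins; bits; constant series
have entropy 0.

**Sample entropy**: SampEn = -ln(A/B) with Chebyshev template matching,
tolerance r = 0.2 x sd (so the measure is affine-invariant), template
lengths m+1 and m with m = 1 by default. A and B count ordered pairs
(i != j) over *all* templates of the respective length; the alternative
convention that truncates the shorter-template set to align counts
changes values by O(1/N) and neither convention is canonical here. A
constant series is defined as 0 and flagged; a zero count makes the
ratio undefined and propagates as NaN with a warning, never silently as
0 or infinity. Natural log, following the defining formula (Shannon
entropy uses log2; the bases are deliberately not harmonised).

**Effort-to-compress (ETC)** is the number of Non-Sequential Recursive
Pair Substitution (NSRPS) steps needed to reduce a symbol sequence to a
constant or single symbol, normalised by L-1. One NSRPS step counts all
overlapping adjacent pairs, picks the most frequent (ties broken by the
pair whose first occurrence starts earliest), and replaces its
occurrences greedily left-to-right, non-overlapping, with a fresh symbol
(the current alphabet size). This exact combination — overlapping
counting, greedy non-overlapping replacement, earliest-first ties — is
the only one consistent with the canonical worked example
00101101 -> 02212 -> 3212 -> 412 -> 52 -> 6 (5 iterations), which is
pinned by tests symbol-for-symbol. Real-valued series are symbolised
into 10 equal-width bins (maximum value assigned to the top bin) first.

## Structure-function dynamics

For each window, the FC matrix is proportionally thresholded to exactly
the structural connectome's edge count E (the E most positive
correlations by default; absolute-value ranking is available — sign
handling is an open choice and result tables record which was used),
then the thresholded FC and the structural weights are compared by
Pearson correlation on their vectorised upper triangles. The resulting
similarity-over-time series is summarised by sample entropy, normalised
ETC, and its maximum. Structural weights are used raw by default; a
log1p option exists for heavy-tailed streamline counts. Undefined
windows are dropped, not imputed. Tie-breaks in thresholding are
deterministic by (value, row, column).

## Ordinal inference

Per-subject measures are relation to ordered condition labels through a
proportional-odds cumulative-logit model, P(Y <= j | x) =
logistic(zeta_j - x'beta), fitted by maximum likelihood (statsmodels
`OrderedModel`). Predictors are z-scored by default so odds ratios are
per standard deviation — every result row records this flag, because OR
magnitudes are not comparable across scalings. Wald 95% intervals and
z-based p-values are reported; one-sided tests halve the two-sided p
when the estimated sign matches the declared direction. Reversing the
condition order flips beta's sign and maps OR to 1/OR exactly (at the
MLE), which is how "per step toward lower awareness" readings are
produced. With two or more predictors, variance inflation factors are
computed and a warning is issued above 5. No multiple-testing correction
is applied by default (a Benjamini-Hochberg helper is out of scope here;
see Non-goals in the module docstrings).

The proportional-odds assumption is checked by a likelihood-ratio test
between the parallel-slopes model and a relaxed cumulative model with
level-specific slopes, fitted on the same categorical likelihood by
derivative-free search (Nelder-Mead) started at the constrained
solution — the relaxed likelihood is only piecewise-smooth where
cumulative curves cross, which defeats gradient methods. The statistic
is referred to chi-square with (J-2) x p degrees of freedom. Under
proportional-odds data at n = 1000 the empirical size at the 5% level is
within about +/-2% (verified by simulation in the test suite);
non-convergent relaxed fits mark the check inconclusive rather than
significant.

Group contrasts use the two-sample rank-sum z test with normal
approximation and tie-corrected variance (exact-enumeration agreement is
verified for small groups); Spearman correlations quantify shared
variance between measures.

## Synthetic cohort generator

No generative model is inherited from the clinical setting; every
generator choice is an artifact decision, made once and documented here.

A subject is simulated as a piecewise-stationary Gaussian process:
first-order Markov regime labels (self-transition probability
1 - 1/mean_dwell, uniform switch targets) select among `n_states`
covariance states; covariances are blended linearly over
`transition_width` timepoints around switches; samples are AR(1)
smoothed (coefficient 0.4) and perturbed with iid noise (sd 0.3).
Each state covariance is a convex blend of

* a **structural component**: the communicability matrix
  expm(4 x SC/rho(SC)) of the subject's connectome, standardised to unit
  diagonal. Communicability is used because a scaled-adjacency-plus-
  identity covariance is neither guaranteed positive definite nor strong
  enough off-diagonal for coupling to matter; matrix-exponential
  communicability is the standard smooth structure-function kernel in
  network neuroscience and keeps the FC pattern strongly correlated with
  the connectome weights;
* a **random component**: a 3-factor model LL' + 0.1 I standardised to
  unit diagonal, fresh loadings per state.

The blend weight is the state's structure-function coupling. Coupling is
heterogeneous across states (fixed relative spread 0.25-1.75 around the
configured mean), so a subject's states differ in how tightly they track
the structural backbone — this is what gives the structure-function
similarity series its slow between-state swings. Independently, a
per-timepoint rank-1 "transient co-activation" component
(`state_jitter`) superimposes fast stochastic reconfiguration on the
slow regime structure.

Structural connectomes are random graphs with exactly
round(density x R(R-1)/2) edges and lognormal weights (heavy-tailed,
like streamline counts); density defaults to 0.3.

**Arousal mapping.** A cohort spans ordered conditions (least to most
aware; defaults UWS < MCS < SED < CON with 12/11/18/18 subjects,
mirroring the clinical group sizes). Condition rank maps linearly onto
four generator parameters:

| parameter        | least aware | most aware | reading                          |
|------------------|------------:|-----------:|----------------------------------|
| mean_dwell       | 32 TP       | 8 TP       | slower regime turnover            |
| transition_width | 14 TP       | 2 TP       | more sluggish state blending      |
| sc_coupling      | 0.40        | 0.12       | dynamics pinned to structure      |
| state_jitter     | 0.00        | 0.22       | fewer transient co-activations    |

The first three directions encode the planted hypotheses directly; the
jitter direction encodes fast, irregular reconfiguration as a signature
of wakefulness. The magnitudes were chosen during generator design so
that the planted contrasts are recoverable by the analysis pipeline at
the study's group sizes — recoverability is the generator's contract,
since the cohorts exist to exercise the pipeline end-to-end. With these
defaults, 20 independent cohorts reproduce each planted direction
(higher TDSM fit, higher proximal median in less-aware groups; higher
proximal sample entropy, distal ETC, and structure-function sample
entropy in more-aware groups) in at least 90% of cohorts.

Per-subject seeds derive from SeedSequence((base_seed, condition_index,
subject_index)); identical configuration and seed give bit-identical
output, with no global random state.

**What the generator does not emulate.** No hemodynamic response,
scanner noise spectra, motion, physiological confounds, spatial
autocorrelation of parcels, or subject-level covariates (age, lesion
load). Real BOLD also mixes continuous connectivity drift with regime
switching in ways this piecewise-stationary model only caricatures.
Passing recovery tests therefore shows the *pipeline* is sensitive to
the planted kinds of structure at clinical sample sizes — it does not
validate the clinical findings themselves, and the headline clinical
effect sizes (specific odds ratios, rho values, group z scores) are
deliberately not reproduction targets.

## Numerical choices and degenerate inputs

* Window indexing is 0-based; lags are in window steps (1 step = 1 TR).
* Meta-matrices are symmetrised exactly ((M + M')/2) and Pearson values
  clipped to [-1, 1] after floating-point round-off.
* Covariance blends that lose positive definiteness to round-off are
  repaired with escalating diagonal jitter (1e-10 to 1e-6, logged);
  failure after repair raises.
* Constant series: entropies are 0 (flagged); constancy is detected via
  the range, not the computed variance, to be robust to floating-point
  residue.
* Thresholding ties are resolved by (value, row, column) ordering.
* Proportional-odds predictors that are constant cannot be z-scored and
  raise immediately.

## Problem sizes

Default simulated geometry is 30 regions x 145 timepoints at TR = 2 s
(five covariance states), and recovery experiments use 20 cohorts of 59
subjects; these sizes were chosen so the full recovery suite and
statistical-calibration simulations run comfortably on a single CPU
while leaving the planted effects clearly resolvable. All generator and
pipeline parameters scale to the 100-300-region regime the file formats
anticipate.

## Known limitations

* **Proximal standard deviation.** The clinical finding that proximal
  similarity is *more* variable in less-aware subjects is not planted by
  this generator: under regime switching viewed through 24-point
  windows, spread and sample entropy of the proximal series are
  antagonistic (large smooth swings raise the sd but make the series
  predictable), and the generator prioritises the sample-entropy
  direction. The sd direction is reported but carries no directional
  guarantee here.
* The windowed FC pattern's correlation with the structural connectome
  is attenuated by finite-window estimation noise (mean r about 0.45 at
  full coupling); the population FC pattern correlates above 0.7.
* The relaxed cumulative model in the proportional-odds check can sit at
  a boundary (crossing cumulative curves just outside the data range);
  non-convergence there is reported as inconclusive.
* Sample entropy with m = 1 follows the reading that "template lengths 2
  and 1" means m = 1; m is exposed for the m = 2 reading.
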