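# Methods

## Setting

A bed-mat prototype embeds a 32 × 32 array of piezoresistive pressure
sensors (N = 1024 cells, voltages 0–5 V).  Scanning every cell takes about
0.2 s per frame; the frame rate limits how finely the respiratory waveform
— the per-frame sum of all cell voltages — is sampled.  Because the
scanning multiplexers can address any cell directly, the system can instead
acquire M ≪ N randomly chosen cells per frame and reconstruct the full
pressure image in software.  csmat implements that reconstruction chain and
everything needed to evaluate it: sub-sampling, basis-pursuit recovery,
an interpolation baseline, respiratory-rate extraction, the evaluation
statistics, and a synthetic data generator.

## Signal model and sparsity

Body-contact pressure images are smooth blobs, so they compress well under
the orthonormal type-II 2D discrete cosine transform,

    F(u,v) = α(u) β(v) Σ_x Σ_y f(x,y)
             cos[π(2x−1)(u−1)/(2P)] cos[π(2y−1)(v−1)/(2Q)],

with α(1) = √(1/P), α(u) = √(2/P) for u ≥ 2 (β likewise with Q).  `dct2` /
`idct2` delegate to `scipy.fft.dctn` / `idctn` (`norm="ortho"`), which
realize exactly these weights.  The practical sparsity S counts
coefficients whose magnitude is at least a threshold fraction of a
reference maximum; coefficients below the threshold are treated as zero,
and exact ties are kept (the rule zeroes only what is *less than* the
threshold).  The reference maximum may be the per-image maximum or a fixed
corpus value (`CORPUS_REFERENCE_MAX = 2.85e3`, the published corpus-average
maximum coefficient of body-part images from this mat); both conventions
are supported because the published table does not say which was used.
Numerical compressed-sensing practice is that most S-sparse signals are
recovered exactly from about m ≥ 4S random measurements; `min_samples_rule`
returns 4S.

## Sampling and the sensing matrix

An `AddressPlan` is an ordered list of M *distinct* 1-based cells
(x_m, y_m).  Three generators exist:

* `uniform` (default) — without-replacement uniform draws.  Duplicate
  addresses would waste measurements, so this is the default even though
  the original microcontroller generator is described differently.
* `gaussian_prng` — rounded bivariate-normal draws centered on the mat
  (σ = P/4), de-duplicated by redraw; emulates a center-weighted hardware
  generator.
* `latin_hypercube` — `scipy.stats.qmc.LatinHypercube` points scaled onto
  the grid, de-duplicated by redraw; stratifies rows and columns, matching
  the post-sampling experimental design.

Row m of the sensing matrix A = ΦΨ evaluates every DCT basis function at
the sampled cell, so `A @ vec(F)` reproduces the sampled voltages; columns
are flattened row-major over (u, v), and this ordering is recorded on the
`SensingMatrix` so coefficient vectors are unambiguous.  With M = N the
plan is a permutation and A is orthogonal.

The acquisition-time model reflects that each sub-sampled point is
transmitted together with its address: a full scan takes `t_full = 0.2 s`;
sub-sampling only pays off below the break-even of 512 points; below it,
every 100 points removed saves 20% of `t_full` (so M = 300 gives
0.1152 s per frame, a 42.4% saving).  The linear rule extrapolates to
nonpositive time near M = 0, so predicted time is floored at 5% of
`t_full`.

## Basis-pursuit solver

Reconstruction solves min ‖z‖₁ s.t. Az = b.  The L1 objective is lifted
with slacks μ (−μ ≤ z ≤ μ), giving 2N inequality constraints
f₁ = z − μ ≤ 0, f₂ = −z − μ ≤ 0 with multipliers λ ≥ 0 and equality
multipliers ν.  A primal–dual interior-point iteration applies Newton's
method to the relaxed KKT residual

    r_τ = [ ∇f₀ + Df(z)ᵀλ + Ãᵀν ;  −diag(λ) f − (1/τ)𝟙 ;  Az − b ],

where the complementary-slackness relaxation λ_l f_l = −1/τ smooths the
central path.  Implementation choices (the source names none of these, so
they follow standard interior-point practice and are exposed on
`SolverConfig`):

* **Initialization** — z₀ = Aᵀ(AAᵀ)⁻¹b (minimum-norm feasible point);
  μ₀ = max(0.95·|z₀| + 0.10·max|z₀|, floor) with floor 10⁻³·max|z₀|
  (10⁻³ when b = 0) so the start is strictly interior; λ = −1/f, ν =
  −A(λ₁ − λ₂).  Starting feasible keeps Az = b (up to round-off)
  throughout, since Newton steps preserve the equality block.
* **Barrier schedule** — τ = 10 · 2N / η with η = −fᵀλ the surrogate
  duality gap; the gap shrinks roughly tenfold per iteration.
* **Newton reduction** — eliminating (Δλ, Δμ) yields an M × M SPD system
  (A diag(1/σ_x) Aᵀ) Δν = rhs with σ_x = 4 (λ₁/f₁)(λ₂/f₂)/σ₁ computed in
  that cancellation-free form (the naive σ₁ − σ₂²/σ₁ underflows near
  convergence).  The Gram matrix is built with a BLAS symmetric rank-k
  update and solved by Jacobi-scaled Cholesky; if the factorization fails
  (extreme barrier values), an LDL solve is tried, and if that also fails
  the solver returns the last strictly interior iterate.
* **Line search** — the step is first capped at 0.99 of the longest step
  keeping λ > 0 and f < 0, then backtracked (factor 0.5) until ‖r_τ‖
  decreases by (1 − 0.01·s).
* **Stopping** — η < `gap_tol` (default 10⁻³) or `max_iters` (default 50);
  hitting the cap flags the result (`converged=False`) and warns rather
  than failing silently.

Tolerance guidance: 10⁻³ is ample for frame display and error-rate work;
exact-recovery experiments use 10⁻⁸; waveform pipelines use 10⁻² (see
below).  An independent exact reference, `solve_l1_linprog`, solves the
positive-split LP (min 1ᵀ(z⁺+z⁻) s.t. Az⁺ − Az⁻ = b) with
`scipy.optimize.linprog`/HiGHS and shares no code with the interior-point
path; the test suite checks objective agreement on seeded instances.

`reconstruct_frame` assembles A from the plan, solves for z, and inverse
transforms.  Basis pursuit leaves faint speckle in unloaded mat regions
(small nonzero values where the true pressure is zero); the optional
`cleanup` step zeroes negative cells and cells below 1% of the frame
maximum.  Cleanup defaults to **off** so metrics are computed on raw
reconstructions; it is intended for display.

## Interpolation baseline

`interpolate_frame` Delaunay-triangulates the sampled cells and applies
barycentric linear interpolation (`scipy.interpolate.griddata`); grid cells
outside the convex hull take the nearest sampled value.  The baseline is
exact at sampled cells and reproduces affine fields inside the hull.
Collinear sample sets raise a degenerate-geometry error.  Triangulations of
regular grid subsets are not unique; any valid triangulation is accepted —
the exactness properties are unaffected.

## Respiratory chain

The waveform is the per-frame cell-sum with frame timestamps.  The analysis
convention is valleys = end-inhalation: supine (back/waist) recordings pass
through, prone (chest/abdomen) recordings are flipped about their mean
(`orient_waveform`, an involution).  Smoothing uses a cubic smoothing
spline minimizing p·Σ residual² + (1−p)·∫ s″², implemented via
`scipy.interpolate.make_smoothing_spline` with λ = (1−p)/p so the
conventional p parameter (default p = 0.96812749, the published value)
keeps its meaning; p = 1 interpolates, p = 0 is handled as the
least-squares line.

Valley detection (`scipy.signal.find_peaks` on the negated series) uses
two physiological guards that the source does not specify and are
config-exposed: prominence ≥ 10% of the epoch's peak-to-peak range, and
separation ≥ 1.5 s (capping detectable RR at 40 breaths/min).  A
numerically flat epoch (span below 10⁻⁹ of the signal scale, e.g. spline
round-off on constant input) yields no valleys rather than noise-driven
ones.  Epochs are half-open 30-s intervals [start, start+30); a trailing
partial epoch is dropped and logged.  RR per epoch is 60/INT with INT the
mean successive-valley interval, which telescopes to
(t_last − t_first)/(n−1); epochs with fewer than two valleys raise a
flagged error and are excluded (with counts recorded) by the pipeline.

## Metrics

* Image error rate: per image Σ(f* − f)² / Σf², averaged, *without* a
  square root — exactly the published form (0 = perfect, 1 = zero
  estimate, scale-invariant).  A square-rooted variant exists as
  `relative_rmse` but feeds no standard report.
* Waveform agreement: Pearson correlation after both series are linearly
  resampled onto the union of their sample times within the common
  support (reconstructed and reference waveforms generally have different
  time grids).  The named statistic is not specified in the source;
  Pearson is the conventional reading.
* RR accuracy: per epoch 1 − (RR_est − RR_ref)²/RR_ref², averaged,
  reported in percent.  Sample SD (ddof = 1) accompanies every mean.

## Synthetic data

`gen_phantom` renders sums of anisotropic Gaussian blobs (presets for
back, waist, chest, abdomen laid out on the 32 × 32 grid) plus baseline
and per-sensor additive Gaussian noise, clipped to [0, 5] V.  Defaults are
fixed study conditions: noise SD 0.02 V (a quiet sensor on a 0–5 V scale)
and breathing modulation depth 0.2 — respiration scales all blob
amplitudes by 1 + 0.2·sin(2π(RR/60)t + φ), with fresh noise per frame, so
the total pressure is a noisy sinusoid at the true rate.  The noiseless
presets put ≥ 95% of their energy in the top 60 DCT coefficients,
matching the approximate-sparsity premise.

What the generator does *not* emulate: posture changes, movement
artifacts, sensor hysteresis and creep, the spatially correlated noise of
real electronics, and the sharper pressure gradients of bony prominences.
Passing tests therefore demonstrate the correctness and the qualitative
behavior of the method (error falls with M; CS beats interpolation; RR is
recoverable through the fore-sampling chain), not clinical accuracy on
human recordings, whose absolute error rates are substantially higher than
the phantoms'.

## Pipelines and problem sizes

`run_frame_experiment` / `run_error_sweep` implement the post-sampling
(PSCS/PSI) image experiments: per frame, draw a plan (deterministic child
seeds from the experiment seed), sub-sample, reconstruct, score.
`run_rr_experiment` implements the fore-sampling (FSCS/FSI) chain with the
frame period supplied by the acquisition-time model (0.1152 s at M = 300)
and per-frame random plans, as the hardware would draw them.  PSCS and
FSCS share the identical per-frame reconstruction; only ground-truth
availability and frame timing differ.

Within waveform pipelines the per-frame solver runs at `gap_tol = 1e-2`
(`WAVEFORM_SOLVER`): a waveform point is a whole-frame voltage sum,
dominated by the lowest DCT coefficients, which are pinned far more
tightly than the duality gap suggests, and thousands of frames are solved
per recording.  Evaluation sizes are likewise the package's desk-scale
choices: error sweeps use 50 phantoms (tests) or 20 (acceptance script)
over M ∈ {100,…,500} instead of thousands of recorded images, and RR runs
use 10–12 synthetic epochs per experiment instead of hour-long
recordings; counts are arguments throughout.

## Known limitations

* The solver assumes A has full row rank (guaranteed for distinct-cell
  plans of a full DCT basis in exact arithmetic; rank failures raise a
  plan-regeneration error).
* The dense M × N sensing matrix limits practical grids to a few thousand
  cells; no operator-form (FFT-based) path is provided.
* Valley detection is threshold-based; waveforms whose noise power
  approaches the breathing modulation will produce spurious or missed
  valleys, which the pipeline only partially mitigates by flagging
  low-valley epochs.
* The 0–255 normalization is display-only post-processing; no ADC model
  is implied.
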