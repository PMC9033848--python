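# Methods

This note documents the models and numerical choices behind `frpbp`: what
is computed, which parameters matter, and what the synthetic experiments do
and do not demonstrate.

## Phase-space embedding

A segment `x_1..x_L` is delay-embedded with dimension `m_e` and delay `τ`
(samples): state `p` is `(x_p, x_{p+τ}, …, x_{p+(m_e−1)τ})`, giving
`N = L − (m_e − 1)τ` states in temporal order. Defaults are `m_e = 3`,
`τ = 5` samples (40 ms at 125 Hz) — standard practice for pulse waveforms,
where the delay spans a meaningful fraction of the systolic upstroke without
decorrelating neighbouring states. Automatic selection (mutual information,
false nearest neighbours) is deliberately out of scope; both parameters are
plain config values.

The recurrence-plot side length is a modelling parameter, so the trajectory
is reduced to exactly `S` states by **uniform index decimation**:
indices `round(linspace(1, N, S))` (half-up rounding, 1-based, then shifted
to 0-based). This keeps the plot a true state-similarity matrix — image
interpolation would average similarities of unrelated state pairs. The
default side is 88; 89 and other sizes are reachable through configuration.
Windows default to 1024 samples (~8.2 s at 125 Hz, several beats of
recurrence texture) with non-overlapping stride.

## Fuzzy c-means

FCM minimises `J(U, Z) = Σ_i Σ_k μ_ik^ω d(x_i, z_k)²` subject to row sums
`Σ_k μ_ik = 1`, alternating

* memberships `μ_ik = 1 / Σ_j (d_ik / d_ij)^(2/(ω−1))`,
* centers `z_j = Σ_i μ_ij^ω x_i / Σ_i μ_ij^ω`,

until `max |U(t) − U(t+1)| ≤ α` or `max_iter` is reached (then the result is
flagged unconverged, not raised). Defaults: `c = 3` clusters (coarse texture,
the common choice in the fuzzy-recurrence literature), `ω = 2`, `α = 1e−5`,
`max_iter = 300`, seeded random row-normalised initial memberships.

Numerical details:

* **Zero distances.** A state within `1e−12·max(1, ‖x‖_∞)` of a center gets
  crisp membership there (lowest cluster index on ties). The relative
  tolerance matters: for a constant segment all states coincide with every
  center only up to float rounding, and without it the update would settle
  on the uninformative uniform partition instead of the crisp one.
* **Emptied clusters.** A crisp assignment can strip a cluster of all
  membership (again the constant-segment case). Inside `fcm_fit` such a
  cluster keeps its previous center and the partition is flagged
  `degenerate`; the standalone center update raises instead, since a caller
  invoking it directly has no sensible previous center to fall back on.
* The objective is non-increasing across iterations (asserted in tests to
  1e−9) and `J` is invariant under cluster relabelling.

## Recurrence plots

Binary plot: `R_ij = 1` iff `‖r_i − r_j‖₂ < ε` (strict inequality at exactly
`ε`; the boundary is measure-zero). Fuzzy plot: max–min composition
`M_ij = max_k min(μ_ik, μ_jk)`, diagonal set to 1 explicitly (reflexivity is
an axiom of the fuzzy relation, not a numerical consequence), symmetrised to
kill float asymmetry below 1e−12. The network consumes `M` directly;
inversion (`1 − M`) exists only as a rendering option for white-background
PNG export, where 8-bit quantisation bounds the round-trip error by 1/255.

## Two-stream network

* **1-D stream** (raw window, shape `1×L`): six conv blocks with kernel
  length 25 everywhere, filters 32-32-64-64-128-128, each conv followed by
  batch norm and ReLU; average pooling (factor 2) after blocks 1–4; dropout
  0.25 after blocks 5–6; flatten.
* **2-D stream** (FRP, `1×S×S`): exactly seven 3×3 conv blocks, filters
  16-32-32-64-64-128-128, batch norm + ReLU each; 2×2 average pooling after
  the first five ReLUs only (side 88 shrinks 88→44→22→11→5→2 under floor
  halving, so sides below 32 are rejected); flatten.
* **Fusion.** Stream outputs are flattened vectors, so co-located fusion
  acts on channels at a single spatial position: concatenation (default)
  stacks both feature vectors; sum/max require equal widths; conv fusion is
  a learnable 1×1 map from the `2N` stacked channels back to `N`. The
  general `fuse()` operator on `(H, W, N)` feature maps implements the same
  four rules with an explicit filter bank.
* **Head:** dense 256 → ReLU → dropout 0.25 → dense 64 → ReLU → dense 1
  (linear). One model per target (SBP or DBP).

The exact per-layer filter counts are configurable; the defaults above widen
monotonically with depth and keep the model CPU-trainable. A reduced profile
(`ModelConfig.small()`: window 512, side 32, filters 8…32 / 4…32) is what
the package's own experiments and the acceptance script use; it was sized
once from arithmetic-cost estimates for a single CPU, and all reported
numbers come from it unless stated otherwise.

All layers are implemented on numpy: same-padded stride-1 convolutions via
im2col + GEMM, with input gradients computed as convolutions with the
transposed, kernel-flipped filter bank; batch normalisation with running
statistics (momentum 0.9, ε = 1e−5); floor-semantics average pooling;
inverted dropout with a layer-owned seeded generator. Every layer's
analytic gradient is verified against central differences in the test suite.

## Training

MSE loss, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch 100, learning rate
0.001, up to 300 epochs. Because validation loss flattens and then degrades
with long training, early stopping on validation loss (patience 30) with
best-weight restoration is built in. Two normalisations stabilise the
optimisation and are part of the model contract: raw windows are z-scored
per segment (the waveform's offset and gain carry no pressure information in
this formulation), and targets are z-scored on training-set statistics,
inverted at prediction time. A non-finite loss aborts with diagnostics
rather than silently producing NaN weights. Runs are fully seeded — weight
initialisation, dropout masks and batch order all derive from the one seed —
so duplicate runs are bitwise identical.

## Synthetic records

Each beat is a two-Gaussian template over the beat phase: a systolic wave of
amplitude `a0 + a1·(SBP − 120)/40` at 30% phase (width 10%) and a dicrotic
wave of amplitude `b0 + b1·(DBP − 80)/30` at 65% phase (width 15%), with
`a0=1.0, a1=0.5, b0=0.4, b1=0.3`. Beat period is `60/HR` s, HR jittered per
beat (mean 75, SD 3 bpm). SBP and DBP follow per-beat bounded random walks
(reflection at the bounds 90–180 / 50–110 mmHg; steps 1.5 / 1.0 mmHg, pulse
pressure floored at 10 mmHg). Sinusoidal baseline wander (amplitude 0.1,
0.2 Hz) and white Gaussian noise (SD 0.02) are added; sampling is 125 Hz.
Per-sample label series accompany the waveform, and a window's scalar label
is the mean over the window.

The coupling coefficients are artifact choices — real photoplethysmography
has no closed-form BP→morphology law — chosen once so that pressure is
recoverable in principle at realistic signal-to-noise. Consequently, passing
end-to-end tests demonstrates that the pipeline can extract a morphology-
encoded pressure signal through the FRP + CNN machinery; it does **not**
demonstrate clinical accuracy on ICU waveforms, where the PPG–BP
relationship is weaker, non-stationary and subject-dependent. Splits are
chronological within each record (first 70% train, next 10% validation,
last 20% test, floor counts with the remainder to test), so no window leaks
across splits; a strict subject-held-out mode (whole records held out) is
available behind a CLI flag for leakage-free evaluation, without any claim
of equivalence to the per-record protocol.

## Evaluation conventions

With errors `e_i = Y_i − Ŷ_i`: MAE, MSE, ME are means of `|e|`, `e²`, `e`;
R² is `1 − SSres/SStot`; R is Pearson correlation of targets and estimates;
STD is the **population** standard deviation of the errors, so
`MSE = STD² + ME²` holds as an identity (this error-spread reading is what
the "MAE ± STD" and AAMI usages require). R — and R² for a constant target —
is flagged undefined on constant inputs, never silently zeroed. BHS bands
use inclusive bounds (`|e| ≤ 5/10/15` mmHg), and a grade requires all three
band thresholds simultaneously; the AAMI mean-error bound is two-sided
(`|ME| ≤ 5`). Bland–Altman differences are estimate minus reference, and the
limits of agreement use the sample SD (ddof = 1), the convention of
agreement analysis; the within-limits fraction uses inclusive bounds.

## Known limitations

* The generator's idealised morphology makes the regression easier than on
  clinical data; reported synthetic-corpus numbers quantify pipeline
  correctness, not device-grade accuracy.
* FCM is restarted from one seeded initialisation per segment, not
  multi-restarted; occasional convergence to a poorer local optimum changes
  individual plots slightly but is deterministic under the seed.
* Batch normalisation requires batch size ≥ 2 during training.
* The conv-fusion and sum/max-fusion network variants require equal stream
  widths and are therefore only usable with matching configurations;
  concatenation, the default, has no such restriction.
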