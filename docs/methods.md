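# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `myoscreen`. Everything quantitative below is computed by the
test suite or the acceptance script; nothing is asserted that the code does
not reproduce.

## 1. Synthetic transient generator

A paced record is a baseline plus one deflection per stimulus,

```
g(t) = k · (1 − e^{−(t−ts)/τr}) · e^{−(t−ts)/τd},   t ≥ ts
```

with `k` chosen analytically so the peak deflection equals
`amplitude_frac × baseline` (the stationary point of the kernel is
`t* = τr·ln(1 + τd/τr)`, giving a closed-form peak height). Contraction
signals deflect downward from resting sarcomere (or cell) length; Ca²⁺
ratio signals deflect upward from a baseline ratio of 1. Noise is i.i.d.
Gaussian per sample; photobleaching and motion artifacts are out of scope.
Defaults: 1000 Hz sampling (camera-class temporal resolution), 10 s records,
stimulus onset 0.1 s into each pacing period.

**Species profiles** (`profiles.py`, versioned, explicitly generator
defaults rather than measurements) are seeded from published species means:
rat resting sarcomere length 1.826 μm and 3.67 % shortening, mouse 2.54 %,
guinea pig 5.21 %, Ca²⁺ F/F0 of 1.136/1.143/1.196 for rat/mouse/guinea pig.
The kinetic constants (τr, τd) were solved offline against a 100 kHz
dense-grid evaluation of `g` so a noiseless generated beat reproduces the
published TTB90 exactly.

*Limitation:* the two-exponential family cannot produce every
(TTP90, TTB90) pair — its TTP90/TTB90 ratio is bounded at ≈0.147, whereas
published contraction kinetics reach 0.16–0.36 (real upstrokes are
sigmoidal). Contraction profiles therefore fix the rise:decay ratio at 1:4
and match TTB90 exactly, accepting a shorter TTP90; Ca²⁺ profiles are exact
for rat and mouse, while guinea-pig Ca²⁺ (ratio at the family boundary) uses
τr = τd. Kinetics-recovery tests compare against the dense-grid oracle for
the *configured* taus, which is exact; only the absolute printed TTP90 values
for contraction are not reproduced by the generator.

**Nested datasets** draw preparation means `m_i ~ N(μ, σb²)` and cell values
`~ N(m_i, σw²)`; the implied ICC is `σb²/(σb²+σw²)`. The full nested record
generator converts sampled per-cell amplitudes into complete traces so the
analysis chain can be tested end-to-end; its default between/within spread
(10.6 % / 22.2 % of the mean amplitude) implies ICC ≈ 0.185, the clustering
level reported for rat % sarcomere shortening.

**Field images** render each cell as a rotated rounded rectangle (corner
radius = width/4) whose interior intensity is modulated sinusoidally along
the long axis at the striation period; this is sufficient for the finder,
detector and spectral code under test but is *not* realistic cell texture —
rendered rods have solidity ≈ 0.98 versus ≈ 0.86 for real rat cells, so
solidity-based conclusions transfer only qualitatively.

All generators consume explicit integer seeds (spawned from one root
`SeedSequence` in the CLI and the acceptance script); identical spec + seed
is bit-identical.

## 2. Transient analysis

Beats are segmented at stimulus times when available, each window starting
10 % of a pacing period before its stimulus so the averaged beat carries a
pre-onset baseline segment. Without stimulus metadata the pacing period is
taken from the record's autocorrelation peak and the onset phase from the
period-folded mean waveform (steepest deflection, backed off to the last
sub-5 % sample). Averaging is the pointwise mean of stimulus-aligned beats,
truncated to the shortest.

From the averaged beat: baseline = mean of the pre-onset window; peak =
vertex of a parabola through the 5 samples around the extreme deviation
(sub-sample accuracy); % shortening = 100·(baseline−peak)/baseline
(upward-signal analogue for Ca²⁺, where F/F0 = peak/baseline is also
reported). TTP90 is the 10 %→90 % rising-phase crossing interval and TTB90
the time from the peak to 90 % recovery, both located by linear
interpolation between bracketing samples. With the stimulus onset sharp
relative to the rise these conventions agree with "time from 10 % of peak"
and "time to 90 % of peak from baseline" readings. Relaxation τ comes from a
least-squares single exponential on the peak→90 %-recovery segment; a double
exponential is retained only when it reduces the SSE by ≥ 5 %.

A beat is **non-contractile** when its peak deflection is below
`max(0.5 % of baseline, 3 × pre-onset residual SD)` — a threshold the source
instrumentation does not document, chosen so that noiseless flat traces and
noise-only wander are both excluded. Non-contractile cells report
% shortening = 0 (so population means are unbiased) and missing kinetics
(rate parameters are undefined without contraction).

## 3. Image analysis

**Cell finder.** Gaussian smoothing (σ = 1 μm, below the sarcomere period so
striation texture is suppressed but edges survive) → Otsu threshold →
morphological opening (disk radius 2 px) → connected components → area
window 1000–6000 μm², aspect-ratio (minor/major moment axis) window 0.1–0.5
→ mutual-proximity exclusion: any two candidates whose masks are closer than
40 μm (distance-transform gap test) are *both* discarded. Output is capped
at 50 masks ranked by area (acquisition order is a hardware behaviour the
pipeline does not model). The finder is invariant to affine grayscale
transforms (threshold and smoothing are relative operations).

**FFT sarcomere length.** The intensity is sampled on a rotated grid along
the mask's long axis (bilinear interpolation, width-averaged inside the
mask), mean-removed, Hann-windowed, zero-padded 8×; the maximum of the power
spectrum inside the physiological 1.4–2.4 μm band (bracketing all published
resting sarcomere lengths) is refined by parabolic interpolation of
log-power. A peak below 3× the in-band median power raises "no striation
detected". On noiseless rendered cells the error is < 0.001 μm at any
orientation; over 50 noisy renders the mean error is < 0.005 μm.

**Cell length.** When striations are unclear: the unmasked axial profile
(extended 30 % beyond the mask) is smoothed (σ = 0.5 μm) and the distance
between the outermost crossings of the half level — midway between tail
background and the central plateau median — is returned. Residual bias from
smoothing the rounded-end taper is ≈ −0.6 μm on a 133 μm rod (within the
±1 μm working tolerance).

**Morphology.** Area, perimeter, moment-ellipse major/minor axes,
eccentricity and solidity come from `skimage.measure.regionprops`, scaled by
the calibration; sarcomere length is attached from the FFT detector. Note
that moment-ellipse "length" of a uniform rod exceeds its physical length by
up to 2/√3; the edge-based detector measures physical length.

**Spectral profile.** The masked, Hann-windowed bounding-box region is
2-D-FFT'd (2× zero-padding per axis) and the power summed in annuli of
radial spatial frequency, giving power versus wavelength integrated over
orientation; the dominant 1.4–2.4 μm peak and its prominence (peak over
in-band median) quantify sarcomere organisation. Agrees with the axial FFT
detector within 0.05 μm on the same cell.

## 4. Hierarchical statistics

The one-way random-intercept REML criterion is profiled to a 1-D problem in
λ = σb²/σw²: given λ, the GLS mean, the profiled σw² and the REML correction
all have closed forms, and the criterion is minimised over log λ ∈ [−14, 10]
(bounded Brent), with the λ = 0 boundary checked explicitly. This is exact
REML for the balanced and unbalanced two-level layout (verified against
statsmodels `MixedLM` in the tests) and runs in well under a millisecond,
which makes the 2000-replicate type-I-error simulations cheap. The ANOVA
method-of-moments estimator (negative σb² clipped to 0) is provided as a
cross-check; on balanced designs the two coincide.

The grand mean is the precision-weighted mean of cluster means,
`w_i = 1/(σw²/m_i + σb²)`, with SE `(Σw)^{-1/2}`. Effective degrees of
freedom use Satterthwaite's approximation applied to the two
variance-component contributions of `Var(grand mean)` with (k−1) and (n−k)
component df; for balanced data with non-trivial ICC this collapses toward
k−1, reproducing the phenomenon that hundreds of cells from a handful of
hearts carry only a few independent degrees of freedom. Two-group
comparisons combine the group SEs and Satterthwaite-combine the two
effective df; the conventional (independence-assuming) t-test is always
reported alongside. **Suitability** is called "hierarchical" when a REML
likelihood-ratio test of σb² = 0 against the half-χ²₁ mixture rejects at
α = 0.05 in either group — an operationalisation chosen here; the upstream
implementation's exact rule and df formula are not published, so numeric
agreement with it is not claimed. No multiple-testing correction is applied.

Calibration (2000-replicate null simulations, 5 preps × 45 cells): at
ICC 0.2 the conventional t-test rejects at ≈ 0.55 while the hierarchical
test stays within [0.03, 0.07] at α = 0.05; at ICC 0 both sit at ≈ 0.05.

*Known estimator property:* the sampling distribution of the estimated ICC
with few clusters is strongly right-skewed (the between-cluster variance
estimate has only k−1 df), so its **median** underestimates the true ICC:
with truth 0.185 at 5×45 the median estimate is ≈ 0.157; with truth 0.309 at
3×50 it is ≈ 0.228 (REML, ML and method-of-moments coincide here; verified
against statsmodels). Mean estimates are less affected. Tests that assert
median recovery at 3 clusters to better than ~8 percentage points will fail
for *any* standard estimator; this is a property of the design, not of the
implementation.

## 5. Pharmacology

The three binding-equation forms (Hill coefficient fixed at 1 — the source
equations are hyperbolic) are fitted by `scipy.optimize.curve_fit` on
dose-level means, weighted by 1/SE² (the `weighted` flag can disable this;
noiseless data fall back to unweighted). Dose 0 is included as an anchor.
Parameters are constrained positive; standard errors come from the Jacobian.
A fit whose EC50 exceeds 10× the top tested dose is flagged **unfittable**
rather than reported — the saturation plateau is outside the tested range,
as happens for near-linear dose responses. A dose trend contradicting the
requested form beyond 3× the dose-mean SE raises a warning.

Screens report the fractional change `100·(treated mean/baseline mean) − 100`
per parameter; zero-shortening cells are included in the % shortening means
(avoiding selection bias toward contracting cells) and excluded from
TTP90/TTB90 means. Replicate screens are aggregated by expressing each
treated cell relative to its own preparation's baseline mean and routing the
pooled per-cell fractional data through the two-level fit, reporting simple
and cluster-corrected summaries side by side and flagging compounds whose
significance call flips.

Monte-Carlo recovery at the profile settings (6 log-spaced doses + 0 anchor,
20 cells/dose, noise 5 % of y0, 200 seeds): median fitted EC50 within ~2 %
of truth for the full-inhibition (0.8 μM) and decrease (0.14 μM) profiles,
and within ~1 % for the increase profile (3.1 μM, maximal effect
100·Bm/y0 = 216 %).

## 6. I/O and reproducibility

Traces travel as tidy long CSV (cell_id, prep_id, condition, dose_um,
time_s, signal, signal_kind), written with `%.17g` and read with pandas'
round-trip float parser, so numeric round trips are bit-exact. Images are
16-bit TIFF with a JSON calibration sidecar (float renders are quantised to
integer gray levels on write). Statistical reports are JSON with a
simple-statistics and a hierarchical-statistics block per parameter. The CLI
derives all stage seeds from one root seed via `numpy.random.SeedSequence`;
two runs with identical config and seed produce byte-identical tables. Runs
log the resolved configuration, a config hash and the package version.

## 7. What a green test establishes — and what it does not

The synthetic world has Gaussian noise, exactly periodic pacing, ideal
rod-shaped cells and exactly hyperbolic dose responses. Green tests
establish that the extraction, detection, estimation and fitting machinery
is correct and calibrated *under those assumptions*. They do not establish
robustness to arrhythmic beats, motion or focus artifacts, non-Gaussian
noise, partial striation disorder, or receptor pharmacology beyond the
hyperbolic family — all explicitly out of scope.
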