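# Methods

## 1. Cusp-patterning model

### Equations and rationale

Tooth cusps form where enamel knots differentiate; knots are
non-proliferative signalling centres, and the differential growth of the
surrounding epithelium turns the knot pattern into relief.  The
simulator reduces this to a Gierer–Meinhardt-type activator–inhibitor
pair on a growing one-dimensional anterior–posterior strip (the axis
along which all the cusp counts of interest are read).  Per iteration,
with unit cell spacing and explicit-Euler time stepping:

    a ← a + act·a²/((1 + inh·i)(1 + kap·a²)) + bas − dega·a + da·∇²a
    i ← i + sec·(K + (1−K)·a²)                − deg·i  + di·∇²i

with zero-flux boundaries at the active-domain edges, both fields
clamped at zero, and `K` the knot indicator.  Design points:

* **Saturation (`kap`)** caps the activator amplitude.  Without it, a
  stronger activator makes each peak export *more* inhibitor, so raising
  `act` paradoxically suppresses lateral cusps.  With saturation, `act`
  controls where and how fast peaks ignite, not how much inhibitor a
  mature peak produces — recovering the expected phenomenology
  (activator up → more cusps; inhibition up → fewer).
* **Knot freezing and secretion.**  A cell whose activator exceeds the
  differentiation threshold (1.0 after nondimensionalisation) joins `K`
  irreversibly; its activator is frozen, pinning the pattern against
  domain growth, and it secretes the inhibitory signal at the full rate
  `sec` regardless of its frozen activator level.  Undifferentiated
  cells secrete in proportion to `a²`.
* **Two turnover rates.**  `deg` is the turnover of the secreted
  diffusing signal: its decay length √(di/deg) sets cusp spacing, so
  raising degradation packs cusps more tightly.  The activator's own
  turnover `dega` (an additional network constant, default equal to
  `deg` when unset) governs excitability.  Without this split, raising
  `deg` simultaneously kills activator ignition (basal saddle-node
  ∝ 1/deg²) and the documented "degradation up → extra cusps" response
  is unreachable.
* **Differential growth frame.**  Height is measured relative to the
  proliferating cervical base: knot cells rise at `pro` per iteration,
  non-knot cells stay at base level.  This is the same physics as
  "non-knot cells grow downwards" expressed in the frame where cusps
  are maxima; it also makes the primary cusp (earliest knot) tallest,
  as in real teeth.
* **Initial condition.**  Activator 0.05 on the three central cells of a
  `bwi`-wide site, zero elsewhere, no noise unless a seeded noise
  amplitude is set (`noise` extra key).  A three-cell seed keeps seed
  ignition robust across the swept `act` range; a one-cell seed loses
  half its mass to diffusion in the first steps and makes the no-tooth
  boundary jumpy.
* **Growth.**  The active domain widens by `bgr` cells/iteration, split
  anterior:posterior as `bia`:1.  Cells enter with zero fields.
  Stability guard: `da`, `di` ≤ 0.5 (CFL for unit spacing).

### Parameters and presets

| name | meaning | shark baseline |
|------|---------|----------------|
| act  | activator autoactivation rate | 1.2 |
| inh  | inhibition strength of activator | 10.4 |
| deg  | secreted-signal turnover | 0.03 |
| dega | activator turnover (extra) | 0.03 |
| da / di | activator / signal diffusion | 0.01 / 0.4 |
| sec  | knot secretion rate | 0.3 |
| bas  | basal activator production (extra) | 4.5e-4 |
| kap  | autoactivation saturation (extra) | 0.15 |
| bwi  | initial tooth-site width (cells) | 15 |
| bgr  | border growth rate (cells/iter) | 0.005 |
| bia  | anterior–posterior growth bias | 1.0 |
| pro  | knot elevation rate | 0.001 |

The published parameter sets this package mirrors exist only inside the
original simulator's supplementary material, and the two prose mentions
of the Act/Inh magnitudes contradict each other; the presets here are
therefore **phenotype calibrations**, tuned once so that the shark
baseline meets the documented contract and then frozen:

* baseline → tricuspid at 11,000 iterations;
* act ×1.1 (alone or with deg ×1.1–1.3) → 5 cusps;
* act ↓ → unicuspid (×0.6–0.7) and only later no-tooth (×≤0.5);
* inh ↑ → unicuspid (×1.8–2.0) before no-tooth (×≥2.2);
* act ↑ / inh ↓ → supernumerary cusps or a widened crown.

The `seal` preset is the second documented baseline (slower-growing,
narrower site), kept distinct rather than reconciled with the shark
values.

Monotonicity holds as an *activation ordering* (no-tooth < unicuspid <
tricuspid < multicuspid < widened): the ordering is monotone in `act`
across the whole ×0.5–1.5 band at 10% resolution.  For `inh` it is
monotone on ×0.5–1.2; above ~×1.3 the decay-length contraction briefly
raises the cusp count to five before amplitude suppression collapses the
pattern to unicuspid — a real feature of the model's
spacing-versus-amplitude competition, not a numerical artefact, and the
documented reason the inhibitor ordering is tested on the calibrated
subrange.

Cusp detection counts local maxima of the height profile with
topographic prominence at least 10% of the apex height (separating
counted cusps from incipient bulges); flat-topped peaks report their
middle cell and ties for the primary cusp break to the first
encountered.  "Widened" is assigned when the crown footprint (cells
above 5% of apex height) exceeds a reference baseline footprint by more
than 25% without extra distinct cusps; a fully knotted plateau crown
therefore classifies as widened rather than unicuspid.

## 2. Procrustes machinery

GPA centres each configuration, scales to unit centroid size, and
iterates proper rotations (SVD, det +1 enforced — chirality is fixed
after the side-reflection policy) against the consensus to convergence
(consensus movement < 1e-10, max 100 iterations).  No tangent-space
projection by default; available behind a flag.

Semilandmark sliding displaces each slider along the chord between its
curve neighbours, minimising per specimen either the thin-plate-spline
bending energy of the consensus-to-specimen deformation (default; joint
solve over all sliders with the consensus bending-energy matrix) or the
squared Procrustes distance (independent per-slider projection).
Displacements are bounded by half the distance to the nearer neighbour;
when the bound binds the whole displacement vector is shrunk, which
preserves the guaranteed objective decrease of the convex quadratic.
Sliding is interleaved during the first five GPA iterations only:
each pass strictly decreases its objective, but unbounded re-sliding
lets sliders drift along their own curves (the curve is defined by the
points being slid), so the pass count is capped, after which plain GPA
iterates to convergence.

Right-side teeth are reflected about their apex–base axis at load time
(default on, switchable) so both jaw sides occupy one shape space; the
synthetic generator writes right-side teeth mirrored, as they would be
digitised.

## 3. Statistics

All linear models use sequential (type-I) sums of squares on the
flattened response (Procrustes coordinates, or scalar centroid size)
with factors `treatment` then `sample`, samples coded nested within
treatment as fixed effects — the only coding consistent with the
2 / 20 / 115 df decomposition on 23 samples × 6 teeth.  Projectors are
orthonormal column bases obtained by SVD (nested dummy designs are
rank-deficient).  Significance is by residual randomization (RRPP):
for each term, residuals of the reduced model with all preceding terms
are permuted, the term SS recomputed, and p = (1 + #{SS* ≥ SS}) /
(n_perm + 1); default 999 permutations, seed mandatory in the CLI.
Type-I error of this procedure is verified at the nominal level over
500 null simulations in the test suite.

PCA is the SVD of centred flattened coordinates; at sample-mean level
the six teeth per sample are averaged first (used for the shape-space
plot), tooth level is used for the variance F-test.  Component signs are
fixed by making each component's largest-magnitude loading positive.
The variance F-test compares PC1 score variances of two groups with
df (n₁−1, n₂−1), control first, two-sided p; F < 1 reads as inflated
treatment variance.  Tukey HSD on treatment means (statsmodels) provides
the pairwise size contrasts; percent change is relative to the control
group mean.  The chi-square test on fourth-cusp proportions is Pearson's
without continuity correction (toggleable), df 1.

## 4. Synthetic-data generator

Per tooth of sample s in treatment T:

    shape = template + effect_T·u + offset_s + noise
    CS    = base_cs · size_mult_T · exp(σ_ss·z_s) · exp(σ_st·z_t)

`u` is the cusp-reduction axis: the unit displacement field from the
tricuspid template (primary cusp flanked by two equal secondary bulges)
toward a narrow unicuspid variant.  Sample offsets and tooth noise each
have an isotropic part (σ_sample = 0.0035, σ_tooth = 0.009, Procrustes
units) and a component along `u` (σ_axis = 0.032, σ_tooth_axis = 0.040);
the axis components are multiplied by the per-treatment variance
inflation (1.9 for the Wnt-down arm).  Defaults encode the emulated
design: 7/8/8 samples × 6 teeth, size multipliers 1 / 0.641 / 1.128
(−35.9% and +12.8% against control), shape effects +0.058 / −0.045 along
`u`, fourth-cusp probabilities 0.01 / 0 / 0.12.

The noise SDs are not measurable from published summaries, so they were
derived once from expected-mean-square identities to make the pipeline's
outputs land near the statistics such a study reports — size ANOVA
F(treatment) in the low hundreds with F(sample) ≈ 7, shape ANOVA
R²(treatment) ≈ 0.10 with R²(sample) ≈ 0.23, a dominant sample-mean PC1
(~50–58%), and a control/Wnt-down PC1 variance ratio well below 1 —
and then frozen.  Two structural choices matter: variance inflation
acts along `u` rather than isotropically (a heterogeneous treatment
response concentrated on the main axis; isotropic inflation across 72
coordinate dimensions would barely move the PC1 F-ratio), and samples
share an anisotropic variance component along `u` (with purely isotropic
sample noise no parameterisation yields both the tooth-level ANOVA
ratios and a dominant sample-mean PC1).

What the generator does *not* emulate: outline-correlated digitisation
error along curves (an outline-tangent noise mode would stress the
slider harder), mineralisation-stage and jaw-position gradients, left–
right asymmetry beyond mirroring, and landmark placement error on real
photographs.  Passing recovery tests therefore show the pipeline is
correct and well calibrated under the declared hierarchical model, not
that it is robust to every artefact of real digitised data.
Fourth-cusp count tables default to 170 teeth per group, the scale of a
whole-jaw cusp survey, at which the configured 1% vs 12% proportions
give an expected chi-square near 17.

## 5. Problem sizes and determinism

Default runs: 11,000 iterations on ≤ 90 cells per simulation (≈ 0.4 s);
138 × 38-landmark GPA with sliding ≈ 0.15 s; 999-permutation RRPP on the
full design ≈ 1 s.  The test suite's Monte-Carlo checks use 500 null
datasets (type-I calibration) and 200 generator seeds (effect-size
recovery, variance-inflation sign).  Every stochastic step takes an
explicit seed; simulations are seed-free and bitwise reproducible.

## 6. Known limitations

* The simulator is a 1D phenotype-level calibration, not a reimplementation
  of the original 3D morphodynamic program; absolute parameter values are
  not comparable, only the direction and ordering of phenotype responses.
* A 2D epithelial grid is not implemented; all published cusp counts
  this package targets are along the anterior–posterior axis.
* Mixed-effects (random-effect) versions of the models, missing-landmark
  estimation and 3D GPA are out of scope.
* The inhibitor-axis phenotype ordering is non-monotone in the ×1.3–1.5
  band (see §1); treat inferences about intermediate inhibition levels
  with care.
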