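# cuspkit

Tooth-cusp patterning simulation and 2D landmark-based geometric
morphometrics for studies of shark dental development.

Shark teeth develop their cusps around enamel knots — non-proliferative
epithelial signalling centres whose spacing is thought to be set by an
activator–inhibitor (Turing-type) gene network, and whose behaviour is
modulated by canonical Wnt signalling.  `cuspkit` provides the two
computational halves such a study needs:

* **`cuspkit.simulator` / `cuspkit.sweep`** — a morphodynamic
  activator–inhibitor model of cusp formation on a growing 1D
  anterior–posterior strip of dental epithelium, with named parameters
  for activator autoactivation (`act`), inhibition strength (`inh`),
  signal degradation (`deg`), diffusion (`da`, `di`), knot secretion
  (`sec`) and tissue geometry (`bwi`, `bgr`, `bia`, `pro`); plus a
  parameter-sweep engine that scans each parameter at relative intervals,
  filters outcomes by phenotype predicates ("process of elimination"),
  and searches for the minimal parameter change mimicking Wnt up- or
  downregulation.
* **`cuspkit.landmarks` / `cuspkit.procrustes` / `cuspkit.stats`** — a
  geometric-morphometrics engine for the 38-point tooth scheme (two fixed
  landmarks at the primary-cusp tip and tooth base, 18 sliding
  semilandmarks per side): TPS and curve-slide file I/O, generalized
  Procrustes analysis (GPA) with bending-energy or Procrustes-distance
  semilandmark sliding, sequential-SS Procrustes ANOVA with residual
  randomization (RRPP), PCA of shape space at tooth or sample-mean level,
  centroid-size models with Tukey contrasts, pairwise variance F-tests
  and chi-square tests of cusp-count proportions.
* **`cuspkit.synthetic`** — a hierarchical generator of landmark datasets
  emulating a three-arm small-molecule study (control n=7, Wnt-down n=8,
  Wnt-up n=8 samples, six lateral teeth each) with configurable size
  multipliers, shape effects along a cusp-reduction axis, variance
  inflation and fourth-cusp probabilities, so the whole pipeline runs
  and is testable with no external data.

## The models in brief

The simulator integrates, per iteration on the active domain (explicit
Euler, unit spacing, zero-flux boundaries):

    a ← a + act·a²/((1 + inh·i)(1 + kap·a²)) + bas − dega·a + da·∇²a
    i ← i + sec·(K + (1−K)·a²) − deg·i + di·∇²i

where `K` marks differentiated knot cells (activator above 1.0,
irreversible, frozen, secreting at full rate).  Knot cells rise relative
to the proliferating cervical base at rate `pro`, so cusps are maxima of
the height field and the first-formed (primary) knot is tallest.  Cusps
are counted as local maxima with topographic prominence ≥ 10% of the
apex height.

The morphometrics side follows the standard Procrustes paradigm: for
configurations X_j of k landmarks, GPA centres each configuration,
scales it to unit centroid size CS = √Σ‖x_i − x̄‖², and iteratively
rotates it onto the consensus (rotations restricted to det +1);
semilandmarks slide along their outline tangents to minimise thin-plate
-spline bending energy against the consensus.  Shape and size are then
modelled by a sequential (type-I) linear model `response ~ treatment +
sample(treatment)`, giving the df decomposition 2 / 20 / 115 on 138
teeth, with p-values from randomized residual permutation.

## Worked example

`examples/synthetic_morphometrics.py` generates a synthetic study
(seed 1) and runs the full pipeline:

```
138 teeth x 38 landmarks, GPA converged in 8 iterations

Procrustes ANOVA of shape (sequential SS, RRPP p-values):
  treatment  df= 2  R2=0.1566  F= 13.922  p=0.002
  sample     df=20  R2=0.1965  F=  1.747  p=0.002
  residual   df=115

centroid size (ANOVA + Tukey percent change vs control):
  treatment F = 232.0, sample F = 7.41
  CHIR    +2.4%   (generator truth +12.8%)
  DMSO    +0.0%   (generator truth +0.0%)
  IWR    -39.3%   (generator truth -35.9%)

sample-mean PCA: PC1 56.2%, PC2 9.6% of shape variance
tooth-level PC1 variance F-test (control vs Wnt-down): F41,47 = 0.413, p = 0.0047
```

The treatment term is significant for both shape and size; the Wnt-down
arm loses about a third of its centroid size and becomes markedly more
variable along PC1 (F < 1), while the Wnt-up arm gains size — each
estimate scattered around its generator truth by sampling noise of the
23-sample design.  `examples/simulate_tooth.py` prints the simulated
wild-type tooth (three cusps, primary tallest), and
`examples/wnt_perturbation_insilico.py` reports the minimal parameter
changes that flip it to unicuspid (act ×0.7 or inh ×1.8) or to
supernumerary-cusped/widened forms (act ×1.1 or inh ×0.7).

A thin CLI wraps the same functions:

```sh
cuspkit simulate --preset shark --out tooth.json
cuspkit sweep --preset shark --params act,inh --step 0.10 --range 0.5:1.5 --out grid.csv
cuspkit synth --seed 1 --out synth/
cuspkit stats --tps synth/landmarks.tps --curveslide synth/curveslide.csv \
              --metadata synth/metadata.csv --seed 1 --out report/
```

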