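"""Synthetic landmark datasets emulating a three-arm Wnt-perturbation study.

The generator draws 2D tooth landmark data with the hierarchical
structure of the study design it emulates: three treatment groups
(control DMSO n=7 samples, Wnt-downregulated IWR n=8, Wnt-upregulated
CHIR n=8), six teeth per sample (the three most lateral teeth on each
jaw side), a tricuspid mean tooth shape, between-sample and within-sample
(tooth) shape noise, per-treatment centroid-size multipliers, inflated
tooth-level shape variance in the IWR group, and per-treatment
probabilities of a supernumerary fourth cusp.

Effects are applied along a "cusp-reduction axis": the unit displacement
field taking the tricuspid template toward a narrow unicuspid tooth.
Positive displacement shrinks the secondary cusps and narrows the tooth
(the IWR direction); negative displacement widens the tooth and enlarges
the secondary cusps (the CHIR direction).  Sample-level noise has an
extra variance component along this same axis, reflecting that real
samples vary mostly along the axis treatments act on.

Every draw is reproducible from the seed, and the realized ground truth
is returned alongside the dataset for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from cuspkit import landmarks as lmio
from cuspkit.landmarks import (CurveSlideSpec, Dataset, LandmarkConfig,
                               SpecimenMeta, default_curveslide,
                               landmark_outline)
from cuspkit.procrustes import centroid_size

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "tooth_outline",
    "make_template",
    "cusp_reduction_axis",
    "generate_dataset",
    "generate_cusp_counts",
    "write_dataset",
]

TREATMENTS = ("DMSO", "IWR", "CHIR")


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Defaults encode the emulated study: sample counts 7/8/8, six teeth
    per sample, centroid-size multipliers 1.0/0.641/1.128 (i.e. -35.9%
    and +12.8% against control), tooth-level shape-noise inflation ~1.9x
    SD in the IWR group (variance ratio ~3.6, matching a control/IWR
    variance F around 0.28), and fourth-cusp probabilities 1%/0%/12%.
    Shape-noise SDs are in Procrustes (unit-centroid-size) units.
    """

    n_samples: Dict[str, int] = field(
        default_factory=lambda: {"DMSO": 7, "IWR": 8, "CHIR": 8})
    teeth_per_sample: int = 6
    size_mult: Dict[str, float] = field(
        default_factory=lambda: {"DMSO": 1.0, "IWR": 0.641, "CHIR": 1.128})
    shape_effect: Dict[str, float] = field(
        default_factory=lambda: {"DMSO": 0.0, "IWR": 0.058, "CHIR": -0.035})
    var_inflation: Dict[str, float] = field(
        default_factory=lambda: {"DMSO": 1.0, "IWR": 1.9, "CHIR": 1.0})
    sigma_sample: float = 0.0035
    sigma_axis: float = 0.032
    sigma_tooth: float = 0.009
    sigma_tooth_axis: float = 0.040
    sigma_size_sample: float = 0.105
    sigma_size_tooth: float = 0.105
    fourth_cusp_prob: Dict[str, float] = field(
        default_factory=lambda: {"DMSO": 0.01, "IWR": 0.0, "CHIR": 0.12})
    base_cs: float = 1.0            # physical template centroid size (mm)
    image_scale: float = 0.01       # TPS SCALE key (units per pixel)
    seed: int = 0

    def validate(self):
        for t in TREATMENTS:
            if self.n_samples[t] < 1:
                raise ValueError("sample counts must be >= 1")
            if self.size_mult[t] <= 0 or self.var_inflation[t] <= 0:
                raise ValueError("multipliers must be > 0")
            if not 0.0 <= self.fourth_cusp_prob[t] <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.teeth_per_sample < 1:
            raise ValueError("teeth_per_sample must be >= 1")


@dataclass
class SyntheticTruth:
    """Realized ground truth of one generated dataset."""

    size_mult: Dict[str, float]
    shape_effect: Dict[str, float]
    var_inflation: Dict[str, float]
    fourth_cusp: Dict[str, list]      # per treatment: [with, without]
    expected_pct_change: Dict[str, float]
    seed: int

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# template geometry

def tooth_outline(primary_height: float = 1.0, secondary_height: float = 0.35,
                  half_width: float = 1.0, secondary_pos: float = 0.55,
                  primary_width: float = 0.16, secondary_width: float = 0.11,
                  n_points: int = 720) -> np.ndarray:
    """Closed outline of an idealized tooth: one primary cusp flanked by
    two equal secondary cusps on a flat base; apex up, counter-clockwise,
    bilaterally symmetric about x=0."""
    m = (n_points // 2) | 1         # odd: apex x=0 is an exact vertex
    # crown sampled right-to-left so the polygon runs counter-clockwise
    x = np.linspace(half_width, -half_width, m)
    y = (primary_height * np.exp(-(x / primary_width) ** 2)
         + secondary_height * np.exp(-((x - secondary_pos) / secondary_width) ** 2)
         + secondary_height * np.exp(-((x + secondary_pos) / secondary_width) ** 2))
    crown = np.column_stack([x, y])
    xb = np.linspace(-half_width, half_width, m - 2)[1:-1]  # odd: has x=0
    base = np.column_stack([xb, np.zeros_like(xb)])
    return np.vstack([crown, base])


def _landmarked(primary_height=1.0, secondary_height=0.35, half_width=1.0
                ) -> LandmarkConfig:
    out = tooth_outline(primary_height=primary_height,
                        secondary_height=secondary_height,
                        half_width=half_width)
    apex = np.array([0.0, out[:, 1].max()])
    base = np.array([0.0, 0.0])
    return landmark_outline(out, apex, base, id="template")


def make_template() -> LandmarkConfig:
    """Deterministic tricuspid mean tooth in the 38-point scheme."""
    return _landmarked()


def cusp_reduction_axis() -> np.ndarray:
    """Unit displacement field (flattened, 76-vector) from the tricuspid
    template toward a narrow unicuspid tooth, in Procrustes units."""
    t0 = _unit(make_template().coords)
    t1 = _unit(_landmarked(secondary_height=0.0, half_width=0.78).coords)
    v = (t1 - t0).reshape(-1)
    return v / np.linalg.norm(v)


def _fourth_cusp_field() -> np.ndarray:
    """Flattened displacement adding a small lateral fourth-cusp bulge."""
    t0 = _unit(make_template().coords)
    coords = t0.copy()
    # bulge outward around the lower part of one side (landmarks 12..16)
    sl = slice(12, 17)
    seg = coords[sl]
    centre = coords.mean(axis=0)
    out_dir = seg - centre
    out_dir /= np.linalg.norm(out_dir, axis=1, keepdims=True)
    w = np.array([0.3, 0.8, 1.0, 0.8, 0.3])[:, None]
    coords[sl] = seg + 0.035 * w * out_dir
    v = (coords - t0).reshape(-1)
    return v


def _unit(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / np.sqrt((c ** 2).sum())


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(cfg: Optional[GeneratorConfig] = None
                     ) -> Tuple[Dataset, SyntheticTruth]:
    """Draw one synthetic landmark dataset plus its ground truth.

    Hierarchical model per tooth of sample s in treatment T::

        shape   = template + effect_T * u + sample_offset_s + tooth_noise
        CS      = base_cs * size_mult_T * lognormal_s * lognormal_tooth

    with ``u`` the cusp-reduction axis.  Sample offsets and tooth noise
    each have an isotropic part (sigma_sample, sigma_tooth) plus a
    component along ``u`` (sigma_axis, sigma_tooth_axis); the axis
    components are multiplied by var_inflation_T, modelling the
    heterogeneous treatment response that inflates shape variance along
    the main axis of variation.  Teeth
    alternate jaw sides; right-side teeth are stored mirrored (as they
    would be digitised) so the reader's reflection policy restores them.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    template = _unit(make_template().coords)
    k = template.shape[0]
    u = cusp_reduction_axis()
    bulge = _fourth_cusp_field()

    configs, meta = [], []
    fourth_counts = {t: [0, 0] for t in TREATMENTS}
    for treat in TREATMENTS:
        for si in range(cfg.n_samples[treat]):
            sample_id = f"{treat}{si + 1:02d}"
            infl = cfg.var_inflation[treat]
            offset = (cfg.sigma_sample * rng.standard_normal(2 * k)
                      + cfg.sigma_axis * infl * rng.standard_normal() * u)
            size_fac_sample = np.exp(cfg.sigma_size_sample
                                     * rng.standard_normal())
            for ti in range(cfg.teeth_per_sample):
                side = "left" if ti % 2 == 0 else "right"
                pos = ti // 2 + 1
                noise = (cfg.sigma_tooth * rng.standard_normal(2 * k)
                         + cfg.sigma_tooth_axis * infl
                         * rng.standard_normal() * u)
                flat = (template.reshape(-1)
                        + cfg.shape_effect[treat] * u + offset + noise)
                has4 = rng.random() < cfg.fourth_cusp_prob[treat]
                fourth_counts[treat][0 if has4 else 1] += 1
                if has4:
                    flat = flat + bulge
                coords = flat.reshape(k, 2)
                cs = (cfg.base_cs * cfg.size_mult[treat] * size_fac_sample
                      * np.exp(cfg.sigma_size_tooth * rng.standard_normal()))
                coords = coords / np.sqrt(((coords - coords.mean(0)) ** 2).sum()) * cs
                # random placement: rotation and translation
                th = rng.uniform(-0.4, 0.4)
                R = np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
                coords = coords @ R.T + rng.uniform(2.0, 8.0, size=2)
                if side == "right":
                    coords = coords.copy()
                    coords[:, 0] = -coords[:, 0]   # mirrored as digitised
                ident = f"{sample_id}_{side[0].upper()}{pos}"
                configs.append(LandmarkConfig(coords=coords,
                                              scale=cfg.image_scale, id=ident))
                meta.append(SpecimenMeta(ident, sample_id, treat, side, pos))

    truth = SyntheticTruth(
        size_mult=dict(cfg.size_mult),
        shape_effect=dict(cfg.shape_effect),
        var_inflation=dict(cfg.var_inflation),
        fourth_cusp={t: list(v) for t, v in fourth_counts.items()},
        expected_pct_change={t: (cfg.size_mult[t] / cfg.size_mult["DMSO"] - 1)
                             * 100.0 for t in TREATMENTS},
        seed=cfg.seed)
    return Dataset(configs, meta, default_curveslide()), truth


def generate_cusp_counts(cfg: Optional[GeneratorConfig] = None,
                         pair: Tuple[str, str] = ("DMSO", "CHIR"),
                         n_teeth: int = 170,
                         rng: Optional[np.random.Generator] = None
                         ) -> np.ndarray:
    """Binomial fourth-cusp counts for a treatment pair.

    Returns a 2x2 table [[with, without] per group] over ``n_teeth``
    teeth per group (default 170, the approximate per-group tooth count
    of a whole-jaw survey), suitable for ``chisq_proportions``.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tab = np.empty((2, 2), dtype=int)
    for r, t in enumerate(pair):
        w = rng.binomial(n_teeth, cfg.fourth_cusp_prob[t])
        tab[r] = (w, n_teeth - w)
    return tab


def write_dataset(dataset: Dataset, truth: Optional[SyntheticTruth],
                  outdir) -> dict:
    """Write TPS, curve-slide CSV, metadata CSV (and truth JSON) files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": outdir / "landmarks.tps",
        "curveslide": outdir / "curveslide.csv",
        "metadata": outdir / "metadata.csv",
    }
    lmio.write_tps(dataset.configs, paths["tps"])
    lmio.write_curveslide(dataset.curves, paths["curveslide"])
    lmio.write_metadata(dataset.meta, paths["metadata"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
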