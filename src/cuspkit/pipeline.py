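"""End-to-end orchestration: data in, statistics out.

``run_morphometrics`` chains the full landmark analysis — read TPS /
curve-slide / metadata (or take an in-memory Dataset), optionally reflect
right-side teeth into the left-side shape space, generalized Procrustes
superimposition with semilandmark sliding, centroid-size model with
Tukey contrasts, Procrustes ANOVA of shape, PCA at both levels, and the
PC1 variance F-test — and returns everything as one report dictionary
(also writable as JSON/CSV).  ``run_insilico`` runs the simulator
counterpart: baseline phenotype, treatment mimicry in both Wnt
directions, and any requested parameter sweeps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from cuspkit import landmarks as lmio
from cuspkit import stats as cstats
from cuspkit import synthetic
from cuspkit.landmarks import Dataset, reflect_config
from cuspkit.procrustes import align_gpa
from cuspkit.simulator import load_preset, simulate, outline_of
from cuspkit.sweep import SweepSpec, mimic_treatment, sweep

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_morphometrics", "run_insilico",
           "load_dataset", "reproduce_fig6"]


@dataclass
class RunConfig:
    """Switches of a morphometric run, logged into every report."""

    slide_mode: str = "bending-energy"
    reflect_right: bool = True
    n_perm: int = 999
    seed: int = 1
    pca_level: str = "sample-mean"
    control: str = "DMSO"
    outdir: Optional[str] = None


def load_dataset(tps_path, curveslide_path=None, metadata_path=None) -> Dataset:
    configs = lmio.read_tps(tps_path)
    curves = (lmio.read_curveslide(curveslide_path) if curveslide_path
              else lmio.default_curveslide())
    if metadata_path is None:
        raise ValueError("metadata file required")
    meta = lmio.read_metadata(metadata_path)
    by_id = {m.id: m for m in meta}
    meta_sorted = [by_id[c.id] for c in configs]
    return Dataset(configs, meta_sorted, curves)


def run_morphometrics(dataset: Dataset, cfg: Optional[RunConfig] = None) -> dict:
    """Full landmark analysis; returns a JSON-serialisable report dict."""
    cfg = cfg or RunConfig()
    logger.info("morphometrics run: %s", cfg)
    configs = list(dataset.configs)
    if cfg.reflect_right:
        configs = [reflect_config(c) if m.side == "right" else c
                   for c, m in zip(configs, dataset.meta)]
    aligned = align_gpa(configs, curves=dataset.curves,
                        slide_mode=cfg.slide_mode)
    meta_df = dataset.meta_frame()

    shape_anova = cstats.procrustes_anova(aligned, meta_df,
                                          n_perm=cfg.n_perm, seed=cfg.seed)
    size = cstats.size_model(aligned.centroid_sizes, meta_df,
                             control=cfg.control, n_perm=cfg.n_perm,
                             seed=cfg.seed)
    pca_sample = cstats.pca_shapes(aligned, meta_df, level="sample-mean")
    pca_tooth = cstats.pca_shapes(aligned, meta_df, level="tooth")
    F, df1, df2, pF = cstats.variance_ftest(
        pca_tooth.scores[:, 0], meta_df, pair=(cfg.control, "IWR"))

    report = {
        "config": {k: getattr(cfg, k) for k in
                   ("slide_mode", "reflect_right", "n_perm", "seed",
                    "pca_level", "control")},
        "n_teeth": aligned.n,
        "n_landmarks": aligned.k,
        "gpa": {"n_iter": aligned.n_iter_gpa, "slid": aligned.slid},
        "shape_anova": _lm_dict(shape_anova),
        "size_anova": _lm_dict(size.anova),
        "size": {
            "group_means": size.group_means.to_dict(),
            "percent_change": size.percent_change.to_dict(),
            "tukey": size.tukey.to_dict(orient="records"),
        },
        "pca_sample_mean": {
            "var_prop": pca_sample.var_prop[:5].tolist(),
            "scores_pc12": pca_sample.scores[:, :2].tolist(),
            "ids": pca_sample.ids,
        },
        "pca_tooth": {"var_prop": pca_tooth.var_prop[:5].tolist()},
        "variance_ftest_pc1": {"F": F, "df1": df1, "df2": df2, "p": pF,
                               "pair": [cfg.control, "IWR"]},
    }
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        aligned.to_frame().to_csv(out / "aligned_coords.csv", index=False)
        shape_anova.to_frame().to_csv(out / "shape_anova.csv", index=False)
        size.anova.to_frame().to_csv(out / "size_anova.csv", index=False)
        size.tukey.to_csv(out / "tukey.csv", index=False)
    return report


def _lm_dict(res) -> dict:
    return {
        "terms": res.terms, "df": res.df, "SS": res.SS, "R2": res.R2,
        "F": res.F, "p_perm": res.p_perm, "df_res": res.df_res,
        "SS_res": res.SS_res, "SS_total": res.SS_total,
    }


def run_insilico(preset: str = "shark", sweeps: Optional[List[str]] = None,
                 step: float = 0.10, outdir: Optional[str] = None) -> dict:
    """Simulator bundle: baseline + Wnt mimicry + optional sweeps."""
    base = load_preset(preset)
    sheet, cusps, label = simulate(base)
    report = {
        "preset": preset,
        "baseline": {"n_cusps": label.n_cusps, "category": label.category,
                     "width": label.width, "height": label.height},
        "wnt_down": mimic_treatment(base, "wnt-down", step=step),
        "wnt_up": mimic_treatment(base, "wnt-up", step=step),
    }
    if sweeps:
        res = sweep(SweepSpec(base=base, params=list(sweeps), step=step))
        report["sweep"] = res.grid.to_dict(orient="records")
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "insilico.json").write_text(json.dumps(report, indent=2,
                                                      default=float))
        # outline of the baseline tooth, landmarked for morphometrics
        outline = outline_of(sheet)
        apex = outline[int(np.argmax(outline[:, 1]))]
        basep = np.array([outline[:, 0].mean(), 0.0])
        cfgl = lmio.landmark_outline(outline, apex, basep, id=f"{preset}_baseline")
        lmio.write_tps([cfgl], out / "baseline_outline.tps")
    return report


def reproduce_fig6(directory, cfg: Optional[RunConfig] = None) -> dict:
    """Morphometric analysis of a deposited lateral-tooth dataset.

    Expects a directory with ``landmarks.tps`` (38-point configurations
    with SCALE keys), ``curveslide.csv`` and ``metadata.csv``; the other
    deposited tables (PCA scores, aligned shapes, centroid sizes) are
    outputs this pipeline recomputes rather than inputs.
    """
    d = Path(directory)
    ds = load_dataset(d / "landmarks.tps", d / "curveslide.csv",
                      d / "metadata.csv")
    return run_morphometrics(ds, cfg)
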