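"""Landmark I/O: TPS files, curve-slide definitions, specimen metadata.

The landmark scheme is the 38-point tooth scheme: two fixed landmarks
(index 0 at the tip of the primary cusp, index 19 at the base of the
tooth) and eighteen sliding semilandmarks distributed at equal arc length
along the outline on either side of the tooth.

Files follow the tpsUtil/tpsDig dialect: records start with ``LM=<n>``,
followed by ``n`` whitespace-separated coordinate lines and optional
``IMAGE=``, ``ID=`` and ``SCALE=`` keys.  Coordinates are stored on disk
in image convention and kept in math convention (y up) in memory; the
SCALE factor is applied multiplicatively on read and divided out on
write.  TPS and curve-slide files are 1-based; everything in memory is
0-based, with conversion at the I/O boundary only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_LANDMARKS",
    "APEX_INDEX",
    "BASE_INDEX",
    "LandmarkConfig",
    "CurveSlideSpec",
    "SpecimenMeta",
    "Dataset",
    "read_tps",
    "write_tps",
    "read_curveslide",
    "write_curveslide",
    "read_metadata",
    "write_metadata",
    "landmark_outline",
    "default_curveslide",
    "reflect_config",
]

logger = logging.getLogger(__name__)

N_LANDMARKS = 38
N_SEMI_PER_SIDE = 18
#: Fixed landmark at the tip of the primary cusp.
APEX_INDEX = 0
#: Fixed landmark at the base of the tooth.
BASE_INDEX = 1 + N_SEMI_PER_SIDE

TREATMENTS = ("DMSO", "IWR", "CHIR")


@dataclass
class LandmarkConfig:
    """One tooth's ordered 2D landmarks with fixed/semi labels and scale."""

    coords: np.ndarray          # (38, 2), math convention, scale applied
    scale: Optional[float] = None
    id: str = ""
    fixed_idx: tuple = (APEX_INDEX, BASE_INDEX)
    semi_idx: tuple = tuple(i for i in range(N_LANDMARKS)
                            if i not in (APEX_INDEX, BASE_INDEX))

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} landmarks, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if set(self.fixed_idx) & set(self.semi_idx):
            raise ValueError("fixed and semi landmark indices overlap")
        if set(self.fixed_idx) | set(self.semi_idx) != set(range(N_LANDMARKS)):
            raise ValueError("fixed+semi indices must cover all landmarks")


@dataclass
class CurveSlideSpec:
    """(before, slide, after) neighbour triples for sliding semilandmarks.

    Indices are 0-based in memory.  Each semilandmark slides along the
    tangent defined by its two neighbours on its outline curve.
    """

    rows: np.ndarray            # (m, 3) int array; may be empty

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int).reshape(-1, 3)
        if self.rows.size:
            slides = self.rows[:, 1]
            if len(set(slides.tolist())) != len(slides):
                raise ValueError("duplicate slide index in curve-slide spec")
            if self.rows.min() < 0 or self.rows.max() >= N_LANDMARKS:
                raise ValueError("curve-slide index out of range")
            for b, s, a in self.rows:
                if s in (b, a):
                    raise ValueError(f"slide index {s} equals its neighbour")
            self._check_acyclic()

    def _check_acyclic(self):
        # following before-links from any slider must terminate (at a fixed
        # landmark or a non-sliding point), never cycle back
        nxt = {int(s): (int(b), int(a)) for b, s, a in self.rows}
        for start in nxt:
            for direction in (0, 1):
                seen = {start}
                cur = start
                while cur in nxt:
                    cur = nxt[cur][direction]
                    if cur in seen:
                        raise ValueError("cyclic curve-slide definition")
                    seen.add(cur)

    @property
    def n_sliders(self) -> int:
        return len(self.rows)


@dataclass
class SpecimenMeta:
    id: str
    sample_id: str
    treatment: str
    side: str
    tooth_position: int

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not 1 <= int(self.tooth_position) <= 3:
            raise ValueError("tooth_position must be 1..3")


@dataclass
class Dataset:
    """Landmark configurations with aligned metadata and a slide spec."""

    configs: List[LandmarkConfig]
    meta: List[SpecimenMeta]
    curves: CurveSlideSpec = field(
        default_factory=lambda: CurveSlideSpec(np.empty((0, 3), dtype=int)))

    def __post_init__(self):
        if len(self.configs) != len(self.meta):
            raise ValueError("one metadata row per configuration required")
        ids_c = [c.id for c in self.configs]
        ids_m = [m.id for m in self.meta]
        if ids_c != ids_m:
            raise ValueError("configs and meta are not aligned by id")

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.configs])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.id, m.sample_id, m.treatment, m.side, m.tooth_position)
             for m in self.meta],
            columns=["id", "sample_id", "treatment", "side", "tooth_position"])


# ---------------------------------------------------------------------------
# TPS

def read_tps(path, y_flip: bool = True, apply_scale: bool = True
             ) -> List[LandmarkConfig]:
    """Parse a TPS file into landmark configurations.

    ``y_flip`` converts from image convention (y down) to math convention
    (y up) by negating y.  A missing SCALE falls back to 1.0 with a
    warning.
    """
    configs: List[LandmarkConfig] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    k = 0
    rec = 0
    while k < len(lines):
        line = lines[k].strip()
        if not line:
            k += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"record {rec}: expected LM=, got {line!r}")
        rec += 1
        n = int(line.split("=", 1)[1])
        k += 1
        pts = []
        for j in range(n):
            if k >= len(lines):
                raise ValueError(f"record {rec}: LM={n} but file ended "
                                 f"after {j} coordinate lines")
            parts = lines[k].split()
            if len(parts) != 2:
                raise ValueError(
                    f"record {rec}: bad coordinate line {lines[k]!r}")
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError as e:
                raise ValueError(
                    f"record {rec}: non-numeric coordinate {lines[k]!r}") from e
            k += 1
        ident, scale = "", None
        while k < len(lines):
            s = lines[k].strip()
            up = s.upper()
            if up.startswith("LM=") or not s:
                break
            if up.startswith("ID="):
                ident = s.split("=", 1)[1].strip()
            elif up.startswith("SCALE="):
                scale = float(s.split("=", 1)[1])
            elif up.startswith("IMAGE="):
                pass
            else:
                raise ValueError(f"record {rec}: unrecognised key line {s!r}")
            k += 1
        coords = np.array(pts, dtype=float)
        if y_flip:
            coords[:, 1] = -coords[:, 1]
        if scale is None:
            logger.warning("record %d (%s): no SCALE key, assuming 1.0",
                           rec, ident or "unnamed")
            eff_scale = 1.0
        else:
            eff_scale = scale
        if apply_scale:
            coords = coords * eff_scale
        configs.append(LandmarkConfig(coords=coords, scale=scale,
                                      id=ident or f"record{rec}"))
    return configs


def write_tps(configs: Sequence[LandmarkConfig], path, y_flip: bool = True
              ) -> None:
    """Write configurations in the dialect ``read_tps`` accepts (lossless)."""
    with open(path, "w") as fh:
        for c in configs:
            coords = c.coords.copy()
            scale = c.scale if c.scale is not None else 1.0
            coords = coords / scale
            if y_flip:
                coords[:, 1] = -coords[:, 1]
            fh.write(f"LM={len(coords)}\n")
            for x, y in coords:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={c.id}\n")
            if c.scale is not None:
                fh.write(f"SCALE={c.scale:.12g}\n")


# ---------------------------------------------------------------------------
# curve-slide and metadata tables

def read_curveslide(path) -> CurveSlideSpec:
    """Read a before,slide,after CSV (1-based on disk) into a spec."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols != ["before", "slide", "after"]:
        raise ValueError("curve-slide CSV must have header before,slide,after")
    return CurveSlideSpec(df.to_numpy(dtype=int) - 1)


def write_curveslide(spec: CurveSlideSpec, path) -> None:
    pd.DataFrame(spec.rows + 1, columns=["before", "slide", "after"]
                 ).to_csv(path, index=False)


def read_metadata(path) -> List[SpecimenMeta]:
    df = pd.read_csv(path)
    need = ["id", "sample_id", "treatment", "side", "tooth_position"]
    if list(df.columns) != need:
        raise ValueError(f"metadata CSV must have columns {need}")
    return [SpecimenMeta(str(r.id), str(r.sample_id), str(r.treatment),
                         str(r.side), int(r.tooth_position))
            for r in df.itertuples(index=False)]


def write_metadata(meta: Sequence[SpecimenMeta], path) -> None:
    pd.DataFrame(
        [(m.id, m.sample_id, m.treatment, m.side, m.tooth_position)
         for m in meta],
        columns=["id", "sample_id", "treatment", "side", "tooth_position"]
    ).to_csv(path, index=False)


def default_curveslide() -> CurveSlideSpec:
    """Slide spec for the standard 38-point scheme.

    Landmark 0 is the apex, 1..18 run down one side, 19 is the base and
    20..37 run down the other side; each semilandmark slides between its
    two chain neighbours.
    """
    rows = []
    side1 = [APEX_INDEX] + list(range(1, 19)) + [BASE_INDEX]
    side2 = [APEX_INDEX] + list(range(20, 38)) + [BASE_INDEX]
    for chain in (side1, side2):
        for j in range(1, len(chain) - 1):
            rows.append((chain[j - 1], chain[j], chain[j + 1]))
    return CurveSlideSpec(np.array(rows, dtype=int))


# ---------------------------------------------------------------------------
# outline landmarking

def _arc_resample(points: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc length along an open polyline (ends excluded)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) outline arc")
    targets = total * np.arange(1, n + 1) / (n + 1)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, points[:, 0])
    out[:, 1] = np.interp(targets, s, points[:, 1])
    return out


def landmark_outline(outline: np.ndarray, apex: np.ndarray, base: np.ndarray,
                     scale: Optional[float] = None, id: str = "") -> LandmarkConfig:
    """Place the 38-point scheme on a closed outline.

    Fixed landmark 0 at *apex*, fixed landmark 19 at *base*; 18
    semilandmarks at equal arc-length spacing along each of the two
    outline arcs between them.  *apex* and *base* must be (close to)
    vertices of the outline.
    """
    outline = np.asarray(outline, dtype=float)
    apex = np.asarray(apex, dtype=float)
    base = np.asarray(base, dtype=float)
    if np.allclose(apex, base):
        raise ValueError("apex and base coincide")
    ia = int(np.argmin(np.linalg.norm(outline - apex, axis=1)))
    ib = int(np.argmin(np.linalg.norm(outline - base, axis=1)))
    if ia == ib:
        raise ValueError("apex and base map to the same outline vertex")
    n = len(outline)
    # two arcs from apex to base, walking the closed polygon both ways
    idx_fwd = [(ia + j) % n for j in range(0, (ib - ia) % n + 1)]
    idx_bwd = [(ia - j) % n for j in range(0, (ia - ib) % n + 1)]
    arc1 = outline[idx_fwd]
    arc2 = outline[idx_bwd]
    semi1 = _arc_resample(arc1, N_SEMI_PER_SIDE)
    semi2 = _arc_resample(arc2, N_SEMI_PER_SIDE)
    coords = np.vstack([outline[ia], semi1, outline[ib], semi2])
    return LandmarkConfig(coords=coords, scale=scale, id=id)


def reflect_config(c: LandmarkConfig) -> LandmarkConfig:
    """Reflect a configuration about its apex-base axis.

    Used to fold right-side teeth into the left-side shape space so both
    jaw sides share one morphospace.
    """
    apex = c.coords[APEX_INDEX]
    base = c.coords[BASE_INDEX]
    axis = base - apex
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("degenerate apex-base axis")
    u = axis / nrm
    rel = c.coords - apex
    # reflect across the line through apex with direction u
    par = rel @ u
    perp = rel - np.outer(par, u)
    coords = apex + np.outer(par, u) - perp
    return LandmarkConfig(coords=coords, scale=c.scale, id=c.id,
                          fixed_idx=c.fixed_idx, semi_idx=c.semi_idx)
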