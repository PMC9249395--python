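"""Activator-inhibitor simulation of tooth cusp patterning.

Tooth cusps are positioned by enamel knots: non-proliferative epithelial
signalling centres that form where a self-enhancing activator exceeds a
differentiation threshold.  The model couples a Gierer-Meinhardt-type
reaction-diffusion system (short-range activator, long-range inhibitor) to
a growing one-dimensional anterior-posterior strip of epithelium.  Cells
that differentiate into knot cells stop proliferating; because the
surrounding epithelium keeps extending the cervical base, knot cells rise
relative to the base at the proliferation rate, so cusps appear as local
maxima of the height field and the first knot (the primary cusp) ends up
tallest.

Per-iteration update (explicit Euler, unit time step, unit cell spacing)
on the active domain::

    a <- a + act * a^2 / (1 + inh * i) + bas - deg * a + da * lap(a)
    i <- i + sec * a^2                       - deg * i + di * lap(i)

with zero-flux boundaries at the active-domain edges and both fields
clamped at zero.  Cells with ``a`` above the differentiation threshold
(1.0 after nondimensionalisation) join the knot mask irreversibly.  The
active domain widens by ``bgr`` cells per iteration, split between the
anterior and posterior ends by the bias ``bia``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "GeneNetworkParams",
    "TissueParams",
    "SimParams",
    "EpithelialSheet",
    "Cusp",
    "CuspSet",
    "PhenotypeLabel",
    "NumericalInstabilityError",
    "KNOT_THRESHOLD",
    "DEFAULT_MIN_PROMINENCE",
    "step",
    "simulate",
    "detect_cusps",
    "classify_phenotype",
    "outline_of",
    "load_preset",
    "parse_params",
    "preset_path",
]

#: Activator level above which a cell differentiates into a knot cell.
KNOT_THRESHOLD = 1.0

#: Default cusp-detection prominence, as a fraction of maximum height.
#: Separates incipient bulges (ectopic cusps that do not fully form) from
#: counted cusps.
DEFAULT_MIN_PROMINENCE = 0.10


class NumericalInstabilityError(RuntimeError):
    """Raised when a field becomes non-finite; carries the iteration index."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite field values at iteration {iteration}")


@dataclass
class GeneNetworkParams:
    """Gene-network parameters of the activator-inhibitor circuit.

    Parameters
    ----------
    act : activator autoactivation rate (per iteration).
    inh : inhibition strength of the activator by the inhibitor.
    deg : protein degradation rate (per iteration), shared by both fields.
    da, di : activator / inhibitor diffusion coefficients
        (grid units^2 per iteration); explicit-Euler stability requires
        both <= 0.5 for unit spacing.
    sec : inhibitor secretion rate driven by activator (per iteration).
    extra : open map for additional network constants (e.g. ``bas``, the
        basal activator production, default 1e-4).
    """

    act: float
    inh: float
    deg: float
    da: float
    di: float
    sec: float
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        vals = [self.act, self.inh, self.deg, self.da, self.di, self.sec]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("gene-network parameters must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("gene-network rates must be >= 0")
        if self.di <= 0:
            raise ValueError("inhibitor diffusion di must be > 0")
        if self.da > 0.5 or self.di > 0.5:
            raise ValueError("da, di must be <= 0.5 (explicit-Euler stability)")

    @property
    def bas(self) -> float:
        return float(self.extra.get("bas", 1e-4))

    @property
    def kap(self) -> float:
        return float(self.extra.get("kap", 0.0))

    @property
    def dega(self) -> float:
        # activator turnover; `deg` itself is the turnover of the secreted
        # diffusing signal, whose decay length sets cusp spacing
        return float(self.extra.get("dega", self.deg))


@dataclass
class TissueParams:
    """Cellular/tissue parameters of the growing tooth site.

    Parameters
    ----------
    bwi : initial border width of the tooth site (grid cells, >= 3).
    bgr : border growth rate (grid cells per iteration).
    bia : anterior-posterior bias; 1 means symmetric growth, values != 1
        skew the widening toward one end.
    pro : proliferation-driven elevation rate of knot cells relative to
        the growing base (height units per iteration).
    """

    bwi: int
    bgr: float
    bia: float = 1.0
    pro: float = 1.0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.bwi < 3:
            raise ValueError("bwi must be >= 3 grid cells")
        if self.bgr < 0:
            raise ValueError("bgr must be >= 0")
        if self.bia <= 0:
            raise ValueError("bia must be > 0")


@dataclass
class SimParams:
    """Full parameter set for one simulation."""

    gene: GeneNetworkParams
    tissue: TissueParams
    n_iter: int = 11000
    seed: int = 0
    label: str = ""

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        self.gene.validate()
        self.tissue.validate()

    def with_scaled(self, name: str, factor: float) -> "SimParams":
        """Return a copy with one named parameter multiplied by *factor*."""
        return self.with_value(name, self._get(name) * factor)

    def _get(self, name: str) -> float:
        for obj, keys in ((self.gene, _GENE_KEYS), (self.tissue, _TISSUE_KEYS)):
            if name in keys:
                return float(getattr(obj, name))
            if name in obj.extra:
                return float(obj.extra[name])
        if name == "n_iter":
            return float(self.n_iter)
        raise KeyError(f"unknown parameter {name!r}")

    def with_value(self, name: str, value: float) -> "SimParams":
        gene, tissue = replace(self.gene), replace(self.tissue)
        gene.extra, tissue.extra = dict(gene.extra), dict(tissue.extra)
        p = replace(self, gene=gene, tissue=tissue)
        if name == "n_iter":
            p.n_iter = int(round(value))
            return p
        for obj, keys in ((p.gene, _GENE_KEYS), (p.tissue, _TISSUE_KEYS)):
            if name in keys:
                if name == "bwi":
                    value = int(round(value))
                setattr(obj, name, value)
                return p
            if name in obj.extra:
                obj.extra[name] = value
                return p
        raise KeyError(f"unknown parameter {name!r}")


@dataclass
class EpithelialSheet:
    """Discretised anterior-posterior strip of dental epithelium.

    ``lo:hi`` delimits the active (growing) domain inside the allocated
    grid; fields outside it are identically zero.  ``height`` is the
    elevation of each cell above the cervical base.
    """

    ncols: int
    height: np.ndarray
    a: np.ndarray
    i: np.ndarray
    knot_mask: np.ndarray
    lo: int
    hi: int
    grow_anterior: float = 0.0   # fractional growth accumulators
    grow_posterior: float = 0.0
    nrows: int = 1

    @property
    def active_width(self) -> int:
        return self.hi - self.lo

    def copy(self) -> "EpithelialSheet":
        return EpithelialSheet(
            self.ncols, self.height.copy(), self.a.copy(), self.i.copy(),
            self.knot_mask.copy(), self.lo, self.hi,
            self.grow_anterior, self.grow_posterior, self.nrows,
        )


@dataclass
class Cusp:
    position: int
    height: float
    prominence: float


@dataclass
class CuspSet:
    cusps: list
    n: int
    primary_index: int


@dataclass
class PhenotypeLabel:
    category: str
    n_cusps: int
    width: float
    height: float


def _laplacian_zeroflux(f: np.ndarray) -> np.ndarray:
    """1D Laplacian with zero-flux (reflecting) boundaries."""
    lap = np.empty_like(f)
    lap[1:-1] = f[:-2] + f[2:] - 2.0 * f[1:-1]
    lap[0] = f[1] - f[0] if f.size > 1 else 0.0
    lap[-1] = f[-2] - f[-1] if f.size > 1 else 0.0
    return lap


def step(sheet: EpithelialSheet, p: SimParams, iteration: int = 0) -> EpithelialSheet:
    """Apply one synchronous update; returns a new sheet.

    Order: reaction, diffusion, knot differentiation, differential growth
    (knot cells rise by ``pro`` relative to the extending base), border
    widening with anterior-posterior bias.
    """
    g, t = p.gene, p.tissue
    s = sheet.copy()
    lo, hi = s.lo, s.hi
    a = s.a[lo:hi]
    i = s.i[lo:hi]

    # reaction; saturation (kap) caps the activator amplitude so that
    # autoactivation strength controls where peaks ignite, not how much
    # inhibitor a mature peak exports
    auto = g.act * a * a / ((1.0 + g.inh * i) * (1.0 + g.kap * a * a))
    a_new = a + auto + g.bas - g.dega * a
    # differentiated knot cells secrete the inhibitory signal at the full
    # rate sec; undifferentiated cells secrete in proportion to a^2
    knots_before = sheet.knot_mask[lo:hi]
    secretion = g.sec * np.where(knots_before, 1.0, a * a)
    i_new = i + secretion - g.deg * i

    # diffusion, zero flux at the active-domain edges
    a_new += g.da * _laplacian_zeroflux(a)
    i_new += g.di * _laplacian_zeroflux(i)

    np.maximum(a_new, 0.0, out=a_new)
    np.maximum(i_new, 0.0, out=i_new)
    if not (np.all(np.isfinite(a_new)) and np.all(np.isfinite(i_new))):
        raise NumericalInstabilityError(iteration)
    # differentiated knot cells are stable signalling centres: their
    # activator is frozen, pinning the pattern against domain growth
    a_new[knots_before] = a[knots_before]
    s.a[lo:hi] = a_new
    s.i[lo:hi] = i_new

    # knot differentiation (irreversible)
    s.knot_mask[lo:hi] |= a_new > KNOT_THRESHOLD

    # differential growth: knot cells are elevated relative to the base
    s.height[s.knot_mask] += t.pro

    # border growth with anterior-posterior bias
    frac_ant = t.bia / (1.0 + t.bia)
    s.grow_anterior += t.bgr * frac_ant
    s.grow_posterior += t.bgr * (1.0 - frac_ant)
    while s.grow_anterior >= 1.0 and s.lo > 0:
        s.lo -= 1
        s.grow_anterior -= 1.0
    while s.grow_posterior >= 1.0 and s.hi < s.ncols:
        s.hi += 1
        s.grow_posterior -= 1.0
    return s


def _initial_sheet(p: SimParams) -> EpithelialSheet:
    t = p.tissue
    grown = int(np.ceil(p.n_iter * t.bgr)) + 2
    ncols = t.bwi + grown
    z = np.zeros(ncols)
    sheet = EpithelialSheet(
        ncols=ncols, height=z.copy(), a=z.copy(), i=z.copy(),
        knot_mask=np.zeros(ncols, dtype=bool),
        lo=(ncols - t.bwi) // 2, hi=(ncols - t.bwi) // 2 + t.bwi,
    )
    centre = (sheet.lo + sheet.hi) // 2
    sheet.a[centre - 1:centre + 2] = 0.05   # small central activator peak
    noise = float(p.gene.extra.get("noise", 0.0))
    if noise > 0:
        rng = np.random.default_rng(p.seed)
        act_slice = slice(sheet.lo, sheet.hi)
        sheet.a[act_slice] += noise * rng.random(sheet.hi - sheet.lo)
    return sheet


def simulate(p: SimParams):
    """Run the model for ``p.n_iter`` iterations from a seeded centre peak.

    Returns ``(sheet, cusps, phenotype)``.  Deterministic for fixed
    parameters and seed.
    """
    p.validate()
    sheet = _initial_sheet(p)
    for it in range(p.n_iter):
        sheet = step(sheet, p, iteration=it)
    cusps = detect_cusps(sheet)
    label = classify_phenotype(cusps, sheet)
    return sheet, cusps, label


def detect_cusps(sheet: EpithelialSheet,
                 min_prominence: float = DEFAULT_MIN_PROMINENCE) -> CuspSet:
    """Find cusps as prominent local maxima of the height profile.

    A local maximum counts as a cusp when its topographic prominence is at
    least ``min_prominence`` times the maximum height.  Flat-topped peaks
    report their middle cell.  Ties for the primary (tallest) cusp break
    to the first encountered.
    """
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must be in (0, 1)")
    h = np.asarray(sheet.height[sheet.lo:sheet.hi], dtype=float)
    if h.size == 0 or np.all(h == h[0]):
        return CuspSet([], 0, -1)
    hmax = float(h.max())
    from scipy.signal import find_peaks

    idx, props = find_peaks(h, prominence=min_prominence * hmax)
    cusps = [Cusp(int(i0) + sheet.lo, float(h[i0]), float(pr))
             for i0, pr in zip(idx, props["prominences"])]
    if not cusps:
        return CuspSet([], 0, -1)
    heights = np.array([c.height for c in cusps])
    primary = int(np.argmax(heights))  # argmax: first max wins
    return CuspSet(cusps, len(cusps), primary)


def classify_phenotype(c: CuspSet, sheet: EpithelialSheet,
                       ref_width: Optional[float] = None) -> PhenotypeLabel:
    """Map a cusp set to a phenotype category.

    ``serrated-like``: five or more cusps whose secondary prominences are
    all below 25% of the primary's.  ``widened``: a crown footprint more
    than 25% wider than ``ref_width`` (when given) without extra distinct
    cusps.  Width is the crown footprint: the number of cells elevated
    above 5% of the maximum height.
    """
    h = sheet.height[sheet.lo:sheet.hi]
    hmax = float(h.max()) if sheet.active_width else 0.0
    width = float((h >= 0.05 * hmax).sum()) if hmax > 0 else 0.0
    n = c.n
    widened = ref_width is not None and width > 1.25 * ref_width
    if n == 0:
        cat = "no-tooth"
    elif n == 1:
        cat = "widened" if widened else "unicuspid"
    elif n == 3:
        cat = "widened" if widened else "tricuspid"
    else:
        cat = f"multicuspid({n})"
        if n >= 5:
            prim = c.cusps[c.primary_index].prominence
            sec = [cc.prominence for k, cc in enumerate(c.cusps) if k != c.primary_index]
            if sec and max(sec) < 0.25 * prim:
                cat = "serrated-like"
    return PhenotypeLabel(cat, n, width, hmax)


def outline_of(sheet: EpithelialSheet) -> np.ndarray:
    """Occlusal profile of the tooth as a closed 2D outline, apex up.

    The outline runs along the height profile (anterior to posterior) and
    closes along the base; vertices are ordered counter-clockwise and not
    repeated.  Raises if there is no cusp to outline.
    """
    c = detect_cusps(sheet)
    if c.n == 0:
        raise ValueError("no-tooth phenotype: empty outline")
    h = sheet.height[sheet.lo:sheet.hi]
    x = np.arange(sheet.lo, sheet.hi, dtype=float)
    top = np.column_stack([x, h])
    base = np.column_stack([x[::-1], np.zeros_like(x)])
    return np.vstack([top, base])


# ---------------------------------------------------------------------------
# Parameter presets: flat key=value text, one parameter per line.

_GENE_KEYS = {"act", "inh", "deg", "da", "di", "sec"}
_TISSUE_KEYS = {"bwi", "bgr", "bia", "pro"}


def parse_params(text: str, label: str = "") -> SimParams:
    """Parse a flat ``key=value`` parameter file body into SimParams.

    Unknown keys are routed to the ``extra`` map of the gene network.
    ``#`` starts a comment.
    """
    gene_kw: dict = {}
    tissue_kw: dict = {}
    extra: dict = {}
    n_iter, seed = 11000, 0
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key == "n_iter":
            n_iter = int(float(val))
        elif key == "seed":
            seed = int(float(val))
        elif key in _GENE_KEYS:
            gene_kw[key] = float(val)
        elif key in _TISSUE_KEYS:
            tissue_kw[key] = int(float(val)) if key == "bwi" else float(val)
        else:
            extra[key] = float(val)
    gene = GeneNetworkParams(**gene_kw, extra=extra)
    tissue = TissueParams(**tissue_kw)
    return SimParams(gene=gene, tissue=tissue, n_iter=n_iter, seed=seed, label=label)


def preset_path(name: str):
    from importlib import resources

    return resources.files("cuspkit") / "presets" / f"{name}.txt"


def load_preset(name: str) -> SimParams:
    """Load a packaged preset ('shark' or 'seal') or a parameter file path."""
    import os

    if os.path.exists(name):
        with open(name) as fh:
            return parse_params(fh.read(), label=os.path.basename(name))
    res = preset_path(name)
    if not res.is_file():
        raise FileNotFoundError(f"no preset or parameter file named {name!r}")
    return parse_params(res.read_text(), label=name)
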