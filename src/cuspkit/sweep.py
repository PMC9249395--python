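"""Parameter-sweep engine: one-at-a-time scans, elimination, mimicry.

The in silico experimental procedure: each named parameter is varied in
relative steps (default 10%) around a baseline while all others are held
fixed, every resulting tooth is simulated and phenotyped, and candidate
parameter sets are refined by composable predicate filtering
("process of elimination").  ``mimic_treatment`` searches the activator
(act) and inhibitor (inh) axes for the minimal change reproducing the
phenotypes seen under Wnt down- or upregulation: unicuspid teeth for
downregulation, wider or supernumerary-cusped teeth for upregulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from cuspkit.simulator import (NumericalInstabilityError, PhenotypeLabel,
                               SimParams, classify_phenotype, detect_cusps,
                               simulate)

__all__ = ["SweepSpec", "SweepResult", "sweep", "sweep_factorial",
           "eliminate", "mimic_treatment"]


@dataclass
class SweepSpec:
    base: SimParams
    params: List[str]
    step: float = 0.10
    range: Tuple[float, float] = (0.5, 1.5)
    target: Optional[Callable[[pd.Series], bool]] = None

    def validate(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not self.params:
            raise ValueError("params list must be non-empty")
        for p in self.params:
            self.base._get(p)   # raises KeyError if unresolvable
        if self.range[0] > self.range[1]:
            raise ValueError("range must be (lo, hi) with lo <= hi")

    def multiples(self) -> np.ndarray:
        lo, hi = self.range
        n_lo = int(np.floor(round((1.0 - lo) / self.step, 9)))
        n_hi = int(np.floor(round((hi - 1.0) / self.step, 9)))
        return np.round(1.0 + self.step * np.arange(-n_lo, n_hi + 1), 9)


@dataclass
class SweepResult:
    grid: pd.DataFrame
    accepted: pd.DataFrame = field(default_factory=pd.DataFrame)
    base_phenotype: Optional[PhenotypeLabel] = None


_COLS = ["param", "multiple", "value", "param2", "multiple2", "value2",
         "n_cusps", "category", "width", "height", "error"]


def _evaluate(p: SimParams, ref_width: Optional[float]) -> dict:
    try:
        sheet, cusps, _ = simulate(p)
        lab = classify_phenotype(cusps, sheet, ref_width=ref_width)
        return dict(n_cusps=lab.n_cusps, category=lab.category,
                    width=lab.width, height=lab.height, error="")
    except NumericalInstabilityError as e:
        return dict(n_cusps=-1, category="unstable", width=np.nan,
                    height=np.nan, error=str(e))


def sweep(spec: SweepSpec) -> SweepResult:
    """One-at-a-time scan of each parameter over the relative range.

    Rows are recorded in deterministic scan order (parameters in the
    given order, multiples ascending).  Simulation failures are recorded
    per row, never fatal.
    """
    spec.validate()
    base_sheet, base_cusps, base_lab = simulate(spec.base)
    ref_width = base_lab.width
    rows = []
    for name in spec.params:
        base_val = spec.base._get(name)
        for m in spec.multiples():
            p = spec.base.with_scaled(name, float(m))
            r = _evaluate(p, ref_width)
            rows.append(dict(param=name, multiple=float(m),
                             value=base_val * float(m), param2="",
                             multiple2=np.nan, value2=np.nan, **r))
    grid = pd.DataFrame(rows, columns=_COLS)
    res = SweepResult(grid=grid, base_phenotype=base_lab)
    if spec.target is not None:
        res = eliminate(res, spec.target)
    return res


def sweep_factorial(spec: SweepSpec) -> SweepResult:
    """Two-parameter factorial scan (for interacting parameter pairs)."""
    spec.validate()
    if len(spec.params) != 2:
        raise ValueError("factorial mode needs exactly 2 parameters")
    _, _, base_lab = simulate(spec.base)
    ref_width = base_lab.width
    n1, n2 = spec.params
    v1, v2 = spec.base._get(n1), spec.base._get(n2)
    rows = []
    for m1 in spec.multiples():
        for m2 in spec.multiples():
            p = spec.base.with_scaled(n1, float(m1)).with_scaled(n2, float(m2))
            r = _evaluate(p, ref_width)
            rows.append(dict(param=n1, multiple=float(m1), value=v1 * float(m1),
                             param2=n2, multiple2=float(m2),
                             value2=v2 * float(m2), **r))
    grid = pd.DataFrame(rows, columns=_COLS)
    res = SweepResult(grid=grid, base_phenotype=base_lab)
    if spec.target is not None:
        res = eliminate(res, spec.target)
    return res


def eliminate(result: SweepResult, predicate: Callable[[pd.Series], bool]
              ) -> SweepResult:
    """Filter the accepted set by a phenotype predicate; composable.

    The predicate sees one grid row (with ``n_cusps``, ``category``,
    ``width``, ``height`` columns).  Filtering starts from the current
    accepted set when one exists, else from the full grid.
    """
    if result.grid.empty:
        raise ValueError("empty sweep grid")
    pool = result.accepted if len(result.accepted) else result.grid
    mask = pool.apply(predicate, axis=1)
    return SweepResult(grid=result.grid, accepted=pool[mask],
                       base_phenotype=result.base_phenotype)


def mimic_treatment(base: SimParams, direction: str, step: float = 0.10,
                    max_steps: int = 12) -> List[dict]:
    """Minimal single-parameter changes mimicking a Wnt perturbation.

    ``wnt-down`` walks act down and inh up until the tooth is unicuspid;
    ``wnt-up`` walks act up and inh down until the cusp count exceeds 3
    or the tooth is widened.  Returns one record per search axis with the
    minimal multiple achieving the target at the sweep resolution (or a
    ``no-transition`` record if none does within range).
    """
    _, base_cusps, base_lab = simulate(base)
    if base_lab.category != "tricuspid":
        raise ValueError(
            f"mimic_treatment needs a tricuspid baseline, got {base_lab.category}")
    if direction == "wnt-down":
        axes = [("act", -1), ("inh", +1)]

        def hit(lab):
            return lab["category"] == "unicuspid"
    elif direction == "wnt-up":
        axes = [("act", +1), ("inh", -1)]

        def hit(lab):
            return lab["n_cusps"] > 3 or lab["category"] == "widened"
    else:
        raise ValueError("direction must be 'wnt-down' or 'wnt-up'")

    out = []
    for name, sign in axes:
        found = None
        for j in range(1, max_steps + 1):
            m = round(1.0 + sign * step * j, 9)
            if m <= 0:
                break
            r = _evaluate(base.with_scaled(name, m), base_lab.width)
            if r["category"] != "unstable" and hit(r):
                found = dict(param=name, multiple=m,
                             value=base._get(name) * m, **r)
                break
        if found is None:
            found = dict(param=name, multiple=np.nan, value=np.nan,
                         n_cusps=-1, category="no-transition", width=np.nan,
                         height=np.nan, error="")
        out.append(found)
    return out
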