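"""Parameter sweeps, assemblage classification, and bisection of phase boundaries.

The engine behind the stability diagrams: sweep two scenario parameters over
a grid, solve each cell to equilibrium, label the phosphate-bearing solid
assemblage, and refine presence/absence boundaries by log-space bisection.
The whole pipeline is deterministic — identical inputs give identical maps.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

from .scenario import ScenarioSpec, build_composition
from .speciation import (
    EquilibriumState,
    SolverOptions,
    SpeciationError,
    solve_equilibrium,
)
from .thermodb import ThermoDB

__all__ = [
    "STRUVITE",
    "STRUVITE_FLOOR_MOL",
    "SWEEPABLE_PARAMETERS",
    "AxisSpec",
    "PhaseMap",
    "ThresholdResult",
    "PhaseMapError",
    "BracketError",
    "classify_assemblage",
    "other_solids",
    "struvite_present",
    "struvite_only",
    "sweep",
    "find_threshold",
    "export_phasemap",
    "read_phasemap",
]

STRUVITE = "MgNH4PO4:6H2O"
#: presence floor: the diagrams plot presence/absence, the solver needs a
#: numerical cutoff (moles per kg water)
STRUVITE_FLOOR_MOL = 1e-12

#: scenario parameters that may serve as sweep axes
SWEEPABLE_PARAMETERS = (
    "mg_ca_ratio",
    "ammonium_molality",
    "total_phosphate",
    "h2_partial_pressure",
    "ammonia_fraction",
)


class PhaseMapError(Exception):
    pass


class BracketError(PhaseMapError):
    """The predicate does not differ at the two bracket ends."""


def _apply(spec: ScenarioSpec, parameter: str, value: float) -> ScenarioSpec:
    if parameter == "mg_ca_ratio":
        return replace(spec, mg_ca_ratio_override=value)
    if parameter == "ammonium_molality":
        return replace(spec, ammonium_molality=value)
    if parameter == "total_phosphate":
        return replace(spec, total_phosphate=value)
    if parameter == "h2_partial_pressure":
        return replace(spec, h2_partial_pressure=value)
    if parameter == "ammonia_fraction":
        return replace(spec, ammonia_fraction=value)
    raise PhaseMapError(f"unknown sweep parameter {parameter!r}")


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: parameter name, scale, bounds, and point count."""

    parameter: str
    lo: float
    hi: float
    count: int
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise PhaseMapError(f"unknown sweep parameter {self.parameter!r}")
        if self.scale not in ("log", "linear"):
            raise PhaseMapError("scale must be 'log' or 'linear'")
        if not self.lo < self.hi:
            raise PhaseMapError("axis requires lo < hi")
        if self.scale == "log" and self.lo <= 0:
            raise PhaseMapError("log axis requires positive bounds")
        if self.count < 2:
            raise PhaseMapError("axis needs at least 2 points")

    def values(self) -> list[float]:
        n = self.count
        if self.scale == "log":
            la, lb = math.log10(self.lo), math.log10(self.hi)
            return [10.0 ** (la + (lb - la) * i / (n - 1)) for i in range(n)]
        return [self.lo + (self.hi - self.lo) * i / (n - 1) for i in range(n)]


def classify_assemblage(state: EquilibriumState) -> str:
    """Label: the sorted '+'-joined set of phosphate-bearing solids with
    positive moles, or ``"none"``.  Non-phosphate solids (oxides) are reported
    separately by :func:`other_solids`."""
    phos = sorted(
        s for s in state.solid_assemblage
        if "P" in _formula_of(state, s)
    )
    return "+".join(phos) if phos else "none"


def other_solids(state: EquilibriumState) -> str:
    rest = sorted(
        s for s in state.solid_assemblage
        if "P" not in _formula_of(state, s)
    )
    return "+".join(rest) if rest else "none"


_FORMULA_CACHE: dict[str, dict] = {}


def _formula_of(state: EquilibriumState, name: str) -> dict:
    # solids are classified by their stored elemental formulas; the formula is
    # recoverable without the db because assemblage names are db names
    from .thermodb import default_db

    if name not in _FORMULA_CACHE:
        db = default_db()
        _FORMULA_CACHE.update({r.name: dict(r.formula) for r in db})
    return _FORMULA_CACHE.get(name, {})


def struvite_present(state: EquilibriumState) -> bool:
    return (
        state.species_moles.get(STRUVITE, 0.0) / state.water_kg
        > STRUVITE_FLOOR_MOL
    )


def struvite_only(state: EquilibriumState) -> bool:
    """Struvite present and no other phosphate-bearing solid."""
    return struvite_present(state) and classify_assemblage(state) == STRUVITE


PREDICATES: dict[str, Callable[[EquilibriumState], bool]] = {
    "struvite-present": struvite_present,
    "struvite-only": struvite_only,
}


@dataclass
class PhaseMap:
    """Gridded assemblage labels over two swept axes."""

    axis1: AxisSpec
    axis2: AxisSpec
    labels: list[list[str]]          # [i1][i2]
    other: list[list[str]]
    struvite_moles: list[list[float]]  # per kg water
    pH: list[list[float]]
    status: list[list[str]]          # "ok" or "error: ..."
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n1, n2 = self.axis1.count, self.axis2.count
        for grid in (self.labels, self.other, self.struvite_moles, self.pH, self.status):
            if len(grid) != n1 or any(len(row) != n2 for row in grid):
                raise PhaseMapError("grid dimensions do not match axis point counts")


@dataclass(frozen=True)
class ThresholdResult:
    """A bisection-refined phase boundary along one parameter axis."""

    parameter: str
    value: float
    bracket: tuple[float, float]
    relative_width: float
    iterations: int
    predicate: str
    solves: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not lo <= self.value <= hi:
            raise PhaseMapError("threshold outside its final bracket")


def sweep(
    template: ScenarioSpec,
    axis1: AxisSpec,
    axis2: AxisSpec,
    db: ThermoDB,
    opts: SolverOptions | None = None,
) -> PhaseMap:
    """One equilibrium solve per grid cell; failed cells are flagged in the
    status grid, never silently filled."""
    if axis1.parameter == axis2.parameter:
        raise PhaseMapError("sweep axes must name distinct parameters")
    v1, v2 = axis1.values(), axis2.values()
    labels, others, struv, phs, status = [], [], [], [], []
    for a in v1:
        row_l, row_o, row_s, row_p, row_st = [], [], [], [], []
        s1 = _apply(template, axis1.parameter, a)
        for b in v2:
            s = _apply(s1, axis2.parameter, b)
            try:
                state = solve_equilibrium(build_composition(s), db, opts)
                row_l.append(classify_assemblage(state))
                row_o.append(other_solids(state))
                row_s.append(state.species_moles.get(STRUVITE, 0.0) / state.water_kg)
                row_p.append(state.pH)
                row_st.append("ok")
            except SpeciationError as exc:
                row_l.append("failed")
                row_o.append("failed")
                row_s.append(float("nan"))
                row_p.append(float("nan"))
                row_st.append(f"error: {exc}")
        labels.append(row_l)
        others.append(row_o)
        struv.append(row_s)
        phs.append(row_p)
        status.append(row_st)
    meta = {
        "template": template.to_dict(),
        "database_version": db.version,
        "options": {
            "si_tol": (opts or SolverOptions()).si_tol,
            "allow_reduced_p": (opts or SolverOptions()).allow_reduced_p,
        },
    }
    return PhaseMap(axis1, axis2, labels, others, struv, phs, status, meta)


def _bisect(
    test: Callable[[float], bool],
    lo: float,
    hi: float,
    tol: float,
    log_scale: bool,
    max_iter: int = 200,
) -> tuple[float, float, float, int]:
    """Bisection of a boolean predicate; returns (mid, lo, hi, iterations)."""
    t_lo, t_hi = test(lo), test(hi)
    if t_lo == t_hi:
        raise BracketError(
            f"predicate identical at both bracket ends ({t_lo} at {lo} and {hi})"
        )
    it = 0
    while it < max_iter:
        width = (hi / lo - 1.0) if log_scale else (hi - lo) / max(abs(lo), abs(hi))
        if width <= tol:
            break
        mid = math.sqrt(lo * hi) if log_scale else 0.5 * (lo + hi)
        if test(mid) == t_lo:
            lo = mid
        else:
            hi = mid
        it += 1
    mid = math.sqrt(lo * hi) if log_scale else 0.5 * (lo + hi)
    return mid, lo, hi, it


def find_threshold(
    template: ScenarioSpec,
    parameter: str,
    predicate: str | Callable[[EquilibriumState], bool],
    bracket: tuple[float, float],
    db: ThermoDB,
    opts: SolverOptions | None = None,
    tol: float = 1e-3,
    log_scale: bool = True,
) -> ThresholdResult:
    """Log-space bisection of a monotone assemblage predicate along one axis.

    The predicate must differ at the two bracket ends (checked; monotonicity
    along the axis is the caller's assertion).
    """
    pred_name = predicate if isinstance(predicate, str) else getattr(
        predicate, "__name__", "custom"
    )
    fn = PREDICATES[predicate] if isinstance(predicate, str) else predicate
    lo, hi = bracket
    if not 0 < lo < hi:
        raise PhaseMapError("bracket must satisfy 0 < lo < hi")
    counter = {"n": 0}

    def test(x: float) -> bool:
        counter["n"] += 1
        state = solve_equilibrium(
            build_composition(_apply(template, parameter, x)), db, opts
        )
        return fn(state)

    mid, flo, fhi, it = _bisect(test, lo, hi, tol, log_scale)
    width = (fhi / flo - 1.0) if log_scale else (fhi - flo) / max(abs(flo), abs(fhi))
    return ThresholdResult(
        parameter=parameter,
        value=mid,
        bracket=(flo, fhi),
        relative_width=width,
        iterations=it,
        predicate=pred_name,
        solves=counter["n"],
    )


_CSV_FIELDS = (
    "axis1_value", "axis2_value", "label", "other_solids",
    "struvite_mol_per_kg", "pH", "status",
)


def export_phasemap(pmap: PhaseMap, path: str | Path) -> None:
    """Long-format CSV with a JSON metadata header; round-trips losslessly."""
    path = Path(path)
    header_meta = {
        "axis1": {"parameter": pmap.axis1.parameter, "lo": pmap.axis1.lo,
                  "hi": pmap.axis1.hi, "count": pmap.axis1.count,
                  "scale": pmap.axis1.scale},
        "axis2": {"parameter": pmap.axis2.parameter, "lo": pmap.axis2.lo,
                  "hi": pmap.axis2.hi, "count": pmap.axis2.count,
                  "scale": pmap.axis2.scale},
        "metadata": pmap.metadata,
    }
    v1, v2 = pmap.axis1.values(), pmap.axis2.values()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# phasemap " + json.dumps(header_meta, sort_keys=True) + "\n")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_CSV_FIELDS)
        for i, a in enumerate(v1):
            for j, b in enumerate(v2):
                w.writerow([
                    repr(a), repr(b),
                    pmap.labels[i][j], pmap.other[i][j],
                    repr(pmap.struvite_moles[i][j]), repr(pmap.pH[i][j]),
                    pmap.status[i][j],
                ])


def read_phasemap(path: str | Path) -> PhaseMap:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# phasemap "):
            raise PhaseMapError(f"{path}: not a phasemap file")
        meta = json.loads(first[len("# phasemap "):])
        rows = list(csv.reader(fh))
    if rows[0] != list(_CSV_FIELDS):
        raise PhaseMapError(f"{path}: unexpected header {rows[0]}")
    ax1 = AxisSpec(**meta["axis1"])
    ax2 = AxisSpec(**meta["axis2"])
    n1, n2 = ax1.count, ax2.count
    if len(rows) - 1 != n1 * n2:
        raise PhaseMapError(f"{path}: expected {n1 * n2} data rows")
    labels = [[None] * n2 for _ in range(n1)]
    others = [[None] * n2 for _ in range(n1)]
    struv = [[None] * n2 for _ in range(n1)]
    phs = [[None] * n2 for _ in range(n1)]
    status = [[None] * n2 for _ in range(n1)]
    for k, row in enumerate(rows[1:]):
        i, j = divmod(k, n2)
        labels[i][j] = row[2]
        others[i][j] = row[3]
        struv[i][j] = float(row[4])
        phs[i][j] = float(row[5])
        status[i][j] = row[6]
    return PhaseMap(ax1, ax2, labels, others, struv, phs, status, meta["metadata"])
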