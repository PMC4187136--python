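"""Model-ocean scenario recipes.

Builds the bulk compositions the equilibrium solver consumes: a kilogram-
normalised early-ocean water mass holding seawater Na/Mg/Ca as chlorides,
a dinitrogen headspace scaled to the ocean/atmosphere mole ratio
(85,000 mol N2 per 5.56e7 mol H2O), phosphate added as NaH2PO4/Na2HPO4 in a
fixed 4:1 ratio, a sulfide (H2S/Na2S) pH buffer, and nitrogen split between
N2 and the reduced ammonia/ammonium pool.

Two ways of loading reduced nitrogen are provided.  The fraction sweep
converts a fraction of the N2 inventory to NH3 gas (total N conserved), the
mode used for the 0-100 % ammonia sweeps; the explicit ``ammonium_molality``
field adds reduced N as the neutral salt NH4Cl, which scans multi-molar
ammonium without exhausting the buffer.
"""
from __future__ import annotations

from dataclasses import dataclass, replace, asdict

from .speciation import (
    SolverOptions,
    SystemComposition,
    WATER_MOLES_PER_KG,
    solve_equilibrium,
)
from .thermodb import ELEMENTS, ThermoDB, parse_formula

__all__ = [
    "N2_TO_WATER_MOLE_RATIO",
    "ScenarioSpec",
    "ScenarioError",
    "BufferCapacityError",
    "default_early_ocean",
    "build_composition",
    "calibrate_buffer",
    "scenario_from_dict",
]

#: 85,000 mol N2 per 5.56e7 mol ocean water
N2_TO_WATER_MOLE_RATIO = 85_000.0 / 5.56e7

#: fixed NaH2PO4 : Na2HPO4 mole split of added phosphate
PHOSPHATE_SPLIT = (0.8, 0.2)

#: standard mean-seawater major cations, mol per kg water (Millero recipe)
SEAWATER_NA = 0.469
SEAWATER_MG = 0.0528
SEAWATER_CA = 0.0103


class ScenarioError(Exception):
    """Invalid scenario specification."""


class BufferCapacityError(ScenarioError):
    """The sulfide buffer cannot hold the target pH under the requested load."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one model-ocean composition.

    All concentration fields are mol per kg water; ``water_moles`` sets the
    extensive scale (55.51 mol = 1 kg basis).  ``mg_ca_ratio_override``
    re-partitions the Mg + Ca sum at a fixed total by default, or holds Mg
    and shrinks Ca when ``mg_ca_mode`` is ``"fix_mg"``.
    """

    water_moles: float = WATER_MOLES_PER_KG
    n2_moles: float = WATER_MOLES_PER_KG * N2_TO_WATER_MOLE_RATIO
    ammonia_fraction: float = 0.0
    na_molality: float = SEAWATER_NA
    mg_molality: float = SEAWATER_MG
    ca_molality: float = SEAWATER_CA
    mg_ca_ratio_override: float | None = None
    mg_ca_mode: str = "repartition"
    total_phosphate: float = 1e-5
    ammonium_molality: float = 0.0
    sulfide_total: float = 7.0
    sulfide_na2s_fraction: float = 0.4300
    h2_partial_pressure: float | None = None

    def __post_init__(self) -> None:
        numeric = (
            "water_moles", "n2_moles", "na_molality", "mg_molality",
            "ca_molality", "total_phosphate", "ammonium_molality",
            "sulfide_total",
        )
        for name in numeric:
            if getattr(self, name) < 0:
                raise ScenarioError(f"{name} must be non-negative")
        if not 0.0 <= self.ammonia_fraction <= 1.0:
            raise ScenarioError("ammonia_fraction must lie in [0, 1]")
        if not 0.0 <= self.sulfide_na2s_fraction <= 1.0:
            raise ScenarioError("sulfide_na2s_fraction must lie in [0, 1]")
        if self.water_moles <= 0:
            raise ScenarioError("water_moles must be positive")
        if self.mg_ca_mode not in ("repartition", "fix_mg"):
            raise ScenarioError("mg_ca_mode must be 'repartition' or 'fix_mg'")
        if self.mg_ca_ratio_override is not None and self.mg_ca_ratio_override <= 0:
            raise ScenarioError("mg_ca_ratio_override must be positive")

    @property
    def water_kg(self) -> float:
        return self.water_moles / WATER_MOLES_PER_KG

    def mg_ca(self) -> tuple[float, float]:
        """Effective Mg and Ca molalities after any ratio override."""
        mg, ca = self.mg_molality, self.ca_molality
        r = self.mg_ca_ratio_override
        if r is None:
            return mg, ca
        if self.mg_ca_mode == "fix_mg":
            if mg <= 0:
                raise ScenarioError("fix_mg override needs positive Mg")
            return mg, mg / r
        total = mg + ca
        if total <= 0:
            raise ScenarioError("Mg/Ca override with zero Mg + Ca total")
        ca_new = total / (1.0 + r)
        return total - ca_new, ca_new

    def to_dict(self) -> dict:
        return asdict(self)


def scenario_from_dict(data: dict) -> ScenarioSpec:
    known = set(ScenarioSpec.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ScenarioError(f"unknown scenario fields: {sorted(unknown)}")
    return ScenarioSpec(**data)


def default_early_ocean() -> ScenarioSpec:
    """The baseline model ocean: 1-kg water basis, proportionate N2 inventory,
    seawater Na/Mg/Ca, 1e-5 mol/kg phosphate (4:1 salt split), sulfide buffer,
    all nitrogen as N2 (sweep baseline)."""
    return ScenarioSpec()


def build_composition(spec: ScenarioSpec) -> SystemComposition:
    """Pure arithmetic: sum the recipe's neutral salts, acids and gases into
    an elemental inventory.  The result is charge-neutral by construction."""
    kg = spec.water_kg
    totals = {el: 0.0 for el in ELEMENTS}

    def add(formula: str, moles: float) -> None:
        if moles == 0.0:
            return
        if moles < 0:
            raise ScenarioError(f"negative moles for {formula}")
        for el, cnt in parse_formula(formula).items():
            totals[el] += cnt * moles

    add("H2 O1", spec.water_moles)
    mg, ca = spec.mg_ca()
    add("Na1 Cl1", spec.na_molality * kg)
    add("Mg1 Cl2", mg * kg)
    add("Ca1 Cl2", ca * kg)
    p = spec.total_phosphate * kg
    add("Na1 H2 P1 O4", PHOSPHATE_SPLIT[0] * p)
    add("Na2 H1 P1 O4", PHOSPHATE_SPLIT[1] * p)
    s = spec.sulfide_total * kg
    add("H2 S1", (1.0 - spec.sulfide_na2s_fraction) * s)
    add("Na2 S1", spec.sulfide_na2s_fraction * s)
    n_amm = 0.0
    nh3_from_sweep = 2.0 * spec.n2_moles * spec.ammonia_fraction
    add("N1 H3", nh3_from_sweep)
    n_amm += nh3_from_sweep
    add("N2", spec.n2_moles * (1.0 - spec.ammonia_fraction))
    nh4cl = spec.ammonium_molality * kg
    add("N1 H4 Cl1", nh4cl)
    n_amm += nh4cl
    totals = {el: v for el, v in totals.items() if v > 0.0}
    constraints = {"S(-II) only", "P(+V) only"}
    constraints.add(
        "N: H2-coupled" if spec.h2_partial_pressure is not None
        else "N: fixed speciation"
    )
    return SystemComposition(
        element_totals=totals,
        nitrogen_as_ammonium=0.0 if spec.h2_partial_pressure is not None else n_amm,
        h2_fugacity=spec.h2_partial_pressure,
        frozen_constraints=frozenset(constraints),
    )


def calibrate_buffer(
    spec: ScenarioSpec,
    db: ThermoDB,
    target_pH: float,
    opts: SolverOptions | None = None,
    tol: float = 0.01,
) -> ScenarioSpec:
    """Tune the H2S : Na2S split (and, if needed, the total sulfide loading)
    so the spec solves to ``target_pH`` and the buffer holds the pH shift from
    the scenario's maximum NH3 load below 0.1.

    Raises :class:`BufferCapacityError` when the requested load exceeds what
    the sulfide inventory can absorb.
    """
    if not 7.6 <= target_pH <= 7.9:
        raise ScenarioError("target pH must lie within the buffered band [7.6, 7.9]")
    max_nh3 = 2.0 * spec.n2_moles / spec.water_kg  # mol/kg at 100 % conversion
    if spec.sulfide_total <= 0:
        if max_nh3 > 0 or spec.ammonium_molality > 0:
            raise BufferCapacityError(
                "no sulfide buffer but an ammonia load is requested"
            )
        return spec

    def solved_ph(s: ScenarioSpec) -> float:
        return solve_equilibrium(build_composition(s), db, opts).pH

    work = spec
    for _ in range(7):  # doubling ladder on total sulfide
        frac = _solve_split(work, db, target_pH, opts, tol)
        if frac is not None:
            calibrated = replace(work, sulfide_na2s_fraction=frac)
            shifted = replace(calibrated, ammonia_fraction=1.0)
            if abs(solved_ph(shifted) - target_pH) < 0.1:
                return calibrated
        work = replace(work, sulfide_total=work.sulfide_total * 2.0)
    raise BufferCapacityError(
        f"cannot hold pH {target_pH} under the scenario's maximum ammonia load "
        f"(sulfide ladder exhausted at {work.sulfide_total} mol/kg)"
    )


def _solve_split(spec, db, target_pH, opts, tol) -> float | None:
    """Bisect the Na2S fraction to the target pH; None if unreachable."""
    lo, hi = 1e-6, 1.0 - 1e-6

    def ph_at(frac: float) -> float:
        s = replace(spec, sulfide_na2s_fraction=frac)
        return solve_equilibrium(build_composition(s), db, opts).pH

    ph_lo, ph_hi = ph_at(lo), ph_at(hi)
    if not (ph_lo - tol <= target_pH <= ph_hi + tol):
        return None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        ph = ph_at(mid)
        if abs(ph - target_pH) < tol * 0.1:
            return mid
        if ph < target_pH:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)
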