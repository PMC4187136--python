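"""Equilibrium speciation of a closed water + headspace system at 298.15 K, 1 bar.

The solver distributes a bulk elemental inventory among aqueous solutes,
headspace gases, and pure solid phases so that every mass-action law holds
and every candidate solid satisfies the complementarity condition
(present with saturation index 0, or absent and undersaturated).  This is
the dual formulation of total-Gibbs-energy minimisation under mass balance
and is far better conditioned at trace concentrations than direct
minimisation over moles.

Activities are ideal throughout: molality for solutes, partial pressure in
bar for gases, unity for solids and for the solvent.  No activity-coefficient
model is applied.

Redox handling
--------------
The model deliberately freezes redox state rather than letting an
unconstrained solver shuttle electrons:

* sulfur is locked to the -2 state (H2S/HS- only);
* phosphorus is locked to +5 unless ``allow_reduced_p`` is set;
* nitrogen has two modes.  In the default *fixed-speciation* mode the
  reduced-nitrogen pool (NH3 + NH4+) is an input and dissolved/gaseous N2 is
  inert.  In the *H2-coupled* mode an imposed hydrogen fugacity equilibrates
  the whole nitrogen inventory through 1/2 N2 + 3/2 H2 = NH3.

Mechanically the freezes fall out of the basis construction: any species
whose formula/charge vector is not representable over the active basis
(plus solvent, plus any imposed-fugacity species) is excluded from the
active set, so e.g. O2 or monatomic H simply cannot acquire mass in the
fixed-speciation mode.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .thermodb import (
    ELEMENTS,
    LN10RT,
    P_REF,
    R_KJ,
    T_REF,
    Reaction,
    SpeciesRecord,
    ThermoDB,
    UnknownSpeciesError,
    reaction_logK,
)

__all__ = [
    "WATER_MOLES_PER_KG",
    "SystemComposition",
    "SolverOptions",
    "EquilibriumState",
    "ResidualReport",
    "SpeciationError",
    "NonConvergenceError",
    "InfeasibleCompositionError",
    "solve_equilibrium",
    "saturation_index",
    "ammonia_redox_equilibrium",
    "verify_state",
]

LN10 = math.log(10.0)
#: moles of H2O per kilogram of water (molar mass 18.01528 g/mol)
WATER_MOLES_PER_KG = 1000.0 / 18.01528

#: species excluded from the default active set (vanishingly scarce under the
#: reducing, pH-buffered conditions modelled here, and numerically destabilising)
DEFAULT_EXCLUDED = frozenset({"H(g)", "HNO3"})
#: reduced-phosphorus species, frozen unless explicitly re-enabled
REDUCED_P_SPECIES = frozenset(
    {"H3PO2", "H2PO2-", "H3PO3", "H2PO3-", "HPO3-2", "CaHPO3"}
)

# per-component basis candidates, first active one wins
_BASIS_PREFERENCE: tuple[tuple[str, ...], ...] = (
    ("H+",),
    ("Na+",),
    ("Cl-",),
    ("Mg+2",),
    ("Ca+2",),
    ("H2PO4-", "HPO4-2", "PO4-3", "H3PO4"),
    ("HS-", "H2S"),
    ("NH4+", "NH3"),
    ("N2",),
)


class SpeciationError(Exception):
    """Base class for solver errors."""


class NonConvergenceError(SpeciationError):
    """Newton or assemblage iteration failed; carries the residual report."""

    def __init__(self, message: str, report: "ResidualReport | None" = None):
        super().__init__(message)
        self.report = report


class InfeasibleCompositionError(SpeciationError):
    """An element has positive total but no active species can host it."""


@dataclass(frozen=True)
class SystemComposition:
    """Bulk elemental inventory of a closed water + headspace system.

    ``element_totals`` are moles (the solvent water kilograms set the
    molality normalisation; a 1-kg recipe uses ~55.51 mol H2O and 111 mol H).
    ``nitrogen_as_ammonium`` is the portion of total N (mol N) supplied in the
    reduced pool; the remainder is dinitrogen, inert in fixed-speciation mode.
    A non-None ``h2_fugacity`` (bar) switches the solver to the H2-coupled
    nitrogen mode.
    """

    element_totals: Mapping[str, float]
    temperature: float = T_REF
    pressure: float = P_REF
    nitrogen_as_ammonium: float = 0.0
    h2_fugacity: float | None = None
    frozen_constraints: frozenset[str] = frozenset(
        {"S(-II) only", "P(+V) only"}
    )

    def __post_init__(self) -> None:
        for el, tot in self.element_totals.items():
            if el not in ELEMENTS:
                raise InfeasibleCompositionError(f"unknown element {el!r}")
            if tot < 0:
                raise InfeasibleCompositionError(f"negative total for {el}: {tot}")
        if self.element_totals.get("O", 0.0) <= 0 or self.element_totals.get("H", 0.0) <= 0:
            raise InfeasibleCompositionError("composition must contain solvent water")
        n_tot = self.element_totals.get("N", 0.0)
        if self.nitrogen_as_ammonium < 0 or self.nitrogen_as_ammonium > n_tot + 1e-12:
            raise InfeasibleCompositionError(
                "nitrogen_as_ammonium must lie within the total N inventory"
            )

    @property
    def water_kg(self) -> float:
        """Solvent mass implied by the oxygen inventory net of oxy-anions.

        Used only as the molality normalisation; exact water closure is
        recomputed after solving.
        """
        o_in_p = 4.0 * self.element_totals.get("P", 0.0)
        n_w = self.element_totals.get("O", 0.0) - o_in_p
        return n_w / WATER_MOLES_PER_KG

    def scaled(self, factor: float) -> "SystemComposition":
        return replace(
            self,
            element_totals={k: v * factor for k, v in self.element_totals.items()},
            nitrogen_as_ammonium=self.nitrogen_as_ammonium * factor,
        )


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the equilibrium solve."""

    balance_tol: float = 1e-9        # relative, element/component balance
    charge_tol: float = 1e-12        # absolute, mol per kg water
    si_tol: float = 1e-6             # log10 units, solid complementarity
    newton_tol: float = 1e-12        # scaled residual norm
    max_newton_iter: int = 200
    max_assemblage_iter: int = 50
    exclude_species: frozenset[str] = DEFAULT_EXCLUDED
    include_species: frozenset[str] = frozenset()
    allow_reduced_p: bool = False

    def __post_init__(self) -> None:
        for name in ("balance_tol", "charge_tol", "si_tol", "newton_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ResidualReport:
    """Verification residuals for a solved (or hand-built) state."""

    element_residuals: dict[str, float] = field(default_factory=dict)  # relative
    charge_residual: float = 0.0  # mol per kg water
    mass_action_residuals: dict[str, float] = field(default_factory=dict)  # log10
    complementarity_violations: dict[str, float] = field(default_factory=dict)  # SI
    findings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def summary(self) -> str:
        if self.ok:
            return "all residuals within tolerance"
        return "; ".join(self.findings)


@dataclass
class EquilibriumState:
    """Solved distribution of the inventory among species, plus diagnostics."""

    species_moles: dict[str, float]
    solid_assemblage: frozenset[str]
    pH: float
    gas_partial_pressures: dict[str, float]
    total_G: float  # kJ
    composition: SystemComposition
    basis_activities: dict[str, float]
    si_table: dict[str, float]
    water_kg: float
    options: SolverOptions = field(default_factory=SolverOptions)
    frozen_species: tuple[str, ...] = ()

    def molality(self, name: str) -> float:
        return self.species_moles.get(name, 0.0) / self.water_kg

    def to_dict(self) -> dict:
        """JSON-ready document with stable key ordering."""
        return {
            "species_moles": {k: self.species_moles[k] for k in sorted(self.species_moles)},
            "molalities": {
                k: self.species_moles[k] / self.water_kg
                for k in sorted(self.species_moles)
            },
            "solid_assemblage": sorted(self.solid_assemblage),
            "pH": self.pH,
            "gas_partial_pressures": {
                k: self.gas_partial_pressures[k]
                for k in sorted(self.gas_partial_pressures)
            },
            "total_G_kJ": self.total_G,
            "water_kg": self.water_kg,
            "basis_activities": {
                k: self.basis_activities[k] for k in sorted(self.basis_activities)
            },
            "saturation_indices": {k: self.si_table[k] for k in sorted(self.si_table)},
            "frozen_species": list(self.frozen_species),
            "composition": {
                "element_totals": {
                    k: self.composition.element_totals[k]
                    for k in sorted(self.composition.element_totals)
                },
                "temperature_K": self.composition.temperature,
                "pressure_bar": self.composition.pressure,
                "nitrogen_as_ammonium_mol": self.composition.nitrogen_as_ammonium,
                "h2_fugacity_bar": self.composition.h2_fugacity,
                "frozen_constraints": sorted(self.composition.frozen_constraints),
            },
        }


# ---------------------------------------------------------------------------
# internal model assembly
# ---------------------------------------------------------------------------


class _Model:
    """Basis construction, formation matrix, and Newton/active-set machinery."""

    def __init__(self, comp: SystemComposition, db: ThermoDB, opts: SolverOptions):
        self.comp = comp
        self.db = db
        self.opts = opts
        self.h2_mode = comp.h2_fugacity is not None
        self.kg_w = comp.water_kg
        if self.kg_w <= 0:
            raise InfeasibleCompositionError("non-positive solvent water inventory")
        self.solvent = db.solvent
        # pressure available to headspace gases other than imposed-fugacity H2
        self.P_avail = comp.pressure - (comp.h2_fugacity or 0.0)
        if self.P_avail <= 0 and self.h2_mode:
            self.P_avail = 0.0
        self._build_active_set()
        self._build_basis()
        self._decompose_species()
        self._project_totals()

    # -- species bookkeeping ------------------------------------------------

    def _build_active_set(self) -> None:
        excluded = set(self.opts.exclude_species) - set(self.opts.include_species)
        if not self.opts.allow_reduced_p:
            excluded |= REDUCED_P_SPECIES - set(self.opts.include_species)
        present = {
            el for el, tot in self.comp.element_totals.items() if tot > 0.0
        }
        self.active: list[SpeciesRecord] = []
        self.frozen: list[str] = []
        for rec in self.db:
            if rec.phase_class == "solvent":
                continue
            if rec.name in excluded:
                self.frozen.append(rec.name)
                continue
            needed = {el for el in rec.formula if rec.formula[el] > 0}
            if not needed <= present:
                continue  # element absent from the inventory
            self.active.append(rec)

    def _build_basis(self) -> None:
        amm = self.comp.nitrogen_as_ammonium
        active_names = {r.name for r in self.active}
        n_total = self.comp.element_totals.get("N", 0.0)
        names: list[str] = []
        for group in _BASIS_PREFERENCE:
            if group[0] == "H+":
                names.append("H+")
                continue
            if group[0] == "NH4+":
                # reduced-nitrogen pool: only a component in fixed-speciation mode
                if self.h2_mode or amm <= 0:
                    continue
            if group[0] == "N2":
                if self.h2_mode:
                    if n_total <= 0:
                        continue
                elif n_total - amm <= 1e-15 * max(n_total, 1.0):
                    continue
            for cand in group:
                if cand in active_names:
                    names.append(cand)
                    break
        self.basis_names = names
        # fixed-activity columns: solvent always; imposed-fugacity H2 in h2 mode
        self.fixed_names: list[str] = ["H2O"]
        self.fixed_lna: list[float] = [0.0]
        if self.h2_mode:
            if self.comp.h2_fugacity <= 0:
                raise InfeasibleCompositionError("h2_fugacity must be positive")
            self.fixed_names.append("H2(g)")
            self.fixed_lna.append(math.log(self.comp.h2_fugacity))

    @staticmethod
    def _vec(rec: SpeciesRecord) -> np.ndarray:
        v = np.zeros(len(ELEMENTS) + 1)
        for i, el in enumerate(ELEMENTS):
            v[i] = rec.formula.get(el, 0)
        v[-1] = rec.charge
        return v

    def _decompose_species(self) -> None:
        db = self.db
        nb = len(self.basis_names)
        cols = [self._vec(db[n]) for n in self.basis_names]
        cols += [self._vec(db[n]) for n in self.fixed_names]
        A = np.column_stack(cols)
        self._A_basis = A

        aq, gas, solids = [], [], []
        coeffs: dict[str, np.ndarray] = {}
        logk: dict[str, float] = {}
        basis_set = set(self.basis_names)
        for rec in self.active:
            if rec.name in basis_set:
                continue
            if rec.name in self.fixed_names:
                continue
            target = self._vec(rec)
            c, res, *_ = np.linalg.lstsq(A, target, rcond=None)
            resid = np.linalg.norm(A @ c - target)
            if resid > 1e-8:
                self.frozen.append(rec.name)
                continue
            # stoichiometric coefficients are rationals with denominator <= 2;
            # snapping removes least-squares rounding noise
            snapped = np.round(c * 2.0) / 2.0
            if np.linalg.norm(A @ snapped - target) < 1e-9:
                c = snapped
            dg = rec.dGf - sum(
                c[j] * db[n].dGf for j, n in enumerate(self.basis_names)
            ) - sum(
                c[nb + j] * db[n].dGf for j, n in enumerate(self.fixed_names)
            )
            k = -dg / LN10RT  # log10 K of formation from basis
            # constant term: logK plus fixed-activity contributions
            const = k * LN10 + sum(
                c[nb + j] * self.fixed_lna[j] for j in range(len(self.fixed_names))
            )
            coeffs[rec.name] = c
            logk[rec.name] = const
            if rec.phase_class == "aqueous":
                aq.append(rec.name)
            elif rec.phase_class == "gas":
                gas.append(rec.name)
            else:
                solids.append(rec.name)
        self.sec_aq = aq
        self.gases = gas
        self.cand_solids = sorted(solids)
        self.coeffs = coeffs
        self.lnk = logk
        self.nb = nb
        # stacked coefficient matrices over basis only
        def stack(names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            if not names:
                return (np.zeros((0, nb)), np.zeros(0), np.zeros(0))
            C = np.array([coeffs[n][:nb] for n in names])
            K = np.array([logk[n] for n in names])
            W = np.array([coeffs[n][nb] for n in names])  # water coefficient
            return C, K, W

        self.C_aq, self.K_aq, self.W_aq = stack(aq)
        self.C_gas, self.K_gas, self.W_gas = stack(gas)
        self.solid_C = {n: coeffs[n][:nb] for n in self.cand_solids}
        self.solid_K = {n: logk[n] for n in self.cand_solids}
        self.solid_W = {n: coeffs[n][nb] for n in self.cand_solids}
        # charge vector over basis species
        self.z_basis = np.array([db[n].charge if n in db else 1 for n in self.basis_names], dtype=float)
        self.z_aq = np.array([db[n].charge for n in aq], dtype=float) if aq else np.zeros(0)

    def _project_totals(self) -> None:
        """Express the elemental inventory in basis coordinates.

        Every non-proton basis species carries exactly one characteristic
        element outside {H, O}, so the projection is exact per-component
        elimination: no least-squares step that would let the huge hydrogen
        and oxygen inventories contaminate trace-element totals.
        """
        totals = self.comp.element_totals
        amm = self.comp.nitrogen_as_ammonium
        db = self.db
        nb = self.nb
        T = np.zeros(nb)
        hosted = {"H", "O"}
        for j, name in enumerate(self.basis_names):
            if name == "H+":
                continue
            rec = db[name]
            char = [el for el in rec.formula if el not in ("H", "O")]
            el = char[0]
            cnt = rec.formula[el]
            if el == "N" and not self.h2_mode:
                T[j] = amm / cnt if name != "N2" else (totals.get("N", 0.0) - amm) / cnt
            else:
                T[j] = totals.get(el, 0.0) / cnt
            hosted.add(el)
        for el, tot in totals.items():
            if tot > 0 and el not in hosted:
                raise InfeasibleCompositionError(
                    f"element {el} has positive total but no active species to host it"
                )
        # excess protons from charge neutrality of the inputs
        j_h = self.basis_names.index("H+")
        T[j_h] = -sum(
            T[j] * db[name].charge
            for j, name in enumerate(self.basis_names)
            if name != "H+"
        )
        # water from the oxygen inventory
        n_w = totals.get("O", 0.0) - sum(
            T[j] * db[name].formula.get("O", 0)
            for j, name in enumerate(self.basis_names)
        )
        # hydrogen closure is then a consistency check on the inputs
        h_implied = 2.0 * n_w + sum(
            T[j] * db[name].formula.get("H", 0)
            for j, name in enumerate(self.basis_names)
        )
        h_in = totals.get("H", 0.0)
        if abs(h_implied - h_in) > 1e-9 * max(1.0, h_in):
            raise InfeasibleCompositionError(
                "element inventory inconsistent with a charge-neutral recipe "
                f"over the active basis (hydrogen residual {h_implied - h_in:.3e})"
            )
        self.T_basis = T
        self.n_water0 = n_w
        if self.n_water0 <= 0:
            raise InfeasibleCompositionError("inventory implies non-positive water")

    # -- evaluation ---------------------------------------------------------

    def _secondary(self, u: np.ndarray):
        """Molalities of secondary aqueous species and gas partial pressures."""
        m_aq = np.exp(self.K_aq + self.C_aq @ u) if self.sec_aq else np.zeros(0)
        p_gas = np.exp(self.K_gas + self.C_gas @ u) if self.gases else np.zeros(0)
        return m_aq, p_gas

    def solve(self):
        """Active-set loop around the Newton mass-action solve."""
        opts = self.opts
        active_solids: list[str] = []
        gas_on = bool(self.gases) and (
            ("N2" in self.basis_names and not self.h2_mode
             and self.T_basis[self.basis_names.index("N2")] > 0)
        )
        u, ln_ngas, n_solids = None, math.log(max(self.n_water0 * 1e-3, 1e-6)), {}
        last_added: str | None = None
        failed_sets: set[frozenset] = set()
        for _ in range(opts.max_assemblage_iter):
            try:
                u, ln_ngas, n_solids = self._newton(active_solids, gas_on, u, ln_ngas)
            except NonConvergenceError as exc:
                # a freshly added solid can make the trial assemblage
                # unsolvable when it is about to supplant a competitor
                # (e.g. struvite displacing farringtonite); restart from the
                # newcomer alone and let complementarity rebuild the set
                failed_sets.add(frozenset(active_solids))
                if last_added is not None and len(active_solids) > 1:
                    active_solids = [last_added]
                    if frozenset(active_solids) in failed_sets:
                        raise
                    last_added = None
                    u = None
                    continue
                raise
            # remove solids driven negative (one at a time, most negative first)
            neg = [s for s in active_solids if n_solids[s] < 0.0]
            if neg:
                worst = min(neg, key=lambda s: n_solids[s])
                active_solids.remove(worst)
                last_added = None
                continue
            # gas phase collapse
            if gas_on and math.exp(ln_ngas) < 1e-15 * self.n_water0:
                gas_on = False
                continue
            # gas phase nucleation: hypothetical pressures exceed total P
            if not gas_on and self.gases and self.P_avail > 0:
                _, p_gas = self._secondary(u)
                if p_gas.sum() > self.P_avail * (1 + opts.si_tol):
                    gas_on = True
                    continue
            # supersaturated solids
            sis = {
                s: (self.solid_K[s] + self.solid_C[s] @ u) / LN10
                for s in self.cand_solids
                if s not in active_solids
            }
            if sis:
                best = max(sis.items(), key=lambda kv: (kv[1], kv[0]))
                # tie-break: largest SI, then reverse-lexicographic via key above;
                # make exact ties deterministic lexicographically
                top_si = best[1]
                tied = sorted(s for s, v in sis.items() if v == top_si)
                best = (tied[0], top_si)
                if top_si > opts.si_tol:
                    if frozenset(active_solids + [best[0]]) in failed_sets:
                        raise NonConvergenceError(
                            "assemblage oscillates between unsolvable solid "
                            f"sets (stuck adding {best[0]})"
                        )
                    active_solids.append(best[0])
                    last_added = best[0]
                    continue
            return self._assemble(u, gas_on, ln_ngas, active_solids, n_solids)
        raise NonConvergenceError(
            "assemblage iteration did not settle within "
            f"{opts.max_assemblage_iter} iterations",
            getattr(last_exc, "report", None),
        )

    def _init_u(self) -> np.ndarray:
        u = np.zeros(self.nb)
        for j, name in enumerate(self.basis_names):
            if name == "H+":
                u[j] = math.log(1e-7)
            else:
                t = max(self.T_basis[j], 1e-14) / self.kg_w
                u[j] = math.log(max(min(t * 0.5, 50.0), 1e-14))
        return u

    def _newton(self, active_solids, gas_on, u0, ln_ngas0):
        attempts = [0.0, -2.3025850929940457, 2.3025850929940457]
        last_report = None
        for k, shift in enumerate(attempts):
            u = (self._init_u() if u0 is None else u0.copy())
            if k > 0:
                u = self._init_u() + shift
            ln_ngas = ln_ngas0
            try:
                return self._newton_once(active_solids, gas_on, u, ln_ngas)
            except NonConvergenceError as exc:
                last_report = exc.report
                continue
        raise NonConvergenceError(
            "Newton iteration failed from all starts "
            f"(assemblage {sorted(active_solids)}, gas={'on' if gas_on else 'off'})",
            last_report,
        )

    def _fj(self, active_solids, gas_on, u, ln_ngas, n_s, want_jacobian=True):
        """Scaled residual vector (and Jacobian) at one iterate."""
        nb = self.nb
        ns = len(active_solids)
        ng = 1 if gas_on else 0
        P = self.comp.pressure
        kg = self.kg_w
        nun = nb + ng + ns
        m_aq, p_gas = self._secondary(u)
        m_basis = np.exp(u)
        ngas = math.exp(ln_ngas) if gas_on else 0.0
        x_gas = p_gas / P if gas_on else np.zeros(0)

        F = np.zeros(nun)
        J = np.zeros((nun, nun)) if want_jacobian else None
        for j in range(nb):
            tot = m_basis[j] * kg
            absr = m_basis[j] * kg
            if self.sec_aq:
                contrib = self.C_aq[:, j] * m_aq
                tot += contrib.sum() * kg
                absr += np.abs(contrib).sum() * kg
            if gas_on and self.gases:
                gcon = self.C_gas[:, j] * x_gas * ngas
                tot += gcon.sum()
                absr += np.abs(gcon).sum()
            for i, s in enumerate(active_solids):
                tot += self.solid_C[s][j] * n_s[i]
                absr += abs(self.solid_C[s][j] * n_s[i])
            scale = max(abs(self.T_basis[j]), absr, 1e-12)
            F[j] = (tot - self.T_basis[j]) / scale
            if want_jacobian:
                row = np.zeros(nb)
                row[j] += m_basis[j] * kg
                if self.sec_aq:
                    row += (self.C_aq[:, j] * m_aq) @ self.C_aq * kg
                if gas_on and self.gases:
                    row += (self.C_gas[:, j] * x_gas * ngas) @ self.C_gas
                J[j, :nb] = row / scale
                if gas_on:
                    J[j, nb] = (self.C_gas[:, j] * x_gas).sum() * ngas / scale
                for i, s in enumerate(active_solids):
                    J[j, nb + ng + i] = self.solid_C[s][j] / scale
        if gas_on:
            pa = self.P_avail
            F[nb] = (p_gas.sum() - pa) / pa
            if want_jacobian:
                J[nb, :nb] = (p_gas @ self.C_gas) / pa
                J[nb, nb] = 0.0
        # solid equilibrium (SI = 0), linear in u
        for i, s in enumerate(active_solids):
            F[nb + ng + i] = self.solid_K[s] + self.solid_C[s] @ u
            if want_jacobian:
                J[nb + ng + i, :nb] = self.solid_C[s]
        return F, J

    def _newton_once(self, active_solids, gas_on, u, ln_ngas):
        opts = self.opts
        nb = self.nb
        ns = len(active_solids)
        ng = 1 if gas_on else 0
        n_s = np.full(ns, 0.0)
        best = math.inf
        best_iter = (u.copy(), ln_ngas, n_s.copy())
        stall = 0
        F, J = self._fj(active_solids, gas_on, u, ln_ngas, n_s)
        for _ in range(opts.max_newton_iter):
            norm = np.max(np.abs(F)) if F.size else 0.0
            if norm < opts.newton_tol:
                return u, ln_ngas, dict(zip(active_solids, n_s))
            if norm < best:
                best = norm
                best_iter = (u.copy(), ln_ngas, n_s.copy())
                stall = 0
            else:
                stall += 1
                if stall > 20:
                    break
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(J, -F, rcond=None)
            limit = np.max(np.abs(step[: nb + ng])) if nb + ng else 0.0
            if limit > 4.0:
                step *= 4.0 / limit
            # backtracking line search on the max-norm of the residual
            accepted = None
            for alpha in (1.0, 0.5, 0.25, 0.125, 0.0625):
                u_t = u + alpha * step[:nb]
                lg_t = ln_ngas + alpha * step[nb] if gas_on else ln_ngas
                ns_t = n_s + alpha * step[nb + ng:]
                F_t, _ = self._fj(active_solids, gas_on, u_t, lg_t, ns_t,
                                  want_jacobian=False)
                if not np.all(np.isfinite(F_t)):
                    continue
                if np.max(np.abs(F_t)) < norm or alpha == 0.0625:
                    accepted = (u_t, lg_t, ns_t)
                    break
            if accepted is None:
                break
            u, ln_ngas, n_s = accepted
            F, J = self._fj(active_solids, gas_on, u, ln_ngas, n_s)
        if best < 1e-10:
            u, ln_ngas, n_s = best_iter
            return u, ln_ngas, dict(zip(active_solids, n_s))
        report = ResidualReport(findings=[f"Newton residual {best:.3e} (scaled)"])
        raise NonConvergenceError(
            f"Newton did not converge (best scaled residual {best:.3e})", report
        )

    # -- state assembly -----------------------------------------------------

    def _assemble(self, u, gas_on, ln_ngas, active_solids, n_solids) -> EquilibriumState:
        db = self.db
        kg = self.kg_w
        P = self.comp.pressure
        m_aq, p_gas = self._secondary(u)
        m_basis = np.exp(u)
        moles: dict[str, float] = {}
        water_used = 0.0
        for j, name in enumerate(self.basis_names):
            if name == "H+" or name in db:
                moles[name] = float(m_basis[j] * kg)
        for i, name in enumerate(self.sec_aq):
            moles[name] = float(m_aq[i] * kg)
            water_used += self.W_aq[i] * m_aq[i] * kg
        gas_pp: dict[str, float] = {}
        if gas_on:
            ngas = math.exp(ln_ngas)
            for i, name in enumerate(self.gases):
                gas_pp[name] = float(p_gas[i])
                n = float(p_gas[i] / P * ngas)
                moles[name] = n
                water_used += self.W_gas[i] * n
        assemblage = set()
        for s in active_solids:
            n = float(max(n_solids[s], 0.0))
            moles[s] = n
            water_used += self.solid_W[s] * n
            if n > 0:
                assemblage.add(s)
        n_water = self.n_water0 - water_used
        moles["H2O"] = n_water
        ph = float(-u[self.basis_names.index("H+")] / LN10)

        si = {
            s: float((self.solid_K[s] + self.solid_C[s] @ u) / LN10)
            for s in self.cand_solids
        }
        # total Gibbs energy (kJ): sum of n_i * (dGf_i + RT ln a_i)
        rt = R_KJ * self.comp.temperature
        total_g = n_water * db.solvent.dGf
        for j, name in enumerate(self.basis_names):
            if name in db:
                total_g += m_basis[j] * kg * (db[name].dGf + rt * u[j])
        for i, name in enumerate(self.sec_aq):
            total_g += m_aq[i] * kg * (db[name].dGf + rt * math.log(m_aq[i]))
        for name, p in gas_pp.items():
            total_g += moles[name] * (db[name].dGf + rt * math.log(p))
        for s in active_solids:
            total_g += moles[s] * db[s].dGf
        basis_act = {n: float(np.exp(u[j])) for j, n in enumerate(self.basis_names)}
        basis_act["H2O"] = 1.0
        if self.h2_mode:
            basis_act["H2(g)"] = self.comp.h2_fugacity
        return EquilibriumState(
            species_moles=moles,
            solid_assemblage=frozenset(assemblage),
            pH=ph,
            gas_partial_pressures=gas_pp,
            total_G=float(total_g),
            composition=self.comp,
            basis_activities=basis_act,
            si_table=si,
            water_kg=kg,
            options=self.opts,
            frozen_species=tuple(sorted(self.frozen)),
        )


def solve_equilibrium(
    comp: SystemComposition,
    db: ThermoDB,
    opts: SolverOptions | None = None,
) -> EquilibriumState:
    """Solve the minimum-Gibbs-energy state under mass balance.

    Law-of-mass-action Newton iteration on log-molalities of a basis set,
    wrapped in an active-set loop that adds the most supersaturated solid
    (largest saturation index, ties broken lexicographically) and removes any
    solid driven negative, until complementarity holds.  A closed headspace at
    fixed total pressure is treated as one more phase of the active set: it
    exists exactly when the equilibrium partial pressures from solution reach
    the total pressure.
    """
    opts = opts or SolverOptions()
    model = _Model(comp, db, opts)
    return model.solve()


def saturation_index(state: EquilibriumState, solid: str, db: ThermoDB) -> float:
    """log10(IAP / Ksp) for a solid's dissolution reaction in a given state.

    The ion-activity product is evaluated over the state's basis activities
    (molality for solutes, unity for water); the solid and water contribute
    activity one.
    """
    rec = db[solid]
    if rec.phase_class != "solid":
        raise UnknownSpeciesError(f"{solid!r} is not a solid phase")
    names = [n for n in state.basis_activities if n != "H2O"]
    cols = []
    for n in names:
        r = db[n]
        v = np.zeros(len(ELEMENTS) + 1)
        for i, el in enumerate(ELEMENTS):
            v[i] = r.formula.get(el, 0)
        v[-1] = r.charge
        cols.append(v)
    wv = np.zeros(len(ELEMENTS) + 1)
    wv[0], wv[1] = 2, 1
    cols.append(wv)
    A = np.column_stack(cols)
    target = np.zeros(len(ELEMENTS) + 1)
    for i, el in enumerate(ELEMENTS):
        target[i] = rec.formula.get(el, 0)
    target[-1] = rec.charge
    c, *_ = np.linalg.lstsq(A, target, rcond=None)
    if np.linalg.norm(A @ c - target) > 1e-8:
        raise UnknownSpeciesError(
            f"{solid!r} not representable over the state's basis activities"
        )
    dg = rec.dGf - sum(c[j] * db[n].dGf for j, n in enumerate(names))
    dg -= c[-1] * db.solvent.dGf
    logk_form = -dg / LN10RT
    log_iap_over_k = logk_form + sum(
        c[j] * math.log10(state.basis_activities[n]) for j, n in enumerate(names)
    )
    return log_iap_over_k


def ammonia_redox_equilibrium(pN2: float, pH2: float, db: ThermoDB) -> float:
    """Equilibrium NH3 partial pressure over 1/2 N2 + 3/2 H2 = NH3 (bar).

    Ammonia formation is controlled by the hydrogen fugacity; under ideal-gas
    behaviour pNH3 = K * pN2^(1/2) * pH2^(3/2), monotone in both arguments.
    """
    if pN2 < 0 or pH2 < 0:
        raise ValueError("partial pressures must be non-negative")
    rxn = Reaction({"N2(g)": -0.5, "H2(g)": -1.5, "NH3(g)": 1.0})
    k = 10.0 ** reaction_logK(db, rxn)
    return k * pN2 ** 0.5 * pH2 ** 1.5


def verify_state(
    state: EquilibriumState,
    comp: SystemComposition,
    db: ThermoDB,
    opts: SolverOptions | None = None,
) -> ResidualReport:
    """Independent residual audit of a state against a composition.

    Reports element-balance residuals (relative), the aqueous charge residual
    (mol per kg water), per-species mass-action residuals (log10 units against
    the basis activities), and per-solid complementarity violations.  The
    report is empty iff everything is within the solver tolerances.
    """
    opts = opts or state.options
    report = ResidualReport()
    kg = state.water_kg
    # element balances from the full species inventory
    totals = {el: 0.0 for el in ELEMENTS}
    charge = 0.0
    for name, n in state.species_moles.items():
        rec = db[name] if name in db else None
        if rec is None:
            report.findings.append(f"{name}: unknown species in state")
            continue
        for el, cnt in rec.formula.items():
            totals[el] += cnt * n
        if rec.phase_class == "aqueous":
            charge += rec.charge * n
    h2_corr = 0.0
    if comp.h2_fugacity is not None:
        # imposed-fugacity hydrogen acts as an open reservoir; reconcile H
        h_in = comp.element_totals.get("H", 0.0)
        h2_corr = (totals["H"] - h_in) / 2.0
    for el in ELEMENTS:
        want = comp.element_totals.get(el, 0.0)
        have = totals[el]
        if comp.h2_fugacity is not None and el == "H":
            have -= 2.0 * h2_corr
        denom = max(abs(want), 1e-30)
        rel = (have - want) / denom if want > 0 else abs(have)
        report.element_residuals[el] = rel
        if want > 0 and abs(rel) > opts.balance_tol:
            report.findings.append(f"element {el}: relative residual {rel:.3e}")
        elif want == 0 and abs(have) > opts.balance_tol:
            report.findings.append(f"element {el}: spurious {have:.3e} mol")
    report.charge_residual = charge / kg
    if abs(report.charge_residual) > opts.charge_tol:
        report.findings.append(
            f"aqueous charge residual {report.charge_residual:.3e} mol/kg"
        )
    # mass action: every dissolved/gas species against the basis activities
    basis = {n: a for n, a in state.basis_activities.items() if n != "H2O"}
    names = list(basis)
    cols = []
    for n in names:
        r = db[n]
        v = np.zeros(len(ELEMENTS) + 1)
        for i, el in enumerate(ELEMENTS):
            v[i] = r.formula.get(el, 0)
        v[-1] = r.charge
        cols.append(v)
    wv = np.zeros(len(ELEMENTS) + 1)
    wv[0], wv[1] = 2, 1
    cols.append(wv)
    A = np.column_stack(cols)
    for name, n_mol in state.species_moles.items():
        if name == "H2O" or name not in db:
            continue
        rec = db[name]
        if rec.phase_class == "solid":
            continue
        if name in basis:
            continue
        act = (
            state.gas_partial_pressures.get(name)
            if rec.phase_class == "gas"
            else n_mol / kg
        )
        if act is None or act <= 0:
            continue
        target = np.zeros(len(ELEMENTS) + 1)
        for i, el in enumerate(ELEMENTS):
            target[i] = rec.formula.get(el, 0)
        target[-1] = rec.charge
        c, *_ = np.linalg.lstsq(A, target, rcond=None)
        if np.linalg.norm(A @ c - target) > 1e-8:
            continue
        dg = rec.dGf - sum(c[j] * db[n].dGf for j, n in enumerate(names))
        dg -= c[-1] * db.solvent.dGf
        predicted = -dg / LN10RT + sum(
            c[j] * math.log10(basis[n]) for j, n in enumerate(names)
        )
        resid = math.log10(act) - predicted
        report.mass_action_residuals[name] = resid
        if abs(resid) > opts.si_tol:
            report.findings.append(f"{name}: mass-action residual {resid:.3e} log10")
    # complementarity
    for rec in db.species("solid"):
        name = rec.name
        try:
            si = saturation_index(state, name, db)
        except UnknownSpeciesError:
            continue
        present = name in state.solid_assemblage
        if present and abs(si) > opts.si_tol:
            report.complementarity_violations[name] = si
            report.findings.append(f"{name}: present but SI = {si:.3e}")
        elif not present and si > opts.si_tol and name not in state.frozen_species:
            report.complementarity_violations[name] = si
            report.findings.append(f"{name}: absent but supersaturated (SI = {si:.3e})")
    return report
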