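"""Thermodynamic database: species records, validation, and equilibrium constants.

The database is a flat table of chemical species — solvent water, aqueous
solutes, gases, and candidate solid phases — each carrying an elemental
formula, a charge, a phase class, and a standard Gibbs energy of formation
at 298.15 K and 1 bar.  Equilibrium constants for any balanced reaction
follow from logK = -dG_rxn / (RT ln 10); the shipped fixture is assembled so
that the standard 25 C anchor constants (pKw, the phosphoric acid ladder,
the ammonium and sulfide pKa values, the struvite and apatite solubility
products) are reproduced exactly from the tabulated dGf values.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ELEMENTS",
    "R_KJ",
    "T_REF",
    "P_REF",
    "LN10RT",
    "PHASE_CLASSES",
    "SpeciesRecord",
    "ThermoDB",
    "Reaction",
    "ThermoDBError",
    "DuplicateSpeciesError",
    "UnknownElementError",
    "BadRecordError",
    "MissingSolventError",
    "UnknownSpeciesError",
    "UnbalancedReactionError",
    "load_thermodb",
    "default_db",
    "validate_db",
    "reaction_logK",
    "REQUIRED_SPECIES",
]

#: Elements the model tracks, in canonical order.
ELEMENTS: tuple[str, ...] = ("H", "O", "Na", "Cl", "Mg", "Ca", "N", "S", "P")

R_KJ = 8.314462618e-3  # gas constant, kJ/mol/K
T_REF = 298.15  # K
P_REF = 1.0  # bar
LN10RT = R_KJ * T_REF * math.log(10.0)  # kJ/mol per log10 unit

PHASE_CLASSES = ("aqueous", "gas", "solid", "solvent")


class ThermoDBError(Exception):
    """Base class for database errors."""


class DuplicateSpeciesError(ThermoDBError):
    """Two records share a name (or an identical formula/charge/phase triple)."""


class UnknownElementError(ThermoDBError):
    """A formula uses an element outside the supported set."""


class BadRecordError(ThermoDBError):
    """A row is structurally invalid (missing or non-numeric dGf, bad charge...)."""


class MissingSolventError(ThermoDBError):
    """No solvent (liquid water) row present."""


class UnknownSpeciesError(ThermoDBError):
    """A reaction references a species absent from the database."""


class UnbalancedReactionError(ThermoDBError):
    """A reaction fails element or charge balance."""


_FORMULA_TOKEN = re.compile(r"^([A-Z][a-z]?)(\d+)$")


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``"Mg1 N1 H16 P1 O10"`` into an element -> count mapping."""
    formula: dict[str, int] = {}
    tokens = text.split()
    if not tokens:
        raise BadRecordError("empty formula")
    for tok in tokens:
        m = _FORMULA_TOKEN.match(tok)
        if m is None:
            raise BadRecordError(f"malformed formula token {tok!r}")
        el, count = m.group(1), int(m.group(2))
        if el not in ELEMENTS:
            raise UnknownElementError(f"unknown element {el!r} in formula {text!r}")
        if count < 0:
            raise BadRecordError(f"negative count in formula token {tok!r}")
        formula[el] = formula.get(el, 0) + count
    return formula


def format_formula(formula: Mapping[str, int]) -> str:
    return " ".join(f"{el}{formula[el]}" for el in ELEMENTS if formula.get(el))


@dataclass(frozen=True)
class SpeciesRecord:
    """One chemical species and its standard-state thermodynamic identity."""

    name: str
    formula: Mapping[str, int]
    charge: int
    phase_class: str
    dGf: float  # kJ/mol at 298.15 K
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase_class not in PHASE_CLASSES:
            raise BadRecordError(
                f"{self.name}: phase_class {self.phase_class!r} not one of {PHASE_CLASSES}"
            )
        if not self.formula:
            raise BadRecordError(f"{self.name}: empty formula")
        for el in self.formula:
            if el not in ELEMENTS:
                raise UnknownElementError(f"{self.name}: unknown element {el!r}")
        if not isinstance(self.dGf, (int, float)) or math.isnan(self.dGf):
            raise BadRecordError(f"{self.name}: missing or non-numeric dGf")

    def element_vector(self) -> dict[str, int]:
        return {el: self.formula.get(el, 0) for el in ELEMENTS}


@dataclass
class ThermoDB:
    """Collection of species records keyed by name, at fixed (T, P) reference."""

    records: dict[str, SpeciesRecord]
    version: str = "unversioned"
    element_list: tuple[str, ...] = ELEMENTS
    reference_temperature: float = T_REF
    reference_pressure: float = P_REF

    def __getitem__(self, name: str) -> SpeciesRecord:
        try:
            return self.records[name]
        except KeyError:
            raise UnknownSpeciesError(f"species {name!r} not in database") from None

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self):
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def species(self, phase_class: str | None = None) -> list[SpeciesRecord]:
        if phase_class is None:
            return list(self.records.values())
        return [r for r in self.records.values() if r.phase_class == phase_class]

    @property
    def solvent(self) -> SpeciesRecord:
        for rec in self.records.values():
            if rec.phase_class == "solvent":
                return rec
        raise MissingSolventError("database has no solvent species")


@dataclass(frozen=True)
class Reaction:
    """A chemical reaction as a species-name -> signed coefficient map.

    Products carry positive coefficients, reactants negative.  Coefficients
    may be rational (e.g. 1/2 N2 in ammonia synthesis).
    """

    stoichiometry: Mapping[str, Fraction | float]

    def reversed(self) -> "Reaction":
        return Reaction({k: -v for k, v in self.stoichiometry.items()})

    def __add__(self, other: "Reaction") -> "Reaction":
        stoich = dict(self.stoichiometry)
        for name, coeff in other.stoichiometry.items():
            stoich[name] = stoich.get(name, 0) + coeff
        return Reaction({k: v for k, v in stoich.items() if v != 0})


def balance_residual(db: ThermoDB, rxn: Reaction) -> dict[str, float]:
    """Element and charge imbalance of a reaction (all-zero iff balanced)."""
    resid = {el: 0.0 for el in ELEMENTS}
    resid["charge"] = 0.0
    for name, coeff in rxn.stoichiometry.items():
        rec = db[name]
        for el, count in rec.formula.items():
            resid[el] += float(coeff) * count
        resid["charge"] += float(coeff) * rec.charge
    return resid


def check_balanced(db: ThermoDB, rxn: Reaction, tol: float = 1e-10) -> None:
    resid = balance_residual(db, rxn)
    bad = {k: v for k, v in resid.items() if abs(v) > tol}
    if bad:
        raise UnbalancedReactionError(f"reaction unbalanced: residuals {bad}")


def reaction_logK(db: ThermoDB, rxn: Reaction) -> float:
    """log10 equilibrium constant of a balanced reaction at 298.15 K.

    Computed as -dG_rxn / (RT ln 10) with dG_rxn the signed sum of member
    dGf values.  Reversing a reaction negates logK; adding two reactions
    adds their logK values.
    """
    check_balanced(db, rxn)
    dg = sum(float(c) * db[name].dGf for name, c in rxn.stoichiometry.items())
    return -dg / LN10RT


# Minimum species inventory every valid database must contain.
REQUIRED_SPECIES: tuple[str, ...] = (
    "H2O", "H+", "OH-",
    "H3PO4", "H2PO4-", "HPO4-2", "PO4-3",
    "NH3", "NH4+", "H2S", "HS-",
    "Mg+2", "Ca+2", "Na+", "Cl-",
    "N2(g)", "H2(g)", "NH3(g)", "H2O(g)",
    # the thirteen phosphate-bearing solids
    "CaHPO3", "CaHPO4", "Ca(H2PO4)2", "CaHPO4:2H2O", "Ca(H2PO4)2:H2O",
    "Ca2P2O7", "Ca3(PO4)2", "Ca5(PO4)3OH", "MgNH4PO4:6H2O",
    "Mg2P2O7", "Mg3(PO4)2", "NaH2PO4(s)", "Na2HPO4(s)",
    # the five oxides
    "CaO", "Ca(OH)2", "CaMgO2", "MgO", "Mg(OH)2",
)


def load_thermodb(path: str | Path) -> ThermoDB:
    """Load a TSV thermodynamic database.

    Columns: name / formula / charge / phase_class / dGf_kJ_per_mol / source.
    Lines starting with ``#`` are comments; a leading comment of the form
    ``# <anything> version <v>`` sets the database version string.  Loading is
    order-independent and enforces the structural invariants (unique names,
    unique formula/charge/phase triples, exactly one solvent).
    """
    path = Path(path)
    records: dict[str, SpeciesRecord] = {}
    triples: dict[tuple, str] = {}
    version = "unversioned"
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                m = re.search(r"version\s+(\S+)", line)
                if m and version == "unversioned":
                    version = m.group(1)
                continue
            cols = line.split("\t")
            if header is None:
                header = [c.strip() for c in cols]
                expected = ["name", "formula", "charge", "phase_class",
                            "dGf_kJ_per_mol", "source"]
                if header[: len(expected)] != expected:
                    raise BadRecordError(
                        f"{path}:{lineno}: unexpected header {header!r}"
                    )
                continue
            if len(cols) < 5:
                raise BadRecordError(f"{path}:{lineno}: expected >=5 columns")
            name = cols[0].strip()
            if name in records:
                raise DuplicateSpeciesError(f"{path}:{lineno}: duplicate species {name!r}")
            formula = parse_formula(cols[1].strip())
            try:
                charge = int(cols[2])
            except ValueError:
                raise BadRecordError(f"{path}:{lineno}: non-integer charge {cols[2]!r}")
            phase_class = cols[3].strip()
            try:
                dgf = float(cols[4])
            except ValueError:
                raise BadRecordError(
                    f"{path}:{lineno}: missing or non-numeric dGf {cols[4]!r}"
                )
            source = cols[5].strip() if len(cols) > 5 else ""
            rec = SpeciesRecord(name, formula, charge, phase_class, dgf, source)
            triple = (format_formula(formula), charge, phase_class)
            if triple in triples:
                raise DuplicateSpeciesError(
                    f"{path}:{lineno}: {name!r} duplicates {triples[triple]!r} "
                    f"(same formula, charge and phase class)"
                )
            triples[triple] = name
            records[name] = rec
    solvents = [r for r in records.values() if r.phase_class == "solvent"]
    if not solvents:
        raise MissingSolventError(f"{path}: no solvent row (liquid water) present")
    if len(solvents) > 1:
        raise BadRecordError(f"{path}: more than one solvent row present")
    return ThermoDB(records=records, version=version)


def default_db() -> ThermoDB:
    """The fixture database shipped with the package."""
    with resources.as_file(
        resources.files("protocean.data").joinpath("thermodb.tsv")
    ) as p:
        return load_thermodb(p)


def validate_db(db: ThermoDB, required: Iterable[str] = REQUIRED_SPECIES) -> list[str]:
    """Validation report: empty iff all invariants hold and the required
    species inventory is present.  Findings name the species and rule."""
    findings: list[str] = []
    solvents = [r for r in db if r.phase_class == "solvent"]
    if len(solvents) == 0:
        findings.append("no solvent species present")
    elif len(solvents) > 1:
        findings.append(
            "more than one solvent species: " + ", ".join(r.name for r in solvents)
        )
    triples: dict[tuple, str] = {}
    for rec in db:
        if rec.phase_class in ("gas", "solid", "solvent") and rec.charge != 0:
            findings.append(
                f"{rec.name}: charge inconsistent with phase class "
                f"({rec.phase_class} species must be neutral)"
            )
        if rec.phase_class == "aqueous":
            # formula convention: charge implied by proton count relative to
            # the neutral parent is not checkable in general, but an ion whose
            # name encodes a charge must carry it.
            m = re.search(r"([+-])(\d*)$", rec.name)
            if m:
                implied = int(m.group(2) or "1") * (1 if m.group(1) == "+" else -1)
                if implied != rec.charge:
                    findings.append(
                        f"{rec.name}: charge inconsistent with formula convention "
                        f"(name implies {implied:+d}, record has {rec.charge:+d})"
                    )
        triple = (format_formula(rec.formula), rec.charge, rec.phase_class)
        if triple in triples:
            findings.append(
                f"{rec.name}: duplicates {triples[triple]} "
                "(same formula, charge and phase class)"
            )
        triples[triple] = rec.name
    for name in required:
        if name not in db:
            findings.append(f"{name}: required species absent")
    return findings
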