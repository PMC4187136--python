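import pytest

from protocean.thermodb import default_db
from protocean.scenario import default_early_ocean


@pytest.fixture(scope="session")
def db():
    return default_db()


@pytest.fixture()
def ocean():
    return default_early_ocean()


@pytest.fixture(scope="session")
def reduced_opts(db):
    """Solver options restricting the active set to the oracle's species."""
    from protocean.speciation import SolverOptions

    allowed = {"H+", "OH-", "Mg+2", "NH4+", "PO4-3", "HPO4-2", "MgNH4PO4:6H2O"}
    excluded = frozenset(
        r.name for r in db
        if r.phase_class != "solvent" and r.name not in allowed
    )
    return SolverOptions(exclude_species=excluded)


def reduced_composition(mg=0.002, n=0.01, p=0.005):
    """Neutral-compound inventory for the reduced struvite system (1 kg water):
    Mg(OH)2 + NH4OH + H3PO4 in water."""
    from protocean.speciation import SystemComposition, WATER_MOLES_PER_KG

    totals = {
        "H": 2 * WATER_MOLES_PER_KG + 2 * mg + 5 * n + 3 * p,
        "O": WATER_MOLES_PER_KG + 2 * mg + n + 4 * p,
        "Mg": mg,
        "N": n,
        "P": p,
    }
    return SystemComposition(element_totals=totals, nitrogen_as_ammonium=n)
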