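# protocean

Equilibrium speciation and phosphate-mineral phase maps for a model early
ocean.

Struvite (MgNH₄PO₄·6H₂O) is an unusually reactive phosphate mineral and a
candidate phosphorylating agent for prebiotic chemistry — but only if an
early ocean could actually precipitate it against the thermodynamically
favoured calcium phosphates (apatite above all) and, at high phosphate
loads, magnesium phosphate (farringtonite).  `protocean` answers that
question with a chemical-equilibrium model: a closed sea-water mass plus
nitrogen headspace at 298.15 K and 1 bar, solved to its minimum-Gibbs-energy
species distribution under elemental mass balance, and swept over the
controls the outcome turns on — the Mg/Ca molar ratio, the ammonium and
total-phosphate loadings, and the hydrogen fugacity that sets how much of an
N₂ inventory is reduced to ammonia.  The package is aimed at geochemists and
origins-of-life researchers who want those stability windows as reproducible
numbers rather than as figure panels.

## The model

Equilibrium is formulated in the standard geochemical-speciation way.  With
ideal activities (molality *mᵢ* for solutes, partial pressure in bar for
gases, unity for solids and solvent), a state is an equilibrium when

* every independent reaction obeys mass action,
  Σᵢ νᵢ log *aᵢ* = log *K* with log *K* = −Δ*G*°ᵣ / (*RT* ln 10),
* every element total is conserved and the solution is charge-neutral,
* every candidate solid satisfies complementarity: present with saturation
  index SI = log₁₀(IAP/*K*ₛₚ) = 0, or absent with SI ≤ 0.

The solver is a Newton iteration on log-molalities of a basis set, wrapped
in an active-set loop over solids (and the headspace, which exists exactly
when the equilibrium partial pressures reach 1 bar).  For struvite the
governing reaction is

    Mg²⁺ + NH₄⁺ + PO₄³⁻ + 6 H₂O  =  MgNH₄PO₄·6H₂O,   pKsp = 13.26

against, chiefly, hydroxyapatite Ca₅(PO₄)₃OH and farringtonite Mg₃(PO₄)₂.
Ammonia formation from the headspace is controlled by the hydrogen fugacity
through ½ N₂ + 3⁄2 H₂ = NH₃.  The shipped thermodynamic database
(`src/protocean/data/thermodb.tsv`) is a pinned, self-consistent set of
298.15 K Gibbs energies of formation with per-row provenance; the classic
anchor constants (pK_w = 14.00, the phosphoric-acid ladder 2.15 / 7.21 /
12.34, ammonium 9.25, H₂S 6.99, the struvite and apatite solubility
products) are reproduced exactly from it.  See `docs/methods.md` for the
model's assumptions, parameters, and limitations.

## Worked example

```python
from dataclasses import replace
import protocean as po

db = po.default_db()
ocean = po.default_early_ocean()   # 1 kg water, seawater Na/Mg/Ca, N2 headspace,
                                   # 1e-5 mol/kg phosphate, sulfide pH buffer

# Modern Mg/Ca ratio (~5.1), every bit of nitrogen converted to ammonia:
state = po.solve_equilibrium(po.build_composition(replace(ocean, ammonia_fraction=1.0)), db)
print(f"pH = {state.pH:.2f}")                                  # pH = 7.87
print(po.classify_assemblage(state))                           # Ca5(PO4)3OH
print(f"SI(struvite) = {state.si_table['MgNH4PO4:6H2O']:.2f}") # SI(struvite) = -4.23

# Remove the calcium obstacle (Mg/Ca = 10,000) and add 0.2 mol/kg ammonium:
early = replace(ocean, mg_ca_ratio_override=10_000, ammonium_molality=0.2)
state = po.solve_equilibrium(po.build_composition(early), db)
print(po.classify_assemblage(state))                           # MgNH4PO4:6H2O
print(f"{state.species_moles['MgNH4PO4:6H2O']:.2e} mol")       # 9.79e-06 mol

# How much ammonium does struvite need at that ratio?
tmpl = replace(ocean, mg_ca_ratio_override=10_000, total_phosphate=1e-5)
thr = po.find_threshold(tmpl, "ammonium_molality", "struvite-present", (1e-4, 10), db)
print(f"threshold = {thr.value:.4f} mol/kg")                   # threshold = 0.0568 mol/kg
```

Reading: at the present-day Mg/Ca ratio apatite takes all the phosphate and
struvite stays four orders of magnitude undersaturated no matter how much
ammonia is supplied.  Struvite becomes the sole phosphate mineral only when
dissolved calcium is almost absent *and* ammonium reaches several
hundredths molal — far beyond the ~10⁻³ mol/kg usually estimated for an
early ocean.

A command-line surface wraps the same operations
(`protocean validate-db | solve | build-scenario | sweep | threshold`),
each writing JSON/CSV artifacts plus a manifest that reproduces the run.

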