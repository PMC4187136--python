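# Methods

## Model

`protocean` computes the chemical equilibrium of a closed water + headspace
system at 298.15 K and 1 bar total pressure: a mass of liquid water with
dissolved Na/Mg/Ca chlorides, phosphate and sulfide salts, a reduced-nitrogen
pool, and an N₂ headspace.  The state variables are the molalities of the
aqueous species, the headspace partial pressures, and the moles of any pure
solid phases.  A state is accepted as equilibrium when it satisfies,
simultaneously,

1. **mass action** for every independent reaction expressible in the active
   species set, with log K = −ΔG°ᵣ/(RT ln 10) computed from the tabulated
   Gibbs energies of formation;
2. **mass balance** for every element, plus aqueous charge neutrality;
3. **complementarity** for every candidate solid: in the assemblage with
   saturation index 0, or absent with SI ≤ 0 (and the analogous condition
   for the existence of the gas phase at 1 bar).

This is the Karush–Kuhn–Tucker characterisation of the minimum of total
Gibbs energy under elemental constraints; the package solves the
mass-action form because it is far better conditioned when trace elements
(10⁻⁵ molal phosphate) sit in a concentrated brine.

### Assumptions

* **Ideal activities.**  Activity = molality for solutes, partial pressure
  (bar) for gases, 1 for solids and solvent.  No Debye–Hückel/Davies
  correction is applied — deliberate, because the sulfide pH buffer drives
  the ionic strength far beyond any such model's validity, and the
  quantities of interest are order-of-magnitude stability windows.
* **Fixed 298.15 K, 1 bar.**  The database carries only ΔG°f at the
  reference state; no heat capacities, so no temperature sweeps.
* **Equilibrium only.**  No kinetics, no metastability: a supersaturated
  solid always precipitates.  Real systems can transiently hold struvite
  where this model says apatite; the model gives the long-time attractor.
* **Frozen redox, by construction.**  Sulfur is locked to −2 (H₂S/HS⁻),
  phosphorus to +5 (reduced-P species are loadable but inactive unless
  `allow_reduced_p` is set), and nitrogen follows one of two modes:
  *fixed-speciation* (the reduced pool NH₃+NH₄⁺ is an input, N₂ is inert —
  used for the ammonia-fraction and explicit-ammonium scans) or
  *H₂-coupled* (an imposed hydrogen fugacity equilibrates the whole N
  inventory through ½N₂ + 3⁄2H₂ ⇌ NH₃).  Mechanically the freezes fall out
  of the basis construction: a species whose formula/charge vector is not
  representable over the active basis (plus solvent, plus any
  imposed-fugacity species) cannot acquire mass, so O₂, monatomic H, or
  HNO₃ are structurally absent rather than special-cased.

## Thermodynamic database

The shipped TSV (`src/protocean/data/thermodb.tsv`, version 1.0) holds 49
species: solvent water, 23 aqueous solutes, 7 gases, and 18 solids,
covering the full inventory the model may form.  Assembly policy, fixed
once before any threshold was computed:

* **Aqueous species** take NBS/CODATA 25 °C compilation values
  (ΔG°f(H⁺) = 0 convention).  OH⁻ is adjusted by < 0.01 kJ/mol — within its
  stated uncertainty — so that pK_w = 14.000 exactly; the phosphoric-acid
  ladder then lands at 2.148 / 7.206 / 12.342, ammonium at 9.252, H₂S at
  6.992.
* **Solids with direct 25 °C solubility determinations** are anchored to
  those measurements: struvite pKsp 13.26 (Ohlinger et al. 1998), monetite
  6.90 and brushite 6.59, β-Ca₃(PO₄)₂ 28.92, farringtonite 25.20 (Lange's
  Handbook).  Anchoring means the solid's ΔG°f is back-computed from the
  measured Ksp and the aqueous base set, so the constant is reproduced
  exactly.
* **Remaining solids** (hydroxyapatite, the pyrophosphates, the oxides, the
  sodium phosphates) carry NBS calorimetric values — the same compilation
  family that enthalpy-based equilibrium packages draw on.  The NBS
  hydroxyapatite value (−6337.1 kJ/mol) implies pKsp ≈ 62.3.

**Sensitivity.**  Direct apatite solubility studies scatter between pKsp
≈ 50 and 60 (incongruent dissolution makes the measurement hard); a value
of 58.5 instead of 62.3 would shrink every Mg/Ca threshold roughly
five-fold, since the apatite boundary scales as Ksp^(1/5).  Handbook values
for farringtonite span 24.0–25.2, moving the ammonium thresholds by up to
a factor of four.  These two constants dominate the quantitative
uncertainty of every phase boundary this package prints; the provenance
column records exactly which value is pinned.

## Solver numerics

* Basis species (first active candidate per component): H⁺, Na⁺, Cl⁻,
  Mg²⁺, Ca²⁺, H₂PO₄⁻, HS⁻, NH₄⁺, N₂(aq).  Secondary species are formed by
  exact linear decomposition of their formula/charge vectors over the
  basis (coefficients snapped to the nearest half-integer).
* Element totals are projected onto basis components by exact per-component
  elimination — never least squares, which would let the ~111 mol hydrogen
  inventory contaminate a 10⁻⁷ mol calcium total.  The "excess proton"
  component (TOTH) comes from input charge neutrality, water from the
  oxygen inventory, and the hydrogen closure is the feasibility check on
  the inputs.
* Newton iteration on log-molalities with an analytic Jacobian, residuals
  scaled per component by max(|total|, absolute row sum), step cap of 4 ln
  units, backtracking line search (halving, 5 trials) on the residual
  max-norm, convergence at 10⁻¹² (scaled), fallback acceptance of the best
  iterate at 10⁻¹⁰, and up to 3 restarts from perturbed starts (±1 decade).
* Active-set loop: solve; drop any solid driven negative (most negative
  first); nucleate the gas phase when the hypothetical partial-pressure sum
  exceeds 1 bar; otherwise add the most supersaturated solid (ties broken
  by larger SI, then lexicographic name — a deterministic rule so reruns
  are bit-identical); capped at 50 assemblage iterations.
* Tolerances: element balance 10⁻⁹ relative; aqueous charge 10⁻¹² mol/kg;
  SI complementarity 10⁻⁶ log units.
* Degenerate inputs: components with zero totals are removed before
  solving, together with every species that needs them.
* Initialisation: basis molalities from halved component totals at pH 7.
* The reported total Gibbs energy sums nᵢ(ΔG°f,ᵢ + RT ln aᵢ); it omits the
  solvent's colligative (osmotic) term, consistent with the molality-based
  mass-action formulation.  The brute-force test oracle, which minimises G
  directly, includes that term (−RT per solute mole folded into effective
  potentials) — without it, direct minimisation converges to constants
  offset by one RT.

## Scenario generator

The synthetic-data module emulates a model early-ocean water mass:

| parameter | default | rationale |
|---|---|---|
| water | 55.508 mol (1 kg basis) | intensive recipe; the solver's scale-invariance property makes it equal to the 10⁶ kg formulation |
| N₂ | 0.08486 mol/kg | the 85,000 : 5.56 × 10⁷ N₂ : H₂O mole ratio of an atmosphere-sized nitrogen inventory |
| Na⁺ / Mg²⁺ / Ca²⁺ | 0.469 / 0.0528 / 0.0103 mol/kg | standard mean-seawater major cations (Millero recipe), charge-balanced by Cl⁻; Mg/Ca = 5.13 |
| phosphate | 10⁻⁵ mol/kg, added as NaH₂PO₄ : Na₂HPO₄ = 4 : 1 | the diagrams' reference loading; the 4:1 split is a composition recipe only (on its own it would buffer near pH 6.6, not 7.8 — the sulfide buffer, not the phosphate salts, controls pH) |
| sulfide | 7.0 mol/kg, 43.0 % as Na₂S | "excess" H₂S/Na₂S buffer; split centres the solved pH at 7.78 so that the heaviest ammonium loads (10 mol/kg NH₄Cl pulls pH down ~0.17; full NH₃ conversion pushes it up ~0.09) stay inside the 7.6–7.9 band |
| ammonia fraction | 0 | sweep baseline: all nitrogen as N₂ |

Two loading modes for reduced nitrogen: the **fraction sweep** converts a
fraction of the N₂ inventory to NH₃ gas (total N conserved; this is the
0–100 % sweep mode, and it spends buffer capacity, hence the sizing above),
and the **explicit ammonium** field adds NH₄Cl, a neutral salt, so
multi-molar ammonium can be scanned without exhausting any buffer.  The
Mg/Ca override re-partitions the Mg + Ca sum at a fixed total by default
(`fix_mg` mode instead holds Mg and shrinks Ca, for sensitivity checks).
`calibrate_buffer` bisects the Na₂S fraction to a target pH inside the band
and doubles the sulfide total until the maximum NH₃ load shifts pH by less
than 0.1, raising a capacity error if the ladder is exhausted.

The dotted "more ammonium than the atmosphere holds" guide of the phase
diagrams is not a model constraint; the scenario's N inventory makes it
2 × n2_moles ≈ 0.17 mol/kg for the default ocean.

What the generator does *not* emulate: potassium, carbonate, borate and
sulfate chemistry, realistic ionic-strength effects, and any kinetic
pathway.  Tests passing on these scenarios show the solver reproduces the
stated model faithfully — not that the model captures real seawater.

## Phase maps and thresholds

Assemblage labels are the sorted set of phosphate-bearing solids with
positive moles ("none" if empty; oxides reported separately).  "Struvite
present" means > 10⁻¹² mol per kg water, a numerical floor standing in for
the diagrams' presence/absence plotting.  Sweeps solve one equilibrium per
grid cell (failures are flagged, never filled); boundaries are refined by
bisection in log space to a relative bracket width of 10⁻³ (~16 solves, a
few ms each).  The high-fugacity diagram axis is realised as a separate
sweep in H₂-coupled mode sharing the Mg/Ca axis.  Default diagram
resolution is 40 × 40 (≈ 25 s on one CPU); the grids in the test suite are
smaller where only structure is asserted.

## Headline numbers and known limitations

With the pinned database the package computes: struvite first joins apatite
at Mg/Ca ≈ 750 and becomes the sole phosphate mineral at ≈ 950 (phosphate
10⁻⁵ mol/kg, ammonium ample); at Mg/Ca = 10,000 struvite needs ≈ 0.057
mol/kg ammonium; in H₂-coupled mode the ocean enters the struvite field
only above pH₂ ≈ 10⁻⁵ bar.  All of these inherit the solubility-product
sensitivities quoted above.

One structural result deserves flagging: across the high-phosphate regime
(10⁻⁴–10⁻¹ mol/kg) the ammonium floor is *not* monotone.  While magnesium
is plentiful, farringtonite pins dissolved phosphate and holds the struvite
threshold near 0.03–0.06 mol/kg; but above ~0.04 mol/kg total phosphate the
farringtonite precipitate exhausts the fixed-sum Mg inventory
(≈ 0.063 mol/kg), dissolved Mg²⁺ collapses, dissolved phosphate climbs, and
the threshold falls to ~1.4 × 10⁻³ mol/kg at 0.1 mol/kg phosphate.  Whether
that regime is reached depends entirely on how large the Mg reservoir is
taken to be — i.e., on whether an "Mg/Ca = 10,000" ocean is built by
removing Ca or by adding Mg, which the fixed-sum default decides one way.
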