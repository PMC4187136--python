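"""Brute-force total-Gibbs-energy minimisation for a reduced struvite system.

Independent oracle for the mass-action solver: the system is restricted to
water, H+, OH-, Mg+2, NH4+, HPO4-2, PO4-3 and struvite, and the equilibrium
is found by gridding three degrees of freedom (struvite precipitated, HPO4-2
molality, H+ molality), imposing charge balance for OH- and hydrogen closure
for water, then minimising the summed chemical potentials with nested grid
refinement.  No mass-action law is assumed anywhere.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from protocean.thermodb import R_KJ, T_REF, ThermoDB

RT = R_KJ * T_REF

SPECIES = ("H+", "OH-", "Mg+2", "NH4+", "HPO4-2", "PO4-3")


@dataclass
class OracleResult:
    struvite_mol: float
    molalities: dict[str, float]
    pH: float
    total_G: float  # reduced Gibbs energy (constant water term folded out)
    resolution: dict[str, float]  # final grid spacings


def minimize_reduced_system(
    db: ThermoDB,
    mg_total: float,
    n_total: float,
    p_total: float,
    h_total: float,
    passes: int = 6,
    points: int = 25,
) -> OracleResult:
    """Grid-refine the Gibbs minimum of the reduced struvite system (1 kg water).

    Inputs are elemental totals per kg of water built from neutral compounds
    (e.g. Mg(OH)2 + NH4OH + H3PO4 in water), so aqueous charge is zero.
    """
    g_w = db.solvent.dGf
    # Water moles are an affine function of the species vector through the
    # hydrogen closure n_w = (H_t - sum_i H_i n_i)/2, so the water term of the
    # total Gibbs energy can be folded into effective species potentials
    # mu'_i = mu_i - (H_i/2) g_w plus a constant.  Dropping the constant
    # leaves the argmin unchanged and removes the ~1e4 kJ offset that would
    # otherwise swamp the meaningful 1e-10 kJ variations in double precision.
    # The ideal-dilute solvent also contributes its colligative entropy,
    # n_w RT ln x_w ~ -RT * (total solute moles); folding that -RT per solute
    # mole into mu' makes the minimum's stationarity conditions exactly the
    # molality-based mass-action laws.
    h_count = {"H+": 1, "OH-": 1, "Mg+2": 0, "NH4+": 4, "HPO4-2": 1, "PO4-3": 0}
    g = {name: db[name].dGf - 0.5 * h_count[name] * g_w - RT for name in SPECIES}
    g_struv = db["MgNH4PO4:6H2O"].dGf - 8.0 * g_w

    e1_max = max(min(mg_total, n_total, p_total) * 0.999999, 0.0)
    e1_lo, e1_hi = 0.0, e1_max
    lg_hpo4 = (-14.0, math.log10(max(p_total, 1e-30)))
    lg_h = (-13.5, -1.0)
    best = None
    spacing: dict[str, float] = {}
    for _ in range(passes):
        e1 = np.linspace(e1_lo, e1_hi, points)
        f2 = np.logspace(lg_hpo4[0], lg_hpo4[1], points)
        f3 = np.logspace(lg_h[0], lg_h[1], points)
        E1, F2, H = np.meshgrid(e1, f2, f3, indexing="ij")
        mg = mg_total - E1
        nh4 = n_total - E1
        pd = p_total - E1
        hpo4 = np.minimum(F2, pd * 0.999999)
        po4 = pd - hpo4
        oh = 2.0 * mg + nh4 + H - 2.0 * hpo4 - 3.0 * po4
        ok = (oh > 0) & (po4 > 0) & (mg > 0) & (nh4 > 0) & (hpo4 > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            G = E1 * g_struv
            for arr, name in ((H, "H+"), (oh, "OH-"), (mg, "Mg+2"),
                              (nh4, "NH4+"), (hpo4, "HPO4-2"), (po4, "PO4-3")):
                safe = np.where(ok & (arr > 0), arr, 1.0)
                G = G + np.where(ok, arr * (g[name] + RT * np.log(safe)), 0.0)
            # water closure from the hydrogen inventory (feasibility only)
            n_w = (h_total - (H + oh + 4.0 * nh4 + hpo4 + 16.0 * E1)) / 2.0
        G = np.where(ok & (n_w > 0), G, np.inf)
        idx = np.unravel_index(np.argmin(G), G.shape)
        if not np.isfinite(G[idx]):
            raise RuntimeError("oracle grid found no feasible point")
        i, j, k = idx
        best = (float(E1[idx]), float(hpo4[idx]), float(H[idx]), float(G[idx]),
                float(oh[idx]), float(mg[idx]), float(nh4[idx]), float(po4[idx]))
        # refine around the argmin (clamped to the physical bounds)
        de = (e1_hi - e1_lo) / (points - 1)
        e1_lo = max(0.0, e1[i] - 1.5 * de)
        e1_hi = min(e1_max, e1[i] + 1.5 * de)
        if e1_hi <= e1_lo:
            e1_hi = e1_lo + max(e1_max * 1e-12, 1e-18)
        dl2 = (lg_hpo4[1] - lg_hpo4[0]) / (points - 1)
        c2 = math.log10(best[1])
        lg_hpo4 = (c2 - 1.5 * dl2, min(c2 + 1.5 * dl2,
                                       math.log10(max(p_total, 1e-30))))
        dl3 = (lg_h[1] - lg_h[0]) / (points - 1)
        c3 = math.log10(best[2])
        lg_h = (c3 - 1.5 * dl3, c3 + 1.5 * dl3)
        spacing = {
            "struvite_mol": de,
            "log10_hpo4": dl2,
            "log10_h": dl3,
        }
    e1_v, hpo4_v, h_v, g_v, oh_v, mg_v, nh4_v, po4_v = best
    return OracleResult(
        struvite_mol=e1_v,
        molalities={
            "H+": h_v, "OH-": oh_v, "Mg+2": mg_v, "NH4+": nh4_v,
            "HPO4-2": hpo4_v, "PO4-3": po4_v,
        },
        pH=-math.log10(h_v),
        total_G=g_v,
        resolution=spacing,
    )
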