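"""Van 't Hoff thermodynamics of binding.

ln Ka is regressed on 1/T (natural log); the slope gives the binding enthalpy
(dH = -R * slope) and the intercept the entropy (dS = R * intercept).  Gibbs
free energies are computed by two routes that must be reported side by side,
never merged:

    (i)  dG = -R T ln Ka        (direct, per temperature)
    (ii) dG = dH - T dS         (from the Van 't Hoff line)

For a perfect Van 't Hoff line the two coincide; on real tables they may
not, and :func:`thermo_consistency` quantifies and flags the discrepancy.
The sign pattern of (dH, dS) is mapped to the conventional dominant-force
label (Ross-Subramanian convention); the table is data and can be replaced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

R_GAS = 8.314  # J/(mol K)

#: (sign of dH, sign of dS) -> dominant stabilising forces
SIGN_LABELS = {
    (1, -1): "hydrogen bonds and hydrophobic interaction",
    (-1, -1): "van der Waals forces and hydrogen bonds",
    (-1, 1): "electrostatic interactions",
    (1, 1): "hydrophobic interactions",
}

__all__ = [
    "R_GAS",
    "SIGN_LABELS",
    "ThermoParams",
    "vant_hoff_fit",
    "gibbs_from_ka",
    "gibbs_from_hs",
    "thermo_consistency",
    "j_to_kj",
    "kj_to_j",
]


def j_to_kj(x: float) -> float:
    return x / 1000.0


def kj_to_j(x: float) -> float:
    return x * 1000.0


@dataclass(frozen=True)
class ThermoParams:
    """Van 't Hoff parameters with per-temperature Gibbs energies by both routes (J/mol)."""

    dH_J_mol: float
    dS_J_K_mol: float
    se_dH: float
    se_dS: float
    r2: float
    ka_by_T: Mapping[float, float] = field(default_factory=dict)
    dG_from_ka: Mapping[float, float] = field(default_factory=dict)
    dG_from_hs: Mapping[float, float] = field(default_factory=dict)


def gibbs_from_ka(ka_per_M: float, temperature_K: float) -> float:
    """dG = -R T ln Ka, in J/mol."""
    if ka_per_M <= 0:
        raise ValueError("Ka must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (K)")
    return -R_GAS * temperature_K * math.log(ka_per_M)


def gibbs_from_hs(dH_J_mol: float, dS_J_K_mol: float, temperature_K: float) -> float:
    """dG = dH - T dS, in J/mol."""
    return dH_J_mol - temperature_K * dS_J_K_mol


def vant_hoff_fit(ka_by_T: Mapping[float, float]) -> ThermoParams:
    """Fit ln Ka vs 1/T by OLS and derive dH, dS and both dG routes."""
    items = sorted((float(t), float(k)) for t, k in ka_by_T.items())
    temps = np.array([t for t, _ in items])
    kas = np.array([k for _, k in items])
    if np.unique(temps).size < 2:
        raise ValueError("Van 't Hoff fit needs >= 2 distinct temperatures")
    if np.any(kas <= 0):
        raise ValueError("all Ka must be positive")
    x = 1.0 / temps
    y = np.log(kas)
    if np.ptp(y) == 0:
        # flat line: dH = 0, dS = R ln Ka; linregress would degenerate on r
        slope, intercept, se_s, se_i, r2 = 0.0, float(y[0]), 0.0, 0.0, 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        se_s = float(res.stderr) if res.stderr is not None else float("nan")
        se_i = float(res.intercept_stderr) if res.intercept_stderr is not None else float("nan")
        r2 = float(res.rvalue**2)
    dH = -R_GAS * slope
    dS = R_GAS * intercept
    dg_ka = {t: gibbs_from_ka(k, t) for t, k in items}
    dg_hs = {t: gibbs_from_hs(dH, dS, t) for t, _ in items}
    return ThermoParams(
        dH, dS, R_GAS * se_s if not math.isnan(se_s) else float("nan"),
        R_GAS * se_i if not math.isnan(se_i) else float("nan"),
        r2, dict(items), dg_ka, dg_hs,
    )


def interaction_label(dH_J_mol: float, dS_J_K_mol: float,
                      labels: Mapping | None = None) -> str:
    """Dominant-force label from the (dH, dS) sign pattern."""
    table = SIGN_LABELS if labels is None else labels
    key = (1 if dH_J_mol >= 0 else -1, 1 if dS_J_K_mol >= 0 else -1)
    return table[key]


def thermo_consistency(params: ThermoParams, labels: Mapping | None = None) -> dict:
    """Compare the two dG routes per temperature and label the interaction.

    Returns a dict with per-temperature absolute (J/mol) and relative
    discrepancies, per-temperature sign-agreement flags, an overall
    ``consistent`` flag (every |discrepancy| < 1 J/mol) and the dominant-force
    label for the fitted sign pattern.
    """
    rows = {}
    all_ok = True
    for t in params.dG_from_ka:
        a = params.dG_from_ka[t]
        b = params.dG_from_hs.get(t)
        if b is None:
            continue
        abs_d = abs(a - b)
        rel_d = abs_d / max(abs(a), abs(b), 1e-300)
        sign_ok = (a >= 0) == (b >= 0)
        all_ok = all_ok and abs_d < 1.0
        rows[t] = {
            "dG_from_ka_J_mol": a,
            "dG_from_hs_J_mol": b,
            "abs_discrepancy_J_mol": abs_d,
            "rel_discrepancy": rel_d,
            "sign_agreement": sign_ok,
        }
    return {
        "per_temperature": rows,
        "consistent": all_ok,
        "sign_conflict": any(not r["sign_agreement"] for r in rows.values()),
        "interaction_label": interaction_label(params.dH_J_mol, params.dS_J_K_mol, labels),
    }
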