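"""Urea-denaturation analysis.

A chemically denatured lectin is tracked through three observables:

* intrinsic fluorescence — the emission maximum (lambda_max) red-shifts on
  unfolding, while the intensity (Imax) first rises when the oligomer
  dissociates into folded monomers and then falls when those unfold;
* far-UV circular dichroism at 218 nm — sensitive to secondary structure and
  to monomerisation;
* hemagglutinating activity (HA) — the functional readout, reported as the
  reciprocal of the highest two-fold dilution still giving full agglutination.

Replicated per-condition peak metrics are compared by one-way ANOVA with
Tukey's HSD post-test (significance defaults to alpha = 0.1); Shapiro-Wilk
normality checks are reported as diagnostics only.  State verdicts
(native / intermediate_monomer / unfolded) are a pure function of three
boolean flags per condition: significant Imax increase, significant red
shift, and CD218 magnitude increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectra import CDSpectrum, EmissionSpectrum, peak_metrics

__all__ = [
    "DenaturationRecord",
    "ShiftReport",
    "StateAssignment",
    "HAPlate",
    "HAResult",
    "shift_report",
    "cd218",
    "assign_states",
    "ha_titer",
    "ha_activity_profile",
]


@dataclass(frozen=True)
class HAPlate:
    """Ordered wells of a two-fold serial dilution; wells[0] is 1:start_dilution."""

    wells: tuple
    start_dilution: int = 1

    def __post_init__(self):
        if len(self.wells) < 1:
            raise ValueError("a plate needs at least one well")
        if self.start_dilution < 1:
            raise ValueError("start dilution must be >= 1")
        object.__setattr__(self, "wells", tuple(bool(w) for w in self.wells))

    @property
    def dilutions(self) -> tuple:
        return tuple(self.start_dilution * 2**i for i in range(len(self.wells)))


@dataclass(frozen=True)
class HAResult:
    """Titer = reciprocal dilution of the last well in the leading positive run."""

    titer: int
    anomaly: bool = False


@dataclass(frozen=True)
class DenaturationRecord:
    """Replicated emission spectra (plus optional CD and HA) at one urea concentration."""

    urea_M: float
    spectra: tuple
    cd: CDSpectrum | None = None
    ha: HAPlate | None = None

    def __post_init__(self):
        specs = tuple(self.spectra)
        if not specs:
            raise ValueError("at least one replicate spectrum required")
        grid = specs[0].wavelengths
        for s in specs[1:]:
            if not np.array_equal(s.wavelengths, grid):
                raise ValueError("replicates must share one wavelength grid")
        object.__setattr__(self, "spectra", specs)
        object.__setattr__(self, "urea_M", float(self.urea_M))


@dataclass(frozen=True)
class ShiftReport:
    """Per-condition lambda_max / Imax statistics with Tukey-adjusted pairwise tests."""

    conditions: tuple                      # urea concentrations, ascending
    stats: Mapping                         # metric -> {urea: (mean, sd, n)}
    pairwise: Mapping                      # metric -> {(u_lo, u_hi): {diff, p, significant}}
    anova: Mapping                         # metric -> (F, p) or None
    shapiro: Mapping                       # metric -> {urea: p or None}
    alpha: float
    inference_enabled: bool

    def mean(self, metric: str, cond: float) -> float:
        return self.stats[metric][cond][0]

    def _pair(self, metric: str, a: float, b: float):
        key = (min(a, b), max(a, b))
        return self.pairwise[metric][key]

    def significant_increase(self, metric: str, cond: float, ref: float) -> bool:
        """Tukey p <= alpha AND mean(cond) > mean(ref): sign and significance are separate checks."""
        if not self.inference_enabled:
            raise ValueError("inference disabled: need >= 2 replicates per condition")
        pair = self._pair(metric, cond, ref)
        return pair["significant"] and self.mean(metric, cond) > self.mean(metric, ref)


def _tukey_pvalues(groups: list[np.ndarray]) -> np.ndarray:
    """Pairwise Tukey HSD p-value matrix; degenerate (zero within-group
    variance) designs fall back to exact comparison of means."""
    k = len(groups)
    mse = np.mean([np.var(g, ddof=1) for g in groups])
    if mse < 1e-24:
        means = [float(np.mean(g)) for g in groups]
        p = np.ones((k, k))
        for i in range(k):
            for j in range(k):
                if i != j and not math.isclose(means[i], means[j], rel_tol=1e-12, abs_tol=1e-12):
                    p[i, j] = 0.0
        return p
    res = stats.tukey_hsd(*groups)
    return np.asarray(res.pvalue)


def shift_report(
    records: Sequence[DenaturationRecord],
    alpha: float = 0.1,
    method: str = "quadratic",
) -> ShiftReport:
    """Peak metrics per replicate, ANOVA across conditions, Tukey HSD pairwise.

    With a single replicate anywhere the report is descriptive only
    (``inference_enabled=False``); Shapiro-Wilk p-values are diagnostics and
    gate nothing.
    """
    recs = sorted(records, key=lambda r: r.urea_M)
    if len(recs) < 2:
        raise ValueError("need >= 2 conditions")
    conds = tuple(r.urea_M for r in recs)
    values = {"lambda_max": [], "imax": []}
    for r in recs:
        pms = [peak_metrics(s, method) for s in r.spectra]
        values["lambda_max"].append(np.array([p.lambda_max for p in pms]))
        values["imax"].append(np.array([p.i_max for p in pms]))

    inference = all(v.size >= 2 for v in values["lambda_max"])
    stats_out, pair_out, anova_out, shapiro_out = {}, {}, {}, {}
    for metric, groups in values.items():
        stats_out[metric] = {
            c: (float(np.mean(g)), float(np.std(g, ddof=1)) if g.size > 1 else 0.0, int(g.size))
            for c, g in zip(conds, groups)
        }
        shapiro_out[metric] = {}
        for c, g in zip(conds, groups):
            if g.size >= 3 and np.ptp(g) > 0:
                shapiro_out[metric][c] = float(stats.shapiro(g).pvalue)
            else:
                shapiro_out[metric][c] = None
        if inference:
            flat = np.concatenate(groups)
            if np.ptp(flat) == 0:
                anova_out[metric] = (0.0, 1.0)
            elif all(np.var(g, ddof=1) < 1e-24 for g in groups):
                anova_out[metric] = (float("inf"), 0.0)
            else:
                f, p = stats.f_oneway(*groups)
                anova_out[metric] = (float(f), float(p))
            pmat = _tukey_pvalues(list(groups))
            pairs = {}
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    p = float(pmat[i, j])
                    pairs[(conds[i], conds[j])] = {
                        "diff": stats_out[metric][conds[j]][0] - stats_out[metric][conds[i]][0],
                        "p": p,
                        "significant": p <= alpha,
                    }
            pair_out[metric] = pairs
        else:
            anova_out[metric] = None
            pair_out[metric] = {}
    return ShiftReport(conds, stats_out, pair_out, anova_out, shapiro_out, alpha, inference)


def cd218(cd: CDSpectrum, as_mre: bool = False) -> float:
    """CD signal at 218 nm by linear interpolation.

    With ``as_mre=True`` the raw ellipticity (mdeg) is converted to mean
    residue ellipticity, theta / (10 * path_cm * conc_M * n_residues);
    requires the concentration metadata.
    """
    wl = cd.wavelengths
    if 218.0 < wl[0] or 218.0 > wl[-1]:
        raise ValueError("218 nm outside the scanned CD range")
    val = float(np.interp(218.0, wl, cd.signal))
    if not as_mre:
        return val
    if cd.protein_conc_M is None or cd.path_cm is None or cd.n_residues is None:
        raise ValueError("mean residue ellipticity needs conc, path and residue count")
    return val / (10.0 * cd.path_cm * cd.protein_conc_M * cd.n_residues)


@dataclass(frozen=True)
class StateAssignment:
    verdicts: Mapping            # urea -> native | intermediate_monomer | unfolded
    evidence: Mapping            # urea -> str
    fluorescence_only: bool = False


def _verdict_from_flags(imax_up: bool, red_shift: bool, cd_up: bool,
                        declined_vs_intermediate: bool = False) -> str:
    """Pure rule table over the per-condition flags (total: every combination
    yields a verdict).

    intermediate: intensity rose significantly and either the peak did not
    shift or CD218 corroborates monomerisation.  unfolded: a significant red
    shift together with an intensity decline relative to an already
    identified intermediate (or with no intensity gain at all).  A red shift
    with a still-rising intensity and no decline is the intermediate
    persisting, not unfolding.  Otherwise native-like.
    """
    if imax_up and (not red_shift or cd_up):
        return "intermediate_monomer"
    if red_shift and (declined_vs_intermediate or not imax_up):
        return "unfolded"
    if red_shift and imax_up:
        return "intermediate_monomer"
    return "native"


def assign_states(
    shift: ShiftReport,
    cd218_by_condition: Mapping[float, float] | None = None,
    reference_condition: float = 0.0,
) -> StateAssignment:
    """Assign native / intermediate_monomer / unfolded per condition.

    CD218 "increase" means larger magnitude than the reference condition.
    Without CD data the fluorescence-only rule path is used and flagged.
    """
    if reference_condition not in shift.conditions:
        raise ValueError(f"reference condition {reference_condition} M not present")
    if not shift.inference_enabled:
        raise ValueError("state assignment needs replicate statistics")
    cd_map = dict(cd218_by_condition or {})
    fluor_only = not cd_map
    verdicts, evidence = {}, {}
    intermediates: list[float] = []
    for c in shift.conditions:  # ascending urea
        if c == reference_condition:
            verdicts[c] = "native"
            evidence[c] = "reference condition"
            continue
        imax_up = shift.significant_increase("imax", c, reference_condition)
        red = shift.significant_increase("lambda_max", c, reference_condition)
        if fluor_only or c not in cd_map or reference_condition not in cd_map:
            cd_up = False
        else:
            cd_up = abs(cd_map[c]) > abs(cd_map[reference_condition]) + 1e-12
        # significant Imax decline relative to an already identified intermediate
        declined = any(
            shift.significant_increase("imax", j, c) for j in intermediates
        )
        verdicts[c] = _verdict_from_flags(imax_up, red, cd_up, declined)
        if verdicts[c] == "intermediate_monomer":
            intermediates.append(c)
        evidence[c] = (
            f"Imax sig. increase={imax_up}, red shift sig.={red}, "
            f"CD218 magnitude increase={cd_up}, "
            f"declined vs intermediate={declined}"
            f"{' (no CD data)' if fluor_only else ''}"
        )
    return StateAssignment(verdicts, evidence, fluorescence_only=fluor_only)


def ha_titer(plate: HAPlate) -> HAResult:
    """Titer of the leading contiguous positive run; 0 if the first well is negative.

    Positives appearing after a negative well are physically implausible for
    a dilution series and raise the ``anomaly`` flag (the leading-run titer
    is still reported).
    """
    run = 0
    for w in plate.wells:
        if w:
            run += 1
        else:
            break
    anomaly = any(plate.wells[run:])
    titer = plate.dilutions[run - 1] if run else 0
    return HAResult(int(titer), anomaly)


def ha_activity_profile(results_by_urea: Mapping[float, HAResult | int]) -> dict:
    """Classify HA loss per urea level against the 0 M reference.

    ``partial``: 0 < titer < reference; ``none``: titer equals the reference;
    ``full``: no agglutination at all.  A titer above the reference is
    impossible under the model and flagged as an anomaly.
    """
    titers = {
        float(u): (r.titer if isinstance(r, HAResult) else int(r))
        for u, r in results_by_urea.items()
    }
    if len(titers) < 2 or 0.0 not in titers:
        raise ValueError("need >= 2 urea levels including the 0 M reference")
    ref = titers[0.0]
    out = {}
    for u in sorted(titers):
        t = titers[u]
        if u == 0.0:
            label = "reference"
        elif t == 0:
            label = "full"
        elif t == ref:
            label = "none"
        elif t < ref:
            label = "partial"
        else:
            label = "anomaly"
        out[u] = {"titer": t, "loss": label}
    return out
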