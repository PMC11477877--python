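"""Quenching analysis: Stern-Volmer constants, mechanism classification,
modified Stern-Volmer binding constants and Hill cooperativity.

The classical Stern-Volmer relation F0/F = 1 + Ksv[Q] is fitted by ordinary
least squares with a free intercept (its deviation from 1 is a diagnostic).
The binding constant Ka and site number n come from the modified double-log
form log10((F0-F)/F) = log10(Ka) + n log10[Q].  Cooperativity is quantified
by a Hill isotherm fitted to the fractional quench,

    y = Bmax [Q]^h / (Kd^h + [Q]^h),

where Kd = 1/Ka and h is the Hill coefficient (h ~ 2 for an all-or-none
two-site, i.e. dimer-mediated, binding event).  Mechanism (static vs dynamic
quenching) is decided from the temperature trend of Ksv: ground-state complex
formation weakens on heating (Ksv falls), collisional quenching strengthens
(Ksv rises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .spectra import TitrationSeries, band_integral, peak_metrics

__all__ = [
    "QuenchPoint",
    "KsvEstimate",
    "BindingFit",
    "HillFit",
    "MechanismCall",
    "quench_points",
    "stern_volmer_fit",
    "classify_mechanism",
    "modified_sv_fit",
    "hill_fit",
]


@dataclass(frozen=True)
class QuenchPoint:
    """One titration step reduced to quenching statistics.

    ``logterm`` (log10((F0-F)/F)) is None when F >= F0 — those points carry
    no binding signal and are excluded from the double-log fit.
    """

    q_M: float
    ratio: float            # F0/F
    frac: float             # (F0-F)/F0
    logq: float             # log10 [Q]
    logterm: float | None   # log10((F0-F)/F), None if F >= F0

    @property
    def usable(self) -> bool:
        return self.logterm is not None


@dataclass(frozen=True)
class KsvEstimate:
    ksv_per_M: float
    intercept: float
    se_slope: float
    r2: float
    temperature_K: float | None
    n_points: int


@dataclass(frozen=True)
class BindingFit:
    ka_per_M: float
    n_sites: float
    se_log_ka: float
    se_n: float
    r2: float
    temperature_K: float | None
    n_points: int


@dataclass(frozen=True)
class HillFit:
    bmax: float
    kd_M: float
    h: float
    se_bmax: float
    se_kd: float
    se_h: float
    ssr: float
    converged: bool


@dataclass(frozen=True)
class MechanismCall:
    verdict: str                 # static | dynamic | ambiguous
    slope_ksv_vs_T: float
    se_slope: float
    z_score: float
    estimates: tuple             # per-temperature KsvEstimates, sorted by T


def _f_value(spectrum, f_mode: str) -> float:
    if f_mode == "peak":
        return peak_metrics(spectrum, "quadratic").i_max
    if f_mode == "integral":
        return band_integral(spectrum)
    raise ValueError(f"unknown f_mode {f_mode!r}")


def quench_points(series: TitrationSeries, f_mode: str = "peak") -> list[QuenchPoint]:
    """Reduce a titration series to (ratio, frac, double-log) statistics.

    ``f_mode='peak'`` uses the refined peak intensity as F; ``'integral'``
    integrates over the scanned band instead.
    """
    f0 = _f_value(series.f0, f_mode)
    if f0 <= 0:
        raise ValueError("non-positive reference intensity F0")
    out = []
    for q, spec in series.points:
        f = _f_value(spec, f_mode)
        if f <= 0:
            raise ValueError(f"non-positive intensity at [Q]={q} M")
        ratio = f0 / f
        frac = (f0 - f) / f0
        logterm = math.log10((f0 - f) / f) if f0 > f else None
        out.append(QuenchPoint(q, ratio, frac, math.log10(q), logterm))
    return out


def _ols(x: np.ndarray, y: np.ndarray):
    """Two-parameter OLS returning slope, intercept, se_slope, se_intercept, r2."""
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all abscissae equal")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return (
        float(res.slope),
        float(res.intercept),
        float(res.stderr) if res.stderr is not None else float("nan"),
        float(res.intercept_stderr) if res.intercept_stderr is not None else float("nan"),
        r2,
    )


def stern_volmer_fit(
    points: Sequence[QuenchPoint], temperature_K: float | None = None
) -> KsvEstimate:
    """OLS of F0/F on [Q]; the slope is Ksv, the intercept is left free."""
    if len(points) < 3:
        raise ValueError("Stern-Volmer fit needs at least 3 points")
    q = np.array([p.q_M for p in points])
    r = np.array([p.ratio for p in points])
    slope, intercept, se_s, _, r2 = _ols(q, r)
    return KsvEstimate(slope, intercept, se_s, r2, temperature_K, len(points))


def modified_sv_fit(
    points: Sequence[QuenchPoint], temperature_K: float | None = None
) -> BindingFit:
    """Double-log fit: intercept = log10 Ka, slope = n (binding sites)."""
    usable = [p for p in points if p.usable]
    if len(usable) < 3:
        raise ValueError("modified Stern-Volmer fit needs >= 3 points with F < F0")
    x = np.array([p.logq for p in usable])
    y = np.array([p.logterm for p in usable])
    slope, intercept, se_s, se_i, r2 = _ols(x, y)
    return BindingFit(10.0**intercept, slope, se_i, se_s, r2, temperature_K, len(usable))


def classify_mechanism(
    estimates: Sequence[KsvEstimate], z_threshold: float = 2.0
) -> MechanismCall:
    """Call the quenching mechanism from the Ksv-vs-temperature trend.

    The OLS slope of Ksv on T is reduced to z = slope/SE; verdicts are
    ``static`` (z <= -threshold), ``dynamic`` (z >= +threshold) and
    ``ambiguous`` otherwise.  ``z_threshold=0`` reproduces a sign-only call.
    With per-temperature standard errors available the slope SE is propagated
    from them; otherwise it comes from the regression residuals.
    """
    ests = tuple(sorted(estimates, key=lambda e: e.temperature_K))
    temps = np.array([e.temperature_K for e in ests], dtype=float)
    if np.unique(temps).size < 2:
        raise ValueError("mechanism classification needs >= 2 distinct temperatures")
    ksv = np.array([e.ksv_per_M for e in ests])
    tc = temps - temps.mean()
    sxx = float(np.sum(tc**2))
    slope = float(np.sum(tc * ksv) / sxx)
    per_t_se = np.array([e.se_slope for e in ests])
    if np.all(np.isfinite(per_t_se)) and np.all(per_t_se > 0):
        se = float(np.sqrt(np.sum((tc / sxx) ** 2 * per_t_se**2)))
    elif temps.size >= 3:
        intercept = float(ksv.mean() - slope * temps.mean())
        resid = ksv - (intercept + slope * temps)
        s2 = float(np.sum(resid**2) / (temps.size - 2))
        se = math.sqrt(s2 / sxx)
    else:
        se = 0.0  # two points, no uncertainties: sign decides
    z = slope / se if se > 0 else math.copysign(math.inf, slope) if slope else 0.0
    if z < 0 and abs(z) >= z_threshold:
        verdict = "static"
    elif z > 0 and z >= z_threshold:
        verdict = "dynamic"
    else:
        verdict = "ambiguous"
    return MechanismCall(verdict, slope, se, z, ests)


def _hill_model(q, bmax, kd, h):
    return bmax * q**h / (kd**h + q**h)


def hill_fit(
    points: Sequence[QuenchPoint],
    response: str = "f0",
    init_h: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
    bmax_max: float = 1.5,
    fix_bmax: float | None = None,
) -> HillFit:
    """Nonlinear fit of the Hill isotherm to the fractional quench.

    ``response='f0'`` fits (F0-F)/F0 (default; Bmax then lives in (0, 1]);
    ``response='f'`` fits (F0-F)/F.  Initialisation is multistarted over
    ``init_h``; ties are broken by lowest residual sum of squares, then
    lowest h.  Non-convergence across all starts is reported via the
    ``converged`` flag, never as an exception.
    """
    if len(points) < 5:
        raise ValueError("Hill fit needs at least 5 points")
    q = np.array([p.q_M for p in points])
    if response == "f0":
        y = np.array([p.frac for p in points])
    elif response == "f":
        y = np.array([p.ratio - 1.0 for p in points])
    else:
        raise ValueError(f"unknown response {response!r}")
    if np.sum(y > 0) < 4:
        raise ValueError("Hill fit needs positive fractional quench at >= 4 points")

    ymax = float(np.max(y))
    # [Q] nearest half-saturation as the Kd guess
    kd0 = float(q[int(np.argmin(np.abs(y - ymax / 2)))])
    results = []
    for h0 in init_h:
        try:
            if fix_bmax is None:
                p0 = (min(ymax * 1.05, bmax_max * 0.99), kd0, h0)
                bounds = ([1e-12, 1e-12, 0.05], [bmax_max, np.inf, 20.0])
                popt, pcov = optimize.curve_fit(
                    _hill_model, q, y, p0=p0, bounds=bounds, maxfev=20000
                )
                bm, kd, h = popt
                se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
                se_bm, se_kd, se_h = se
            else:
                model = lambda qq, kd, h: _hill_model(qq, fix_bmax, kd, h)
                popt, pcov = optimize.curve_fit(
                    model, q, y, p0=(kd0, h0),
                    bounds=([1e-12, 0.05], [np.inf, 20.0]), maxfev=20000,
                )
                bm, (kd, h) = fix_bmax, popt
                se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
                se_bm, (se_kd, se_h) = 0.0, se
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((y - _hill_model(q, bm, kd, h)) ** 2))
        results.append((ssr, float(h), float(bm), float(kd), float(se_bm), float(se_kd), float(se_h)))
    if not results:
        nan = float("nan")
        return HillFit(nan, nan, nan, nan, nan, nan, nan, converged=False)
    ssr, h, bm, kd, se_bm, se_kd, se_h = min(results, key=lambda t: (t[0], t[1]))
    return HillFit(bm, kd, h, se_bm, se_kd, se_h, ssr, converged=True)
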