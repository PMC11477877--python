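"""Synthetic instrument data with the statistical structure the analysis assumes.

The generator emulates four experiment families:

* **Titration** — Gaussian tryptophan-emission bands quenched by a ligand
  according to a chosen isotherm (static / dynamic Stern-Volmer, Hill, or an
  all-or-none concerted two-site isotherm), with the temperature dependence
  of the quenching constant following a Van 't Hoff law so that a negative
  binding enthalpy makes Ksv fall with temperature (static signature).
* **Denaturation** — three conformational states (native dimer, folded
  monomer intermediate, unfolded chain), mixed by two sequential two-state
  linear-extrapolation transitions in denaturant concentration; the observed
  band center, intensity and CD218 are population-weighted state values.
* **CD** — a linear combination of a helix-like and a coil-like basis band.
* **Hemagglutination** — boolean two-fold dilution plates from a titer.

Noise is Gaussian, relative to signal, applied per wavelength sample after
isotherm scaling; a mandatory integer seed makes every dataset bit-exactly
reproducible.  Spectrum metadata carries the true generating parameters so
recovery tests can compare estimates against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .denaturation import DenaturationRecord, HAPlate
from .spectra import CDSpectrum, EmissionSpectrum, TitrationSeries
from .thermo import R_GAS

__all__ = [
    "GeneratorConfig",
    "DenatGeneratorConfig",
    "gen_titration",
    "gen_denaturation",
    "gen_cd",
    "gen_ha",
]

_QUENCH_MODELS = ("static", "dynamic", "hill", "concerted")


def _default_q_grid() -> tuple:
    # 12 final cuvette concentrations spanning 2-11 mM
    return tuple(np.linspace(2e-3, 11e-3, 12))


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth for a quenching titration experiment.

    ``ksv_ref_per_M`` anchors the quenching/association constant at
    ``t_ref_K``; ``dH_J_mol`` sets its Van 't Hoff temperature dependence
    (``dS_J_K_mol``, if given, overrides the anchor: K(T) is then computed
    directly from exp(-dH/RT + dS/R)).  ``hill_h``/``kd_M``/``bmax``
    parameterise the cooperative isotherms.
    """

    peak_center_nm: float = 344.3
    peak_width_nm: float = 18.0
    peak_amplitude: float = 100.0
    quench_model: str = "static"
    ksv_ref_per_M: float = 28.47
    t_ref_K: float = 298.0
    dH_J_mol: float = -53240.0
    dS_J_K_mol: float | None = None
    hill_h: float = 2.0
    kd_M: float = 6e-3
    bmax: float = 1.0
    noise_rel: float = 0.0
    seed: int = 0
    q_grid_M: tuple = field(default_factory=_default_q_grid)
    temps_K: tuple = (298.0, 303.0, 308.0)
    wl_start_nm: float = 300.0
    wl_stop_nm: float = 400.0
    wl_step_nm: float = 1.0

    def __post_init__(self):
        if self.quench_model not in _QUENCH_MODELS:
            raise ValueError(f"quench_model must be one of {_QUENCH_MODELS}")
        if self.peak_width_nm <= 0:
            raise ValueError("peak_width_nm must be positive")
        if not (0 < self.bmax <= 1):
            raise ValueError("bmax must lie in (0, 1]")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        q = np.asarray(self.q_grid_M, dtype=float)
        if q.size == 0 or len(self.temps_K) == 0:
            raise ValueError("empty concentration or temperature grid")
        if np.any(q <= 0):
            raise ValueError("quencher concentrations must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q_grid_M must be strictly increasing")
        object.__setattr__(self, "q_grid_M", tuple(q))
        object.__setattr__(self, "temps_K", tuple(float(t) for t in self.temps_K))

    def ksv_at(self, temperature_K: float) -> float:
        """Quenching/association constant at T under the Van 't Hoff law."""
        if self.dS_J_K_mol is not None:
            return math.exp(-self.dH_J_mol / (R_GAS * temperature_K)
                            + self.dS_J_K_mol / R_GAS)
        if self.ksv_ref_per_M == 0:
            return 0.0
        return self.ksv_ref_per_M * math.exp(
            -self.dH_J_mol / R_GAS * (1.0 / temperature_K - 1.0 / self.t_ref_K)
        )

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wl_stop_nm - self.wl_start_nm) / self.wl_step_nm)) + 1
        return self.wl_start_nm + self.wl_step_nm * np.arange(n)


def _gaussian_band(wl: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-(((wl - center) / width) ** 2))


def _quench_scale(config: GeneratorConfig, q: float, temperature_K: float) -> float:
    """F/F0 at quencher concentration q."""
    model = config.quench_model
    if model in ("static", "dynamic"):
        return 1.0 / (1.0 + config.ksv_at(temperature_K) * q)
    if model == "hill":
        h = config.hill_h
    else:  # concerted: all-or-none two-site
        h = 2.0
    y = config.bmax * q**h / (config.kd_M**h + q**h)
    return 1.0 - y


def _noisy(rng: np.random.Generator, values: np.ndarray, noise_rel: float) -> np.ndarray:
    if noise_rel == 0:
        return values
    return values * (1.0 + noise_rel * rng.standard_normal(values.size))


def gen_titration(config: GeneratorConfig) -> list[TitrationSeries]:
    """One TitrationSeries per temperature in ``config.temps_K``.

    Noise-free static output satisfies F = F0 / (1 + Ksv(T) [Q]) exactly at
    every grid point.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelength_grid()
    band = _gaussian_band(wl, config.peak_center_nm, config.peak_width_nm,
                          config.peak_amplitude)
    series = []
    for t in config.temps_K:
        truth = {
            "model": config.quench_model,
            "true_ksv_per_M": config.ksv_at(t),
            "true_kd_M": config.kd_M,
            "true_h": config.hill_h if config.quench_model == "hill" else
                      (2.0 if config.quench_model == "concerted" else 1.0),
            "true_bmax": config.bmax,
            "dH_J_mol": config.dH_J_mol,
        }
        f0 = EmissionSpectrum(
            wl, _noisy(rng, band, config.noise_rel),
            meta={"temperature_K": t, "quencher_M": 0.0, **truth},
        )
        points = []
        for q in config.q_grid_M:
            scale = _quench_scale(config, q, t)
            spec = EmissionSpectrum(
                wl, _noisy(rng, band * scale, config.noise_rel),
                meta={"temperature_K": t, "quencher_M": q, **truth},
            )
            points.append((q, spec))
        series.append(TitrationSeries(f0, tuple(points), t))
    return series


# ---------------------------------------------------------------------------
# denaturation


@dataclass(frozen=True)
class DenatGeneratorConfig:
    """Ground truth for a urea-denaturation experiment.

    State triples give (band center nm, band intensity a.u., CD218 mdeg) for
    the native dimer, the folded monomer and the unfolded chain.  The two
    transitions are two-state linear-extrapolation steps with midpoints
    ``c_half1_M`` (dimer -> monomer) and ``c_half2_M`` (monomer -> unfolded)
    and m-values in J/mol per molar denaturant.
    """

    native: tuple = (344.3, 53.82, -8.0)
    intermediate: tuple = (346.3, 64.5, -12.0)
    unfolded: tuple = (346.3, 56.11, -3.0)
    c_half1_M: float = 2.5
    c_half2_M: float = 7.5
    m1_J_mol_M: float = 10000.0
    m2_J_mol_M: float = 10000.0
    urea_grid_M: tuple = (0.0, 5.0, 10.0)
    replicates: int = 3
    noise_rel: float = 0.005
    ha_activity_native: int = 64
    ha_intermediate_factor: float = 0.125
    ha_n_wells: int = 10
    temperature_K: float = 298.15
    peak_width_nm: float = 18.0
    wl_start_nm: float = 300.0
    wl_stop_nm: float = 430.0
    wl_step_nm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.c_half1_M < self.c_half2_M:
            raise ValueError("c_half1_M must be < c_half2_M")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.urea_grid_M) == 0:
            raise ValueError("empty urea grid")
        object.__setattr__(self, "urea_grid_M",
                           tuple(float(u) for u in self.urea_grid_M))

    def populations(self, urea_M: float) -> tuple[float, float, float]:
        """(native, intermediate, unfolded) fractions; they sum to 1 exactly."""
        rt = R_GAS * self.temperature_K
        k1 = math.exp(self.m1_J_mol_M * (urea_M - self.c_half1_M) / rt)
        k2 = math.exp(self.m2_J_mol_M * (urea_M - self.c_half2_M) / rt)
        z = 1.0 + k1 + k1 * k2
        return 1.0 / z, k1 / z, k1 * k2 / z

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wl_stop_nm - self.wl_start_nm) / self.wl_step_nm)) + 1
        return self.wl_start_nm + self.wl_step_nm * np.arange(n)


def _power_of_two_titer(x: float) -> int:
    """Nearest power of two to x (0 below 1)."""
    if x < 1.0:
        return 0
    return int(2 ** round(math.log2(x)))


def gen_denaturation(config: DenatGeneratorConfig) -> list[DenaturationRecord]:
    """One DenaturationRecord (replicated spectra + CD + HA plate) per urea level."""
    rng = np.random.default_rng(config.seed)
    wl = config.wavelength_grid()
    states = (config.native, config.intermediate, config.unfolded)
    records = []
    for u in config.urea_grid_M:
        pops = config.populations(u)
        lam = sum(p * s[0] for p, s in zip(pops, states))
        imax = sum(p * s[1] for p, s in zip(pops, states))
        cdval = sum(p * s[2] for p, s in zip(pops, states))
        band = _gaussian_band(wl, lam, config.peak_width_nm, imax)
        truth = {"true_lambda_max": lam, "true_imax": imax,
                 "true_cd218": cdval, "populations": pops}
        specs = tuple(
            EmissionSpectrum(
                wl, _noisy(rng, band, config.noise_rel),
                meta={"urea_M": u, "replicate": r + 1, **truth},
            )
            for r in range(config.replicates)
        )
        # smooth far-UV curve whose 218 nm value equals the mixed CD218;
        # urea-treated scans start at 210 nm (poor signal-to-noise below)
        cd_wl = np.arange(210.0 if u > 0 else 180.0, 281.0, 1.0)
        cd_sig = cdval * np.exp(-(((cd_wl - 218.0) / 20.0) ** 2))
        cd = CDSpectrum(cd_wl, _noisy(rng, cd_sig, config.noise_rel),
                        protein_conc_M=30e-6, path_cm=0.02, n_residues=101,
                        meta={"urea_M": u, "true_cd218": cdval})
        activity = config.ha_activity_native * (
            pops[0] + config.ha_intermediate_factor * pops[1]
        )
        ha = gen_ha(_power_of_two_titer(activity), config.ha_n_wells)
        records.append(DenaturationRecord(u, specs, cd=cd, ha=ha))
    return records


# ---------------------------------------------------------------------------
# CD and HA primitives


def _helix_basis(wl: np.ndarray) -> np.ndarray:
    # positive pi->pi* lobe near 192 nm, broad negative lobe centred ~221 nm
    return 60.0 * np.exp(-(((wl - 192.0) / 8.0) ** 2)) - 12.0 * np.exp(
        -(((wl - 221.0) / 16.0) ** 2)
    )


def _coil_basis(wl: np.ndarray) -> np.ndarray:
    # strong negative band near 198 nm, nearly flat through the 218 nm region
    return -15.0 * np.exp(-(((wl - 198.0) / 10.0) ** 2)) - 0.3 * np.exp(
        -(((wl - 220.0) / 25.0) ** 2)
    )


def gen_cd(helix_fraction: float, noise_rel: float = 0.0, seed: int = 0,
           wl_start_nm: float = 180.0, wl_stop_nm: float = 280.0) -> CDSpectrum:
    """Linear mix of a helix-like and a coil-like basis band over 180-280 nm."""
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValueError("helix_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    wl = np.arange(wl_start_nm, wl_stop_nm + 0.5, 1.0)
    sig = helix_fraction * _helix_basis(wl) + (1.0 - helix_fraction) * _coil_basis(wl)
    if noise_rel:
        sig = sig + noise_rel * np.max(np.abs(sig)) * rng.standard_normal(sig.size)
    return CDSpectrum(wl, sig, meta={"helix_fraction": helix_fraction})


def gen_ha(activity_titer: int, n_wells: int = 10, start_dilution: int = 1) -> HAPlate:
    """Boolean plate positive exactly for dilutions 1:start ... 1:activity_titer."""
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if activity_titer < 0:
        raise ValueError("activity_titer must be >= 0")
    dilutions = [start_dilution * 2**i for i in range(n_wells)]
    wells = tuple(d <= activity_titer for d in dilutions)
    return HAPlate(wells, start_dilution)
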