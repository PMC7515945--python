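"""Isotope and Cerenkov physics primitives.

This module provides the physical building blocks used by the specimen
phantom and by the quantification chain:

* allowed-shape beta spectra with a non-relativistic Coulomb (Fermi)
  correction,
* the Cerenkov kinetic-energy threshold in a dielectric medium,
* a Frank-Tamm photon yield per decay under the continuous-slowing-down
  approximation (CSDA) with a tabulated water stopping power,
* radioactive decay factors,
* depth-dependent optical transmission of tissue in a wavelength band.

Energies are in keV, wavelengths in nm, depths in mm, attenuation
coefficients in cm^-1 and time in minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

ELECTRON_MASS_KEV = 510.999  # electron rest energy m_e c^2
FINE_STRUCTURE = 1.0 / 137.035999

# Default bands: the open detector window and the 550 nm shortpass filter.
# The effective attenuation coefficients are order-of-magnitude soft-tissue
# defaults (short wavelengths attenuate faster); only their ordering is
# physically asserted, the magnitudes are configuration.
DEFAULT_MU_UNFILTERED_PER_CM = 2.0
DEFAULT_MU_SHORTPASS_PER_CM = 10.0


@dataclass(frozen=True)
class Isotope:
    """A beta-emitting isotope as registered for CLI use."""

    name: str
    half_life_min: float
    beta_endpoint_kev: float
    mean_positron_range_mm: float
    branching_fraction_beta: float
    daughter_z: int = 0
    beta_plus: bool = True

    def __post_init__(self) -> None:
        if self.half_life_min <= 0:
            raise DomainError("half_life_min must be positive")
        if self.beta_endpoint_kev <= 0:
            raise DomainError("beta_endpoint_kev must be positive")
        if self.mean_positron_range_mm < 0:
            raise DomainError("mean_positron_range_mm must be non-negative")
        if not 0 < self.branching_fraction_beta <= 1:
            raise DomainError("branching_fraction_beta must lie in (0, 1]")


@dataclass(frozen=True)
class OpticalBand:
    """A wavelength band with an effective tissue attenuation coefficient."""

    lower_nm: float
    upper_nm: float
    mu_eff_per_cm: float

    def __post_init__(self) -> None:
        if not 0 < self.lower_nm < self.upper_nm:
            raise DomainError("require 0 < lower_nm < upper_nm")
        if self.mu_eff_per_cm < 0:
            raise DomainError("mu_eff_per_cm must be non-negative")


UNFILTERED_BAND = OpticalBand(400.0, 800.0, DEFAULT_MU_UNFILTERED_PER_CM)
SHORTPASS_550_BAND = OpticalBand(400.0, 550.0, DEFAULT_MU_SHORTPASS_PER_CM)


@dataclass(frozen=True)
class BetaSpectrum:
    """Kinetic-energy distribution of emitted beta particles.

    ``density`` is a probability density per keV on ``energy_kev`` and
    integrates to one over [0, endpoint].
    """

    energy_kev: np.ndarray
    density: np.ndarray
    endpoint_kev: float

    def mean_energy_kev(self) -> float:
        return float(np.trapezoid(self.energy_kev * self.density, self.energy_kev))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw kinetic energies by inverse-CDF interpolation."""
        cdf = _cumtrapz(self.density, self.energy_kev)
        cdf /= cdf[-1]
        u = rng.random(n)
        return np.interp(u, cdf, self.energy_kev)


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    dx = np.diff(x)
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * dx * (y[1:] + y[:-1]))
    return out


# ---------------------------------------------------------------------------
# Isotope registry
# ---------------------------------------------------------------------------

def load_isotope_registry(path: str | Path | None = None) -> dict[str, Isotope]:
    """Load the isotope registry from YAML (the packaged file by default)."""
    if path is None:
        text = resources.files("climargin").joinpath("data/isotopes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "isotopes" not in raw:
        raise ConfigurationError("isotope registry must contain an 'isotopes' mapping")
    registry: dict[str, Isotope] = {}
    for name, fields in raw["isotopes"].items():
        try:
            registry[name] = Isotope(name=name, **fields)
        except (TypeError, DomainError) as exc:
            raise ConfigurationError(f"bad registry entry for {name!r}: {exc}") from exc
    return registry


_REGISTRY: dict[str, Isotope] | None = None


def get_isotope(name: str) -> Isotope:
    """Look up an isotope in the packaged registry."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_isotope_registry()
    try:
        return _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise ConfigurationError(f"unknown isotope {name!r}; registry has: {known}")


# ---------------------------------------------------------------------------
# Beta spectrum
# ---------------------------------------------------------------------------

def beta_spectrum(isotope: Isotope, grid_resolution_kev: float = 1.0) -> BetaSpectrum:
    """Allowed-shape beta spectrum with non-relativistic Fermi correction.

    N(T) ∝ F(Z, T) · p · E_tot · (Q − T)², where p and E_tot are the
    momentum and total energy of the beta particle, Q the endpoint and
    F the non-relativistic Coulomb factor F = 2πη / (1 − exp(−2πη)) with
    η = ∓ Z α / β: Coulomb repulsion suppresses the low-energy end for
    positrons, attraction enhances it for electrons. The density is
    normalised to unit area on [0, Q].
    """
    if grid_resolution_kev <= 0:
        raise DomainError("grid_resolution_kev must be positive")
    q = isotope.beta_endpoint_kev
    n_pts = max(int(np.ceil(q / grid_resolution_kev)) + 1, 16)
    energy = np.linspace(0.0, q, n_pts)
    density = _allowed_shape(energy, q, isotope.daughter_z, isotope.beta_plus)
    area = np.trapezoid(density, energy)
    if area <= 0:
        raise ConfigurationError(f"degenerate beta spectrum for {isotope.name}")
    return BetaSpectrum(energy_kev=energy, density=density / area, endpoint_kev=q)


def _allowed_shape(t_kev: np.ndarray, q_kev: float, z_daughter: int,
                   beta_plus: bool) -> np.ndarray:
    t = np.asarray(t_kev, dtype=float)
    e_tot = t + ELECTRON_MASS_KEV
    pc = np.sqrt(np.maximum(e_tot**2 - ELECTRON_MASS_KEV**2, 0.0))
    shape = pc * e_tot * np.maximum(q_kev - t, 0.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(e_tot > 0, pc / e_tot, 0.0)
        eta = z_daughter * FINE_STRUCTURE / np.where(beta > 0, beta, np.inf)
        if beta_plus:
            eta = -eta
        x = 2.0 * np.pi * eta
        fermi = np.where(np.abs(x) < 1e-12, 1.0, x / (1.0 - np.exp(-x)))
    out = shape * np.nan_to_num(fermi, nan=0.0, posinf=0.0)
    out[t <= 0] = 0.0
    out[t >= q_kev] = 0.0
    return out


# ---------------------------------------------------------------------------
# Cerenkov threshold and yield
# ---------------------------------------------------------------------------

def cerenkov_threshold_energy(refractive_index: float) -> float:
    """Kinetic energy [keV] at which a particle reaches phase velocity c/n.

    Closed form: T = m_e c² (1/√(1 − n⁻²) − 1); diverges as n → 1.
    """
    if refractive_index <= 1.0:
        raise DomainError("refractive_index must exceed 1")
    gamma = 1.0 / np.sqrt(1.0 - refractive_index**-2)
    return ELECTRON_MASS_KEV * (gamma - 1.0)


# Total (collision + radiative) electron stopping power of liquid water,
# MeV cm²/g == MeV/cm at unit density; interpolated log-log between nodes.
_WATER_T_MEV = np.array([
    0.01, 0.015, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10,
    0.15, 0.20, 0.30, 0.40, 0.50, 0.60, 0.80, 1.00, 1.50, 2.00, 3.00,
])
_WATER_S_MEV_CM = np.array([
    22.56, 16.47, 13.17, 9.753, 7.781, 6.603, 5.797, 4.757, 4.115,
    3.238, 2.793, 2.355, 2.148, 2.034, 1.963, 1.886, 1.849, 1.822,
    1.824, 1.846,
])


def water_stopping_power(t_kev: np.ndarray | float) -> np.ndarray:
    """Electron total stopping power of water [keV/cm] at kinetic energy t_kev."""
    t_mev = np.atleast_1d(np.asarray(t_kev, dtype=float)) / 1000.0
    t_mev = np.clip(t_mev, _WATER_T_MEV[0], _WATER_T_MEV[-1])
    logs = np.interp(np.log(t_mev), np.log(_WATER_T_MEV), np.log(_WATER_S_MEV_CM))
    return np.exp(logs) * 1000.0


def frank_tamm_photons_per_cm(t_kev: np.ndarray, refractive_index: float,
                              band: OpticalBand) -> np.ndarray:
    """Frank-Tamm photon emission rate per unit path [photons/cm].

    dN/dx = 2πα (1/λ₁ − 1/λ₂)(1 − 1/(β²n²)) for β n > 1, else 0;
    dispersion of n over the band is neglected.
    """
    e_tot = np.asarray(t_kev, dtype=float) + ELECTRON_MASS_KEV
    beta2 = 1.0 - (ELECTRON_MASS_KEV / e_tot) ** 2
    factor = 1.0 - 1.0 / (beta2 * refractive_index**2)
    factor = np.maximum(factor, 0.0)
    inv_lambda = 1.0 / (band.lower_nm * 1e-7) - 1.0 / (band.upper_nm * 1e-7)  # cm^-1
    return 2.0 * np.pi * FINE_STRUCTURE * inv_lambda * factor


def cerenkov_photons_per_particle(t0_kev: np.ndarray, refractive_index: float,
                                  band: OpticalBand,
                                  stopping_power=water_stopping_power,
                                  grid_points: int = 2000) -> np.ndarray:
    """Photons emitted by an electron of initial kinetic energy t0 slowing to rest.

    CSDA path integral N(T₀) = ∫_{T_thr}^{T₀} (dN/dx)(T) / S(T) dT evaluated
    on a fixed energy grid and interpolated at the requested energies.
    """
    t0 = np.atleast_1d(np.asarray(t0_kev, dtype=float))
    t_thr = cerenkov_threshold_energy(refractive_index)
    t_max = max(float(t0.max(initial=0.0)), t_thr * 1.001)
    grid = np.linspace(t_thr, t_max, grid_points)
    integrand = frank_tamm_photons_per_cm(grid, refractive_index, band) / stopping_power(grid)
    cumulative = _cumtrapz(integrand, grid)
    return np.interp(t0, grid, cumulative, left=0.0)


def cerenkov_yield(spectrum: BetaSpectrum, refractive_index: float,
                   band: OpticalBand, n_samples: int = 100_000,
                   seed: int = 0, branching_fraction: float = 1.0,
                   stopping_power=water_stopping_power) -> float:
    """Monte-Carlo mean Cerenkov photon number per decay in ``band``.

    Initial energies are sampled from the beta spectrum; each particle's
    photon count is the CSDA Frank-Tamm path integral; the mean is scaled
    by the beta branching fraction to give photons per decay.
    """
    if n_samples < 1:
        raise DomainError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    t_thr = cerenkov_threshold_energy(refractive_index)
    if spectrum.endpoint_kev <= t_thr:
        return 0.0
    t0 = spectrum.sample(n_samples, rng)
    photons = cerenkov_photons_per_particle(t0, refractive_index, band,
                                            stopping_power=stopping_power)
    return float(photons.mean() * branching_fraction)


# ---------------------------------------------------------------------------
# Decay and tissue optics
# ---------------------------------------------------------------------------

def decay_factor(elapsed_min: float, half_life_min: float) -> float:
    """Fraction of activity remaining after ``elapsed_min``: 2^(−t/T½)."""
    if half_life_min <= 0:
        raise DomainError("half_life_min must be positive")
    return float(2.0 ** (-elapsed_min / half_life_min))


def tissue_transmission(depth_mm: float | np.ndarray, band: OpticalBand):
    """Optical transmission exp(−μ_eff · depth) of tissue at the given depth."""
    depth = np.asarray(depth_mm, dtype=float)
    if np.any(depth < 0):
        raise DomainError("depth_mm must be non-negative")
    out = np.exp(-band.mu_eff_per_cm * depth / 10.0)
    return float(out) if np.isscalar(depth_mm) else out


def band_spectral_weight(band: OpticalBand) -> float:
    """Relative Cerenkov photon content of a band (∫ λ⁻² dλ = 1/λ₁ − 1/λ₂)."""
    return 1.0 / band.lower_nm - 1.0 / band.upper_nm
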