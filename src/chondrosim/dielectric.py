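"""Effective dielectric spectra and the single-shell suspension oracle.

For a parallel-plate configuration with cell constant k = separation/area
(1/m), the effective properties follow from the admittance Y = 1/Z:

    σ_eff(ω)   = Re(Y) · k
    ε_r_eff(ω) = Im(Y) · k / (ω ε₀)

The analytic reference for dilute suspensions of membrane-covered spherical
cells is the Maxwell–Wagner mixture formula with the shelled particle
replaced by an equivalent homogeneous sphere (single-shell model, after
Asami): with complex relative permittivities ε* = ε_r − jσ/(ωε₀) and
v = (1 − d_m/R)³,

    ε*_p   = ε*_m · [2(1−v)ε*_m + (1+2v)ε*_cyt] / [(2+v)ε*_m + (1−v)ε*_cyt]
    ε*_eff = ε*_buf · [2(1−φ)ε*_buf + (1+2φ)ε*_p] / [(2+φ)ε*_buf + (1−φ)ε*_p]

which exhibits the β-dispersion step near 1 MHz for physiological
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .solver import EPS0, ImpedanceSpectrum, MaterialProps


@dataclass
class DielectricSpectrum:
    frequencies: np.ndarray  # Hz
    sigma_eff: np.ndarray  # S/m
    eps_r_eff: np.ndarray  # dimensionless
    cell_constant: float = np.nan  # 1/m
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.sigma_eff = np.asarray(self.sigma_eff, dtype=float)
        self.eps_r_eff = np.asarray(self.eps_r_eff, dtype=float)


def extract_dielectric(
    spec: ImpedanceSpectrum, plate_separation: float, plate_area: float
) -> DielectricSpectrum:
    """Convert an impedance spectrum to σ_eff, ε_r_eff (plate geometry, SI).

    ω = 0 rows have no defined permittivity and are reported as NaN.
    """
    if plate_separation <= 0 or plate_area <= 0:
        raise ValueError("plate dimensions must be positive")
    if np.any(spec.Z == 0):
        raise ValueError("impedance must be nonzero")
    k = plate_separation / plate_area
    y = 1.0 / spec.Z
    omega = 2.0 * np.pi * spec.frequencies
    sigma = np.real(y) * k
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(omega > 0, np.imag(y) * k / (omega * EPS0), np.nan)
    return DielectricSpectrum(spec.frequencies, sigma, eps, cell_constant=k)


def _complex_rel_permittivity(sigma: float, eps_r: float, omega: np.ndarray) -> np.ndarray:
    return eps_r - 1j * sigma / (omega * EPS0)


def single_shell_suspension(
    props: MaterialProps,
    cell_radius: float,
    volume_fraction: float,
    frequencies: np.ndarray,
) -> DielectricSpectrum:
    """Analytic dilute single-shell suspension spectrum (see module docs).

    ``cell_radius`` in metres.  Valid in the dilute regime (φ < ~0.1) with
    d_m ≪ R; outside that a warning is emitted but the formula is still
    evaluated.
    """
    if not 0 <= volume_fraction < 1:
        raise ValueError("volume_fraction must be in [0, 1)")
    if volume_fraction >= 0.1:
        warnings.warn("volume fraction outside the dilute regime; result is approximate")
    freqs = np.asarray(frequencies, dtype=float)
    omega = 2.0 * np.pi * freqs
    e_m = _complex_rel_permittivity(props.sigma_m, props.eps_rm, omega)
    e_c = _complex_rel_permittivity(props.sigma_cyt, props.eps_rcyt, omega)
    e_b = _complex_rel_permittivity(props.sigma_buf, props.eps_rbuf, omega)
    v = (1.0 - props.d_m / cell_radius) ** 3
    e_p = e_m * (2.0 * (1.0 - v) * e_m + (1.0 + 2.0 * v) * e_c) / (
        (2.0 + v) * e_m + (1.0 - v) * e_c
    )
    phi = volume_fraction
    e_eff = e_b * (2.0 * (1.0 - phi) * e_b + (1.0 + 2.0 * phi) * e_p) / (
        (2.0 + phi) * e_b + (1.0 - phi) * e_p
    )
    sigma_eff = -np.imag(e_eff) * omega * EPS0
    eps_r_eff = np.real(e_eff)
    return DielectricSpectrum(freqs, sigma_eff, eps_r_eff, meta={"phi": phi, "R": cell_radius})


def two_phase_maxwell(
    sigma_p: float,
    eps_rp: float,
    props: MaterialProps,
    volume_fraction: float,
    frequencies: np.ndarray,
) -> DielectricSpectrum:
    """Shell-free Maxwell mixture of homogeneous spheres in the buffer
    (limit check for a functionally vanishing membrane)."""
    freqs = np.asarray(frequencies, dtype=float)
    omega = 2.0 * np.pi * freqs
    e_p = _complex_rel_permittivity(sigma_p, eps_rp, omega)
    e_b = _complex_rel_permittivity(props.sigma_buf, props.eps_rbuf, omega)
    phi = volume_fraction
    e_eff = e_b * (2.0 * (1.0 - phi) * e_b + (1.0 + 2.0 * phi) * e_p) / (
        (2.0 + phi) * e_b + (1.0 - phi) * e_p
    )
    return DielectricSpectrum(freqs, -np.imag(e_eff) * omega * EPS0, np.real(e_eff))
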