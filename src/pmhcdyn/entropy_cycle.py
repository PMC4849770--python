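"""Quasi-harmonic conformational entropy and the binding thermodynamic cycle.

The mass-weighted covariance matrix of an ensemble,

    C = < dq dq^T >,   q_i = sqrt(m_i) * r_i   (units amu·Å²)

is diagonalized; each retained eigenvalue lambda defines an effective
harmonic-oscillator frequency omega = sqrt(k_B T / lambda), and the
vibrational entropy is the quantum harmonic-oscillator sum

    S = k_B * sum_i [ x_i / (exp(x_i) - 1) - ln(1 - exp(-x_i)) ],
    x_i = hbar * omega_i / (k_B T)

(the standard quasi-harmonic estimator).  Results are reported as -T*S in
kJ/mol, the sign convention of entropic contributions to binding free
energy.  The binding cycle subtracts the free-receptor and binary-complex
terms from the ternary complex:

    -T dS_binding = (-T S)_ternary - (-T S)_free_receptor - (-T S)_binary

and species are compared through differences relative to a reference
antigen.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import constants

from .fluctuation_stats import average_structure
from .geometry import superpose_frames
from .io_model import Ensemble, Selection

__all__ = [
    "QuasiHarmonicSpectrum",
    "EntropyResult",
    "CycleResult",
    "mass_weighted_covariance",
    "quasiharmonic_spectrum",
    "quasiharmonic_entropy",
    "binding_cycle",
    "DEFAULT_TEMPERATURE",
]

DEFAULT_TEMPERATURE = 298.0  # K

# Unit chain: covariance eigenvalues are in amu·Å².
#   lambda [kg·m²] = lambda [amu·Å²] * _AMU * 1e-20
#   omega  [rad/s] = sqrt(k_B T / lambda_SI)
#   S [J/(mol·K)]  = R * sum_i s(x_i),  x_i = hbar*omega_i/(k_B T)
_AMU = constants.atomic_mass  # kg
_A2 = 1e-20  # m² per Å²
_KB = constants.k  # J/K
_HBAR = constants.hbar  # J·s
_R = constants.R  # J/(mol·K)


@dataclasses.dataclass
class QuasiHarmonicSpectrum:
    """Eigenvalue/frequency spectrum of a mass-weighted covariance matrix."""

    eigenvalues: np.ndarray  # retained, amu·Å², descending
    frequencies: np.ndarray  # rad/s, ascending (largest eigenvalue -> softest mode)
    n_dropped: int
    temperature: float  # K
    scope: str = ""


@dataclasses.dataclass
class EntropyResult:
    """Conformational entropy reported as -T*S (kJ/mol) at a stated temperature."""

    minus_T_dS: float
    temperature: float
    spectrum: QuasiHarmonicSpectrum | None = None
    label: str = ""


@dataclasses.dataclass
class CycleResult:
    """Entropic binding contribution of one species, optionally vs a reference."""

    label: str
    binding: float  # -T dS_binding, kJ/mol
    delta_delta_binding: float | None = None  # vs reference, kJ/mol
    delta_delta_binary: float | None = None  # binary-complex difference vs reference


def mass_weighted_covariance(
    ensemble: Ensemble,
    selection: Selection,
    fit_selection: Selection | None = None,
) -> np.ndarray:
    """Sample covariance of mass-weighted coordinates, (3n, 3n) in amu·Å².

    If ``fit_selection`` is given, frames are first superposed onto the
    iteratively fitted average structure (removing global translation and
    rotation); pass None for ensembles that are already aligned or for
    free-oscillator analyses where rigid-body motion is part of the model.
    """
    if ensemble.n_frames < 2:
        raise ValueError("covariance requires at least 2 frames")
    coords = ensemble.coordinates
    if fit_selection is not None:
        avg = average_structure(ensemble, fit_selection)
        coords = superpose_frames(coords, avg, fit_selection.as_array())
    idx = selection.as_array()
    x = coords[:, idx, :].reshape(ensemble.n_frames, -1)  # (T, 3n)
    sqrt_m = np.repeat(np.sqrt(ensemble.topology.masses[idx]), 3)
    q = x * sqrt_m
    dq = q - q.mean(axis=0)
    cov = dq.T @ dq / (len(dq) - 1)
    return 0.5 * (cov + cov.T)


def quasiharmonic_spectrum(
    cov: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    tolerance: float = 1e-8,
    n_rigid_modes: int = 6,
    scope: str = "",
) -> QuasiHarmonicSpectrum:
    """Quasi-harmonic mode spectrum of a mass-weighted covariance matrix.

    The ``n_rigid_modes`` smallest eigenvalues are discarded (superposed
    ensembles retain ~6 quasi-null rigid-body modes), as is any eigenvalue
    below ``tolerance`` (amu·Å²).  Each retained eigenvalue maps to a
    harmonic frequency omega = sqrt(k_B T / lambda).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance matrix is not symmetric")
    evals = np.linalg.eigvalsh(cov)[::-1]  # descending
    n_total = len(evals)
    if n_rigid_modes > 0:
        evals = evals[: max(n_total - n_rigid_modes, 0)]
    evals = evals[evals > tolerance]
    lam_si = evals * _AMU * _A2
    freqs = np.sqrt(_KB * temperature / lam_si) if len(lam_si) else np.empty(0)
    return QuasiHarmonicSpectrum(
        eigenvalues=evals,
        frequencies=freqs,
        n_dropped=n_total - len(evals),
        temperature=temperature,
        scope=scope,
    )


def _oscillator_entropy_terms(x: np.ndarray) -> np.ndarray:
    """Dimensionless per-mode entropy s(x) = x/(e^x - 1) - ln(1 - e^-x), overflow-safe."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    small = x < 700  # beyond this a mode is frozen out and contributes ~0
    xs = x[small]
    out[small] = xs / np.expm1(xs) - np.log1p(-np.exp(-xs))
    return out


def quasiharmonic_entropy(spectrum: QuasiHarmonicSpectrum, label: str = "") -> EntropyResult:
    """Vibrational entropy of a quasi-harmonic spectrum, returned as -T*S (kJ/mol)."""
    if len(spectrum.eigenvalues) == 0:
        raise ValueError("spectrum has no retained modes")
    x = _HBAR * spectrum.frequencies / (_KB * spectrum.temperature)
    s_molar = _R * np.sum(_oscillator_entropy_terms(x))  # J/(mol·K)
    minus_t_ds = -spectrum.temperature * s_molar / 1000.0  # kJ/mol
    return EntropyResult(
        minus_T_dS=minus_t_ds,
        temperature=spectrum.temperature,
        spectrum=spectrum,
        label=label,
    )


def oscillator_entropy_from_eigenvalues(
    eigenvalues: np.ndarray, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Closed-form -T*S (kJ/mol) for independent oscillators with given
    covariance eigenvalues (amu·Å²).  Convenience wrapper used as an analytic
    reference for generator-based estimates."""
    spec = quasiharmonic_spectrum(
        np.diag(np.asarray(eigenvalues, dtype=float)),
        temperature=temperature,
        n_rigid_modes=0,
    )
    return quasiharmonic_entropy(spec).minus_T_dS


def binding_cycle(
    binary: EntropyResult,
    ternary: EntropyResult,
    free_receptor: EntropyResult,
    reference: tuple[EntropyResult, EntropyResult] | None = None,
    label: str = "",
) -> CycleResult:
    """Entropic contribution to receptor binding from the thermodynamic cycle.

    ``binding = ternary - free_receptor - binary`` in -T*S terms: the
    entropy change when the pre-formed binary complex and the free receptor
    associate into the ternary complex.  With ``reference`` (the reference
    species' (binary, ternary) results, sharing the same free receptor), the
    result also carries the binding and binary-complex differences relative
    to that species.
    """
    temps = {binary.temperature, ternary.temperature, free_receptor.temperature}
    if reference is not None:
        temps |= {reference[0].temperature, reference[1].temperature}
    if len({round(t, 6) for t in temps}) != 1:
        raise ValueError(f"temperature mismatch across cycle inputs: {sorted(temps)}")
    binding = ternary.minus_T_dS - free_receptor.minus_T_dS - binary.minus_T_dS
    ddb = ddbinary = None
    if reference is not None:
        ref_binary, ref_ternary = reference
        ref_binding = ref_ternary.minus_T_dS - free_receptor.minus_T_dS - ref_binary.minus_T_dS
        ddb = binding - ref_binding
        ddbinary = binary.minus_T_dS - ref_binary.minus_T_dS
    return CycleResult(
        label=label or binary.label,
        binding=binding,
        delta_delta_binding=ddb,
        delta_delta_binary=ddbinary,
    )
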