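"""Vibrational frequencies from the mass-weighted Hessian.

The squared mode frequencies ω² are the generalized eigenvalues of
(H, M), equal to the eigenvalues of M^{-1/2} H M^{-1/2}.  The
highest frequency fixes the time-step rule: Δt = one tenth of the fastest
oscillation period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from ..units import TIME_FS

__all__ = ["FrequencyReport", "mass_weighted_frequencies", "dt_rule_fs"]


@dataclass
class FrequencyReport:
    omega: np.ndarray        # mode angular frequencies, internal units, ≥ 0
    f_max: float             # highest ordinary frequency, ps⁻¹
    dt_rule: float           # fs, (1/f_max)/10
    n_imaginary: int         # count of negative-curvature modes


def dt_rule_fs(f_max_per_ps: float) -> float:
    """One tenth of the fastest vibrational period, in fs."""
    return (1.0 / f_max_per_ps) * 1e3 / 10.0


def mass_weighted_frequencies(H: np.ndarray, M: np.ndarray) -> FrequencyReport:
    """Frequencies of the generalized eigenproblem H v = ω² M v.

    H in eV/Å², M in u (both symmetric, M positive definite).  Negative
    eigenvalues are reported as imaginary-frequency modes and excluded
    from ``omega``/``f_max``.
    """
    H = np.asarray(H, float)
    M = np.asarray(M, float)
    wM, VM = np.linalg.eigh(0.5 * (M + M.T))
    if wM.min() <= 0:
        raise ValueError("mass matrix is not positive definite")
    Minv_half = (VM / np.sqrt(wM)) @ VM.T
    A = Minv_half @ (0.5 * (H + H.T)) @ Minv_half
    lam = np.linalg.eigvalsh(0.5 * (A + A.T))
    n_imag = int(np.sum(lam < -1e-10))
    lam = np.clip(lam, 0.0, None)
    omega = np.sqrt(lam)
    f_max = float(omega.max() / (2.0 * np.pi) * 1e3 / TIME_FS)   # ps⁻¹
    return FrequencyReport(omega, f_max, dt_rule_fs(f_max), n_imag)


def generalized_frequencies(H, M):
    """Independent route via the generalized eigensolver (cross-check)."""
    lam = eigh(0.5 * (np.asarray(H) + np.asarray(H).T),
               0.5 * (np.asarray(M) + np.asarray(M).T),
               eigvals_only=True)
    return np.sqrt(np.clip(lam, 0.0, None))
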