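"""Mode-filtered power spectra of atomic motions.

Per-molecule scalar signals isolate the three motion classes of a
molecular liquid:

* ``trans`` — center-of-mass Cartesian coordinates (three signals per
  molecule),
* ``rot``   — the orientation of the molecular axis relative to the
  laboratory z axis, tracked as the cosine (the z component of the unit
  axis vector).  The cosine is smooth where the bare angle suffers
  reflection kinks at 0 and π, which would otherwise leak broadband noise
  into the derivative spectrum,
* ``vib``   — the first bond length of each molecule.

The spectral estimator is the periodogram of the second time derivative
(by central differences on the stored stride) of each signal: detrended,
Hann-windowed, averaged over molecules and signal components, and smoothed
with a short moving mean before the peak is located.  Weighting by the
second derivative suppresses the large zero-frequency content of diffusive
motion, so peak positions — the quantity of interest — are robust against
the details of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralResult", "mode_signals", "mode_filtered_spectrum",
           "signal_power_spectrum"]

MIN_FRAMES = 512


@dataclass
class SpectralResult:
    frequencies: np.ndarray     # ps⁻¹ (ordinary frequency), 0..Nyquist
    power: np.ndarray           # ≥ 0, same length
    peak_frequency: float       # ps⁻¹
    mode: str = ""


def _molecule_arrays(traj, topo):
    X = traj.positions()                     # (F, N, 3) unwrapped
    mols = topo.molecules()
    return X, mols


def mode_signals(traj, topo, mode: str) -> np.ndarray:
    """Scalar signals (n_signals, n_frames) for one motion class."""
    X, mols = _molecule_arrays(traj, topo)
    if mode == "trans":
        out = []
        for m in mols:
            w = topo.masses[m] / topo.masses[m].sum()
            com = np.einsum("fna,n->fa", X[:, m], w)
            out.append(com.T)                # 3 signals
        return np.concatenate(out, axis=0)
    if mode == "rot":
        out = []
        for m in mols:
            d = X[:, m[-1]] - X[:, m[0]]
            cos = d[:, 2] / np.linalg.norm(d, axis=1)
            out.append(cos[None, :])
        return np.concatenate(out, axis=0)
    if mode == "vib":
        out = []
        for m in mols:
            d = X[:, m[1]] - X[:, m[0]]
            out.append(np.linalg.norm(d, axis=1)[None, :])
        return np.concatenate(out, axis=0)
    raise ValueError(f"unknown mode {mode!r} (trans|rot|vib)")


def signal_power_spectrum(signals: np.ndarray, dt_fs: float,
                          second_derivative: bool = True):
    """Averaged Hann-windowed periodogram; returns (freq ps⁻¹, power)."""
    sig = np.atleast_2d(np.asarray(signals, float))
    if second_derivative:
        sig = (sig[:, 2:] - 2.0 * sig[:, 1:-1] + sig[:, :-2]) / dt_fs ** 2
    sig = sig - sig.mean(axis=1, keepdims=True)
    n = sig.shape[1]
    win = np.hanning(n)
    spec = np.fft.rfft(sig * win, axis=1)
    power = np.mean(np.abs(spec) ** 2, axis=0)
    freq = np.fft.rfftfreq(n, d=dt_fs) * 1e3      # fs⁻¹ -> ps⁻¹
    return freq, power


def _smooth(p, bins=5):
    if bins <= 1:
        return p
    kernel = np.ones(bins) / bins
    return np.convolve(p, kernel, mode="same")


def mode_filtered_spectrum(traj, topo, mode: str,
                           smooth_bins: int = 5,
                           min_frames: int = MIN_FRAMES) -> SpectralResult:
    """Power spectrum of one motion class with its peak frequency."""
    if traj.n_frames < min_frames:
        raise ValueError(
            f"need at least {min_frames} frames, got {traj.n_frames}")
    sig = mode_signals(traj, topo, mode)
    freq, power = signal_power_spectrum(sig, traj.sample_dt_fs)
    sm = _smooth(power, smooth_bins)
    k0 = max(1, smooth_bins // 2 + 1)             # skip DC edge bins
    peak = freq[k0 + int(np.argmax(sm[k0:len(sm) - k0]))]
    return SpectralResult(freq, power, float(peak), mode)
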