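"""Structural and transport observables: radial distribution function,
mean-squared displacement, and the Einstein-relation diffusion fit
⟨|R(t) − R(0)|²⟩ = 6 D t + intercept."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["rdf", "msd", "diffusion_fit", "DiffusionFit"]


def rdf(traj, topo=None, species_pair=None, r_max: float = None,
        n_bins: int = 100, atom_indices=None):
    """Ideal-gas-normalized pair distance histogram averaged over frames.

    ``species_pair`` like ("O", "O") restricts to one element pair;
    ``r_max`` defaults to just below half the smallest cell width.
    Returns (bin centers Å, g(r)).
    """
    h_all = traj.h
    widths = []
    for h in h_all:
        a = h.T
        vol = abs(np.linalg.det(h))
        cr = np.array([np.cross(a[1], a[2]), np.cross(a[2], a[0]),
                       np.cross(a[0], a[1])])
        widths.append(vol / np.linalg.norm(cr, axis=1))
    min_width = float(np.min(widths))
    if r_max is None:
        r_max = 0.49 * min_width
    if r_max >= 0.5 * min_width:
        raise ValueError("r_max must be below half the smallest cell width")

    if atom_indices is None:
        if species_pair is not None and topo is not None:
            ia = [i for i, e in enumerate(topo.elements) if e == species_pair[0]]
            ib = [i for i, e in enumerate(topo.elements) if e == species_pair[1]]
        else:
            n = traj.s.shape[1]
            ia = ib = list(range(n))
    else:
        ia = ib = list(atom_indices)
    same = ia == ib
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    vol_acc = 0.0
    F = traj.n_frames
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    for f in range(F):
        s = traj.s[f]
        h = traj.h[f]
        if same:
            iu, ju = np.triu_indices(len(ia), k=1)
            pi, pj = ia[iu], ia[ju]
        else:
            pi, pj = np.meshgrid(ia, ib, indexing="ij")
            pi, pj = pi.ravel(), pj.ravel()
        ds = s[pi] - s[pj]
        ds -= np.round(ds)
        r = np.linalg.norm(ds @ h.T, axis=1)
        counts += np.histogram(r, bins=edges)[0]
        vol_acc += abs(np.linalg.det(h))
    vol = vol_acc / F
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell = 4.0 * np.pi * centers ** 2 * np.diff(edges)
    if same:
        n_pairs = len(ia) * (len(ia) - 1) / 2.0
        rho_pairs = n_pairs / vol
    else:
        rho_pairs = len(ia) * len(ib) / vol
    g = counts / (F * shell * rho_pairs)
    return centers, g


def msd(traj, atom_indices=None):
    """Mean-squared displacement over all time lags (FFT algorithm),
    averaged over the selected atoms.  Returns (lag times fs, msd Å²)."""
    X = traj.positions()
    if atom_indices is not None:
        X = X[:, list(atom_indices)]
    F, N, _ = X.shape
    # standard FFT-based MSD: msd(k) = S1(k) - 2 S2(k)
    sq = np.einsum("fna,fna->fn", X, X)
    out = np.zeros(F)
    S2 = np.zeros((F, N))
    for a in range(3):
        x = X[:, :, a]
        fx = np.fft.rfft(x, n=2 * F, axis=0)
        acf = np.fft.irfft(fx * np.conj(fx), axis=0)[:F]
        S2 += acf.real
    norm = np.arange(F, 0, -1)[:, None]
    S2 /= norm
    # S1(k) = mean over t of |x(t+k)|² + |x(t)|², by downward recursion
    S1 = np.empty((F, N))
    Q = 2.0 * sq.sum(axis=0)
    for k in range(F):
        if k > 0:
            Q = Q - sq[k - 1] - sq[F - k]
        S1[k] = Q / (F - k)
    msd_per_atom = S1 - 2.0 * S2
    msd_t = msd_per_atom.mean(axis=1)
    msd_t[0] = 0.0
    lags = np.arange(F) * traj.sample_dt_fs
    return lags, msd_t


@dataclass
class DiffusionFit:
    D: float               # Å²/ps
    intercept: float       # Å²
    r_squared: float
    ballistic: bool        # True when MSD is closer to ∝t² than ∝t


def diffusion_fit(traj, atom_indices=None, fit_window=(0.05, 0.3)) -> DiffusionFit:
    """Least-squares fit of MSD = 6 D t + intercept over a lag window
    given as fractions of the trajectory length (the default keeps to the
    early diffusive regime, where the MSD estimator variance is small).
    D in Å²/ps."""
    lags_fs, m = msd(traj, atom_indices)
    F = len(lags_fs)
    lo, hi = int(F * fit_window[0]), max(int(F * fit_window[1]), int(F * fit_window[0]) + 2)
    t_ps = lags_fs[lo:hi] * 1e-3
    y = m[lo:hi]
    A = np.vstack([6.0 * t_ps, np.ones_like(t_ps)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    D, b = float(coef[0]), float(coef[1])
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2)) or 1.0
    r2 = 1.0 - ss_res / ss_tot
    # ballistic diagnostic: compare linear vs quadratic single-term fits
    with np.errstate(divide="ignore", invalid="ignore"):
        mask = (t_ps > 0) & (y > 0)
        slope = (np.polyfit(np.log(t_ps[mask]), np.log(y[mask]), 1)[0]
                 if mask.sum() > 3 else 1.0)
    return DiffusionFit(D, b, r2, bool(slope > 1.6))
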