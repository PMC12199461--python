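"""Maximum-stable-time-step scan.

"Stable" means bounded: the run completes a long horizon with all implicit
solvers converging, no numerical overflow, and no secular growth of the
conserved quantity.  A second-order symplectic integrator carries a
bounded shadow-Hamiltonian oscillation whose amplitude grows as Δt² (and
faster close to the stability edge); that short-term error band is not an
instability, and its slow beating means simple peak-to-peak bands keep
growing with the observation window even for perfectly stable runs.  The
criterion therefore tests stationarity directly: the median of the
conserved quantity over the second half of the run must not shift from
the first-half median by more than a tolerance (default 1 meV/atom).
Drifts, energy jumps and blow-ups move the median; a bounded oscillation
of any amplitude does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..integrator import ConvergenceError, StabilityError

__all__ = ["ScanResult", "conserved_band", "max_stable_dt"]


def conserved_band(conserved: np.ndarray, skip_frac: float = 0.0) -> float:
    """Peak-to-peak excursion of the conserved quantity (eV)."""
    E = np.asarray(conserved, float)
    E = E[int(len(E) * skip_frac):]
    return float(E.max() - E.min())


@dataclass
class ScanResult:
    max_stable_dt_fs: float          # 0.0 if nothing on the grid is stable
    details: dict = field(default_factory=dict)   # dt -> record


def max_stable_dt(run_fn, dt_grid, horizon_steps: int, n_atoms: int,
                  tol_mev_per_atom: float = 1.0) -> ScanResult:
    """Scan an ascending time-step grid for the largest stable step.

    ``run_fn(dt_fs, n_steps, abort_band)`` must run the system and return a
    trajectory (raising :class:`StabilityError` or
    :class:`ConvergenceError` on failure); failures are data, not errors.
    The abort band passed to ``run_fn`` is a generous overflow guard, not
    the stability criterion itself.
    """
    dt_grid = list(dt_grid)
    if any(b <= a for a, b in zip(dt_grid, dt_grid[1:])):
        raise ValueError("dt_grid must be strictly ascending")
    tol_ev = tol_mev_per_atom * 1e-3 * n_atoms
    details = {}
    best = 0.0
    for dt in dt_grid:
        try:
            traj = run_fn(dt, horizon_steps, 200.0 * tol_ev)
            E = traj.conserved
            half = len(E) // 2
            shift = abs(float(np.median(E[half:]) - np.median(E[:half])))
            band = conserved_band(E)
            stable = shift <= tol_ev
            details[dt] = dict(status="completed", band_ev=band,
                               median_shift_ev=shift, allowed_ev=tol_ev,
                               stable=stable)
        except (StabilityError, ConvergenceError, FloatingPointError) as exc:
            details[dt] = dict(status=f"failed: {exc}", band_ev=np.inf,
                               median_shift_ev=np.inf, allowed_ev=tol_ev,
                               stable=False)
            stable = False
        if stable:
            best = dt
    return ScanResult(best, details)
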