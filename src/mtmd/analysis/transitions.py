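"""Polymorph transition detection from molecular axis angles.

The order parameter is the angle between the main axes of two molecules,
each axis defined by the centroids of two atom groups.  A transition event
is an upward crossing of the rolling-average angle above a threshold
(default 80° over a 100-step window).  Events are excluded when the
molecule is internally kinked (angle between two intramolecular group axes
above 30°) or when a user-supplied cell-shape predicate rejects the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MoleculeAxesSpec", "TransitionReport", "transition_detector",
           "axis_angle_series"]


@dataclass
class MoleculeAxesSpec:
    """Atom-group definition of one molecule's axes.

    ``main = (group_a, group_b)``: the main axis runs between the two group
    centroids.  ``kink``: optionally two such axis definitions whose mutual
    angle measures the intramolecular kink.
    """
    main: tuple
    kink: tuple | None = None


@dataclass
class TransitionReport:
    events: list = field(default_factory=list)     # (frame, angle_deg)
    excluded: list = field(default_factory=list)   # (frame, angle_deg, reason)


def _centroid_axis(X, groups):
    a, b = groups
    return X[:, list(b)].mean(axis=1) - X[:, list(a)].mean(axis=1)


def _undirected_angle_deg(u, v):
    cos = np.abs(np.einsum("fa,fa->f", u, v)
                 / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)))
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def axis_angle_series(traj, spec_a: MoleculeAxesSpec, spec_b: MoleculeAxesSpec):
    """Per-frame intermolecular angle (deg) and per-molecule kink angles."""
    X = traj.positions()
    ua = _centroid_axis(X, spec_a.main)
    ub = _centroid_axis(X, spec_b.main)
    angle = _undirected_angle_deg(ua, ub)
    kinks = []
    for spec in (spec_a, spec_b):
        if spec.kink is not None:
            k1 = _centroid_axis(X, spec.kink[0])
            k2 = _centroid_axis(X, spec.kink[1])
            kinks.append(_undirected_angle_deg(k1, k2))
    kink = np.max(kinks, axis=0) if kinks else np.zeros(len(angle))
    return angle, kink


def _rolling_mean(x, window):
    if window <= 1:
        return x.copy()
    out = np.full_like(x, np.nan)
    c = np.concatenate([[0.0], np.cumsum(x)])
    out[window - 1:] = (c[window:] - c[:-window]) / window
    out[:window - 1] = out[window - 1] if len(x) >= window else np.nan
    return out


def transition_detector(traj, spec_a: MoleculeAxesSpec,
                        spec_b: MoleculeAxesSpec, window: int = 100,
                        angle_thresh: float = 80.0,
                        kink_thresh: float = 30.0,
                        cell_predicate=None) -> TransitionReport:
    """Detect transition events in the intermolecular-angle order parameter.

    ``cell_predicate(h) -> bool`` may reject frames whose cell shape does
    not match the target polymorph; rejected crossings are listed under
    ``excluded``.
    """
    angle, kink = axis_angle_series(traj, spec_a, spec_b)
    roll = _rolling_mean(angle, window)
    kroll = _rolling_mean(kink, window)
    report = TransitionReport()
    above = roll > angle_thresh
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    for f in crossings:
        if kroll[f] > kink_thresh:
            report.excluded.append((int(f), float(roll[f]), "kink"))
        elif cell_predicate is not None and not cell_predicate(traj.h[f]):
            report.excluded.append((int(f), float(roll[f]),
                                    "cell-shape mismatch"))
        else:
            report.events.append((int(f), float(roll[f])))
    return report
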