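"""Extended-XYZ trajectory I/O.

Frames are stored with wrapped Cartesian positions plus integer periodic
image counters (so unwrapped coordinates are recovered exactly for
diffusion analysis), scaled momenta, and per-frame scalars (time,
conserved quantity, determinant-constraint factor c, instantaneous
temperature).  Values are written with 17 significant digits so that a
write/read round trip is lossless to double precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Frame", "read_extxyz", "write_extxyz", "ParseError",
           "trajectory_to_frames", "frames_to_trajectory"]


class ParseError(ValueError):
    def __init__(self, msg, line=None):
        super().__init__(f"line {line}: {msg}" if line else msg)
        self.line = line


@dataclass
class Frame:
    elements: list
    positions: np.ndarray          # (N, 3) wrapped Cartesian, Å
    cell: np.ndarray               # (3, 3), columns = lattice vectors
    momenta: np.ndarray = None     # (N, 3) scaled momenta p_s
    images: np.ndarray = None      # (N, 3) int periodic image counters
    info: dict = field(default_factory=dict)

    def scaled_unwrapped(self) -> np.ndarray:
        s = self.positions @ np.linalg.inv(self.cell).T
        if self.images is not None:
            s = s + self.images
        return s


_FMT = "%.17g"


def _fmt_info_value(v):
    if isinstance(v, bool):
        return "T" if v else "F"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return _FMT % v
    if isinstance(v, np.ndarray):
        return '"' + " ".join(_FMT % x for x in v.reshape(-1)) + '"'
    s = str(v)
    return f'"{s}"' if (" " in s or "=" in s) else s


def write_extxyz(frames, path):
    """Write frames (a single Frame or an iterable) to ``path``."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            n = len(fr.elements)
            cols = ["species:S:1", "pos:R:3"]
            if fr.momenta is not None:
                cols.append("ps:R:3")
            if fr.images is not None:
                cols.append("image:I:3")
            # cell written row-major over lattice vectors (h columns)
            lat = " ".join(_FMT % x for x in fr.cell.T.reshape(-1))
            head = [f'Lattice="{lat}"', "Properties=" + ":".join(cols)]
            for k, v in fr.info.items():
                head.append(f"{k}={_fmt_info_value(v)}")
            fh.write(f"{n}\n{' '.join(head)}\n")
            for i in range(n):
                parts = [f"{fr.elements[i]:<2s}"]
                parts += [_FMT % x for x in fr.positions[i]]
                if fr.momenta is not None:
                    parts += [_FMT % x for x in fr.momenta[i]]
                if fr.images is not None:
                    parts += [str(int(x)) for x in fr.images[i]]
                fh.write(" ".join(parts) + "\n")


_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_info(line, lineno):
    out = {}
    for m in _KV_RE.finditer(line):
        key = m.group(1)
        raw = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = raw
    return out


def read_extxyz(path):
    """Read all frames from an extended-XYZ file."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}",
                             line=i + 1)
        if i + 1 >= len(lines):
            raise ParseError("missing comment line", line=i + 2)
        info = _parse_info(lines[i + 1], i + 2)
        if "Lattice" not in info:
            raise ParseError("missing Lattice field", line=i + 2)
        lat = np.array([float(x) for x in info.pop("Lattice").split()])
        if lat.size != 9:
            raise ParseError("Lattice must have 9 entries", line=i + 2)
        cell = lat.reshape(3, 3).T          # back to columns = vectors
        props = info.pop("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        layout = [(fields[k], fields[k + 1], int(fields[k + 2]))
                  for k in range(0, len(fields), 3)]
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise ParseError(f"expected {n} atom lines", line=i + 1)
        elements, pos, mom, img = [], [], [], []
        for j, ln in enumerate(body):
            toks = ln.split()
            want = sum(w for _, _, w in layout)
            if len(toks) != want:
                raise ParseError(
                    f"expected {want} columns, got {len(toks)}",
                    line=i + 3 + j)
            k = 0
            for name, _, width in layout:
                vals = toks[k:k + width]
                k += width
                if name == "species":
                    elements.append(vals[0])
                elif name == "pos":
                    pos.append([float(x) for x in vals])
                elif name == "ps":
                    mom.append([float(x) for x in vals])
                elif name == "image":
                    img.append([int(x) for x in vals])
        scalars = {}
        for key, raw in info.items():
            try:
                scalars[key] = float(raw)
            except ValueError:
                scalars[key] = raw
        frames.append(Frame(
            elements, np.array(pos), cell,
            np.array(mom) if mom else None,
            np.array(img, dtype=int) if img else None, scalars))
        i += 2 + n
    return frames


def trajectory_to_frames(traj) -> list:
    """Convert a :class:`mtmd.integrator.Trajectory` to storable frames."""
    frames = []
    for f in range(traj.n_frames):
        s = traj.s[f]
        img = np.floor(s).astype(int)
        sw = s - img
        h = traj.h[f]
        frames.append(Frame(
            list(traj.topo.elements), sw @ h.T, h, traj.ps[f], img,
            dict(time_fs=traj.t_fs[f], conserved=traj.conserved[f],
                 c_factor=traj.c_factor[f],
                 temperature=traj.temperature[f],
                 det_h=float(np.linalg.det(h)))))
    return frames


def frames_to_trajectory(frames, topo, TrajectoryCls=None):
    """Rebuild an in-memory trajectory (unwrapped) from stored frames."""
    from .integrator import Trajectory
    t = np.array([fr.info.get("time_fs", i) for i, fr in enumerate(frames)])
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    return Trajectory(
        topo, sample_dt_fs=dt,
        s=np.array([fr.scaled_unwrapped() for fr in frames]),
        h=np.array([fr.cell for fr in frames]),
        ps=np.array([fr.momenta if fr.momenta is not None
                     else np.zeros_like(fr.positions) for fr in frames]),
        t_fs=t,
        conserved=np.array([fr.info.get("conserved", np.nan) for fr in frames]),
        c_factor=np.array([fr.info.get("c_factor", 1.0) for fr in frames]),
        temperature=np.array([fr.info.get("temperature", np.nan)
                              for fr in frames]))
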