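"""Run configuration: a single YAML file with sections for the system,
force field, mass model, integrator, ensemble and I/O.

All physical quantities carry the units stated below; pressure is given in
GPa and converted to internal units (eV/Å³) at parse time.

Example::

    system:     {kind: n2_liquid, n_molecules: 64}
    forcefield: {kind: n2, cutoff: 7.0}          # Å
    mass_model: {kind: diatomic, m_trans: 14.007, m_rot: 56.028,
                 m_vib: 1400.7}                  # u
    integrator: {dt_fs: 4.0, W: 20.0}            # fs, u
    ensemble:   {temperature: 180.0, pressure_gpa: 0.0001,
                 uniform_scaling: true}          # K, GPa
    io:         {seed: 1, stride: 2}
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .forcefield import (N2ForceField, N2Params, ToyPolyForceField,
                         ToyPolyParams)
from .integrator import IntegratorConfig
from .massmatrix import (ConstantMassModel, DiatomicMassModel,
                         InternalHessianMassModel)
from .topology import ATOMIC_MASSES

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    system: dict
    forcefield: dict
    mass_model: dict
    integrator: IntegratorConfig
    ensemble: dict
    io: dict = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return int(self.io.get("seed", 0))

    @property
    def stride(self) -> int:
        return int(self.io.get("stride", 1))


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing required key {key!r} in section {where!r}")
    return section[key]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for sec in ("system", "forcefield", "mass_model"):
        if sec not in raw:
            raise ConfigError(f"missing required section {sec!r}")
    ens = raw.get("ensemble", {})
    integ = raw.get("integrator", {})
    try:
        icfg = IntegratorConfig(
            dt_fs=float(integ.get("dt_fs", 1.0)),
            W=float(integ.get("W", 20.0)),
            pressure_gpa=float(ens.get("pressure_gpa", 0.0001)),
            uniform_scaling=bool(ens.get("uniform_scaling", True)),
            fix_cell=bool(ens.get("fix_cell", False)),
            fp_tol=float(integ.get("fp_tol", 1e-12)),
            fp_max_iter=int(integ.get("fp_max_iter", 30)),
            newton_tol=float(integ.get("newton_tol", 1e-12)),
            newton_max_iter=int(integ.get("newton_max_iter", 10)),
            seed=int(raw.get("io", {}).get("seed", 0)))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid integrator/ensemble value: {exc}") from exc
    return RunConfig(raw["system"], raw["forcefield"], raw["mass_model"],
                     icfg, ens, raw.get("io", {}))


def build_forcefield(cfg: RunConfig, topo):
    sec = cfg.forcefield
    kind = _require(sec, "kind", "forcefield")
    if kind == "n2":
        params = N2Params(r0=float(sec.get("r0", 1.0977)),
                          Kr=float(sec.get("Kr", 138.331)),
                          eps=float(sec.get("eps", 0.003456)),
                          rm=float(sec.get("rm", 3.614)))
        return N2ForceField(topo, params, cutoff=float(sec.get("cutoff", 10.0)))
    if kind == "toy":
        params = ToyPolyParams(
            k_b=sec.get("k_b", 20.0), b0=sec.get("b0", 1.0),
            k_a=sec.get("k_a", 3.0), a0=sec.get("a0", 1.9),
            eps=float(sec.get("eps", 0.005)), rm=float(sec.get("rm", 3.2)),
            cutoff=float(sec.get("cutoff", 5.5)))
        return ToyPolyForceField(topo, params)
    raise ConfigError(f"unknown forcefield kind {kind!r}")


def build_mass_model(cfg: RunConfig, topo, X0=None, hessian=None):
    sec = cfg.mass_model
    kind = _require(sec, "kind", "mass_model")
    if kind == "constant":
        return ConstantMassModel.physical(topo)
    if kind == "repartitioned":
        return ConstantMassModel.repartitioned(topo)
    if kind == "diatomic":
        m = ATOMIC_MASSES.get(topo.elements[0], 1.0)
        return DiatomicMassModel(
            m_trans=float(sec.get("m_trans", m)),
            m_rot=float(sec.get("m_rot", m)),
            m_vib=float(sec.get("m_vib", m)))
    if kind == "internal_hessian":
        if X0 is None or hessian is None:
            raise ConfigError("internal_hessian mass model needs a reference "
                              "structure and Hessian")
        return InternalHessianMassModel(
            topo, X0, hessian, w=float(sec.get("w", 0.5)),
            base=sec.get("base", "repartitioned"),
            zero_offdiag=bool(sec.get("zero_offdiag", False)))
    raise ConfigError(f"unknown mass_model kind {kind!r}")
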