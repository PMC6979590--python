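"""TOML run configuration: mesh spec, material, boundary conditions, time
stepping and output control.

All physical quantities are SI: lengths m, stresses Pa, permeability
m^3 s/kg, times s.  Validation collects every offending key before raising,
so a config can be fixed in one pass.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .assembly import BoundaryConditions
from .constitutive import MaterialParams
from .mesh import Mesh, build_box_hex_mesh, build_cylinder_tet_mesh, tetrahedralize
from .solver import NewtonOptions

__all__ = ["RunConfig", "ConfigError", "load_config", "packaged_config_path"]


class ConfigError(ValueError):
    """Schema violations, reported all at once."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass
class RunConfig:
    """Validated simulation setup ready to hand to the time loop."""

    mesh: Mesh
    material: MaterialParams
    bcs: BoundaryConditions
    dt: float
    T: float
    newton: NewtonOptions
    output_dir: str = "out"
    output_every: int = 0  # 0 disables snapshots
    pressure_init: float = 0.0
    k0_cell: np.ndarray = None
    label: str = "run"


def packaged_config_path(name: str):
    """Path to a packaged benchmark config (``unconfined``, ``terzaghi``,
    ``swelling``), carrying the reference parameter-table values."""
    fname = name if name.endswith(".toml") else name + ".toml"
    return resources.files("porofem.configs") / fname


def _build_mesh(spec: dict, problems):
    gen = spec.get("generator")
    if gen == "box_hex":
        n = spec.get("n", [1, 1, 1])
        L = spec.get("lengths", [1.0, 1.0, 1.0])
        mesh = build_box_hex_mesh(*map(int, n), *map(float, L))
        if spec.get("tetrahedralize"):
            mesh = tetrahedralize(mesh, spec["tetrahedralize"])
        return mesh
    if gen == "cylinder_tet":
        return build_cylinder_tet_mesh(
            float(spec.get("radius", 1.0)),
            float(spec.get("height", 1.0)),
            int(spec.get("target_cells", 1000)),
        )
    if "file" in spec:
        from .io import read_mesh

        return read_mesh(spec["file"])
    problems.append(
        f"[mesh] needs generator 'box_hex'/'cylinder_tet' or a 'file' key, got {spec}"
    )
    return None


def _build_material(spec: dict, problems):
    kw = {k: float(spec[k]) for k in ("phi0", "k0", "rho_s", "rho_f") if k in spec}
    kw["upsilon"] = float(spec.get("upsilon", 0.0))
    try:
        if "E" in spec or "nu" in spec:
            missing = [k for k in ("E", "nu") if k not in spec]
            if missing:
                problems.append(f"[material] missing {missing} (E and nu go together)")
                return None
            return MaterialParams.from_young_poisson(
                float(spec["E"]), float(spec["nu"]), **kw
            )
        if "mu" in spec and "lambda" in spec:
            return MaterialParams(mu=float(spec["mu"]), lam=float(spec["lambda"]), **kw)
        problems.append("[material] needs either (E, nu) or (mu, lambda)")
    except (ValueError, ZeroDivisionError) as exc:
        problems.append(f"[material] {exc}")
    return None


def _build_bcs(spec: dict, problems) -> BoundaryConditions:
    bcs = BoundaryConditions()
    for tag, entry in (spec.get("dirichlet") or {}).items():
        try:
            mask = tuple(bool(b) for b in entry["components"])
            value = tuple(float(v) for v in entry.get("value", (0.0, 0.0, 0.0)))
            bcs.dirichlet[tag] = (mask, value)
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"[bc.dirichlet.{tag}] {exc!r}")
    for tag, entry in (spec.get("traction") or {}).items():
        if "normal" in entry:
            bcs.traction[tag] = float(entry["normal"])
        elif "vector" in entry:
            bcs.traction[tag] = np.asarray(entry["vector"], dtype=float)
        else:
            problems.append(f"[bc.traction.{tag}] needs 'normal' or 'vector'")
    for tag, entry in (spec.get("flux") or {}).items():
        bcs.flux[tag] = float(entry.get("q", 0.0))
    for tag, entry in (spec.get("pressure") or {}).items():
        bcs.pressure[tag] = float(entry.get("p", 0.0))
    return bcs


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Raises :class:`ConfigError` listing every invalid or missing key, or
    ``FileNotFoundError`` for a missing file.
    """
    path = Path(str(path))
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    problems: list[str] = []
    mesh = _build_mesh(raw.get("mesh", {}), problems)
    material = _build_material(raw.get("material", {}), problems)
    bcs = _build_bcs(raw.get("bc", {}), problems)
    time_spec = raw.get("time", {})
    dt = float(time_spec.get("dt", 0.0))
    T = float(time_spec.get("T", 0.0))
    if dt <= 0.0:
        problems.append("[time] dt must be positive")
    if T < dt:
        problems.append("[time] T must be at least dt")
    newton_spec = raw.get("newton", {})
    try:
        newton = NewtonOptions(
            residual_tol=float(newton_spec.get("residual_tol", 1e-8)),
            increment_tol=float(newton_spec.get("increment_tol", 1e-9)),
            max_iterations=int(newton_spec.get("max_iterations", 20)),
        )
    except ValueError as exc:
        problems.append(f"[newton] {exc}")
        newton = None
    if mesh is not None:
        try:
            bcs.validate(mesh)
        except ValueError as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError(problems)
    out = raw.get("output", {})
    return RunConfig(
        mesh=mesh,
        material=material,
        bcs=bcs,
        dt=dt,
        T=T,
        newton=newton,
        output_dir=str(out.get("dir", "out")),
        output_every=int(out.get("every", 0)),
        pressure_init=float(raw.get("initial", {}).get("pressure", 0.0)),
        label=str(raw.get("label", path.stem)),
    )
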