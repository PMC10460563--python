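"""Part placement, bracketed totals, mass conversion, and the model report.

Volumes and areas of the two main-body models (low and high superelliptical
exponent) and of every fin are measured independently and summed; where a
placed fin overlaps the body, the overlap is counted twice (no Boolean
union), which is usually negligible relative to body volume.  Total volume
is converted to mass at two densities: seawater (1.027 g/cm^3, neutral
buoyancy near the surface) and a user-adjustable density defaulting to
fresh-water 1.000 g/cm^3.

Fin placement (roll about z, then pitch about x, then yaw about y, then
translation) exists for assembling a visualization model only; measurement
always uses the unplaced part meshes, and rigid motion preserves volume and
area regardless.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import NotWatertight
from .fin_mesher import PartSpec
from .mesh_ops import TriMesh, UnitScale, mesh_area, mesh_volume, to_si

GRAMS_PER_CM3_TO_KG_PER_M3 = 1000.0


@dataclass
class DensityConfig:
    """Mean body densities in g/cm^3 used for mass conversion."""

    rho_seawater: float = 1.027
    rho_user: float = 1.000

    def __post_init__(self) -> None:
        if self.rho_seawater <= 0 or self.rho_user <= 0:
            raise ValueError("densities must be positive")


@dataclass
class ModelReport:
    """Bracketed volumes, areas, and masses of one model run.

    ``body``, ``totals`` and ``masses_kg`` are keyed ``"low"`` / ``"high"``
    for the two exponents; fins carry no exponent and are shared between the
    brackets.  Total volume is body + sum of parts with overlap
    double-counted.
    """

    n_low: float
    n_high: float
    body: dict
    parts: dict
    totals: dict
    masses_kg: dict
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path) -> Path:
        """Flat CSV: one row per part x exponent, plus totals and masses."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["component", "exponent", "volume_m3", "area_m2",
                        "density_g_cm3", "mass_kg"])
            for key, n in (("low", self.n_low), ("high", self.n_high)):
                w.writerow(["body", n, self.body[key]["volume_m3"],
                            self.body[key]["area_m2"], "", ""])
                for name, vals in self.parts.items():
                    w.writerow([name, n, vals["volume_m3"], vals["area_m2"],
                                "", ""])
                w.writerow(["total", n, self.totals[key]["volume_m3"],
                            self.totals[key]["area_m2"], "", ""])
                for rho_name, mass in self.masses_kg[key].items():
                    rho = self.metadata.get("densities_g_cm3", {}).get(
                        rho_name, "")
                    w.writerow(["mass", n, "", "", rho, mass])
        return path


def place_part(mesh: TriMesh, spec: PartSpec) -> TriMesh:
    """Rigidly place a part mesh in the body frame.

    Rotations are applied about the part's vertex centroid: roll about z
    first, then pitch about x, then yaw about y, followed by translation.
    Volume and area are unchanged.
    """
    rot = (Rotation.from_euler("y", spec.yaw, degrees=True)
           * Rotation.from_euler("x", spec.pitch, degrees=True)
           * Rotation.from_euler("z", spec.roll, degrees=True))
    pivot = mesh.vertices.mean(axis=0)
    verts = rot.apply(mesh.vertices - pivot) + pivot + np.asarray(
        spec.translation, dtype=float)
    return TriMesh(verts, mesh.faces.copy(), mesh.watertight)


def _measure(mesh: TriMesh, scale: UnitScale) -> dict:
    if not mesh.watertight:
        raise NotWatertight("summarize requires cleaned, watertight meshes")
    return {
        "volume_px3": mesh_volume(mesh),
        "area_px2": mesh_area(mesh),
        "volume_m3": to_si(mesh_volume(mesh), scale, 3),
        "area_m2": to_si(mesh_area(mesh), scale, 2),
    }


def summarize(body_low: TriMesh, body_high: TriMesh,
              parts: list[tuple[str, TriMesh]],
              scale: UnitScale, dens: DensityConfig | None = None,
              n_low: float = 2.0, n_high: float = 2.4,
              metadata: dict | None = None) -> ModelReport:
    """Measure all meshes and accumulate the bracketed model report.

    ``parts`` is a list of (name, cleaned mesh) pairs; part volumes are
    added to both brackets (fins carry no superelliptical exponent).
    Mass (kg) = total volume (m^3) x density (kg/m^3) for each configured
    density.
    """
    dens = dens or DensityConfig()
    body = {"low": _measure(body_low, scale),
            "high": _measure(body_high, scale)}
    part_vals = {name: _measure(m, scale) for name, m in parts}
    part_v = sum(v["volume_m3"] for v in part_vals.values())
    part_a = sum(v["area_m2"] for v in part_vals.values())
    totals, masses = {}, {}
    for key in ("low", "high"):
        totals[key] = {
            "volume_m3": body[key]["volume_m3"] + part_v,
            "area_m2": body[key]["area_m2"] + part_a,
        }
        masses[key] = {
            "seawater": totals[key]["volume_m3"]
            * dens.rho_seawater * GRAMS_PER_CM3_TO_KG_PER_M3,
            "user": totals[key]["volume_m3"]
            * dens.rho_user * GRAMS_PER_CM3_TO_KG_PER_M3,
        }
    meta = {
        "m_per_px": scale.m_per_px,
        "body_axis_m": scale.body_axis_m,
        "body_axis_px": scale.body_axis_px,
        "densities_g_cm3": {"seawater": dens.rho_seawater,
                            "user": dens.rho_user},
        "rotation_pivot": "part vertex centroid before translation",
        "overlap_handling": "double-counted (no Boolean union)",
    }
    meta.update(metadata or {})
    return ModelReport(n_low=n_low, n_high=n_high, body=body,
                       parts=part_vals, totals=totals, masses_kg=masses,
                       metadata=meta)
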