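"""Triangulated surfaces with per-face traction fields.

:class:`TriSurface` is the carrier for the displacement-force integral: a
triangle soup with optional per-face pressure (Pa) and per-face shear
traction vectors (Pa, tangent to the wall). Generators produce the idealized
geometries used for validation — straight tubes, circular-arc bends (torus
segments) and icospheres — with consistently outward-oriented faces.

Analytic field assignment covers the two oracles: a uniform pressure field
(zero net force on any closed surface, by the divergence theorem) and fully
developed Poiseuille flow in a straight tube (linear axial pressure drop
dP = 8*mu*L*Q/(pi*r^4), uniform wall shear tau_w = 4*mu*Q/(pi*r^3) directed
along the flow axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "TriSurface",
    "MeshError",
    "gen_tube_mesh",
    "gen_closed_sphere",
    "assign_uniform_pressure",
    "assign_poiseuille_fields",
]


class MeshError(ValueError):
    """Raised for invalid mesh geometry, topology or fields."""


@dataclass
class TriSurface:
    """Triangulated surface with optional per-face pressure/shear fields.

    ``vertices`` are metres; ``face_pressure`` is Pa per face;
    ``face_shear`` is a traction vector in Pa per face. Face normals follow
    the right-hand rule on the vertex ordering and are oriented outward
    (away from the lumen) by the generators.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_pressure: np.ndarray | None = None
    face_shear: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array of vertex indices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face indices out of range")
        if self.face_pressure is not None:
            self.face_pressure = np.asarray(self.face_pressure, dtype=float)
            if self.face_pressure.shape != (len(self.faces),):
                raise MeshError("face_pressure must have one value per face")
        if self.face_shear is not None:
            self.face_shear = np.asarray(self.face_shear, dtype=float)
            if self.face_shear.shape != (len(self.faces), 3):
                raise MeshError("face_shear must have one 3-vector per face")

    # -- geometry -------------------------------------------------------

    def _face_cross(self) -> np.ndarray:
        v0, v1, v2 = (self.vertices[self.faces[:, k]] for k in range(3))
        return np.cross(v1 - v0, v2 - v0)

    @property
    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self._face_cross(), axis=1)

    @property
    def face_normals(self) -> np.ndarray:
        cross = self._face_cross()
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise MeshError("degenerate zero-area face")
        return cross / norms

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def total_area(self) -> float:
        """Total surface area, m^2."""
        return float(self.face_areas.sum())

    @property
    def signed_volume(self) -> float:
        """Signed enclosed volume (positive for closed, outward-oriented)."""
        v0, v1, v2 = (self.vertices[self.faces[:, k]] for k in range(3))
        return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)

    def is_consistently_oriented(self) -> bool:
        """True when every shared edge is traversed once in each direction."""
        seen: dict[tuple[int, int], int] = {}
        count: dict[tuple[int, int], int] = {}
        for tri in self.faces:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key, direction = ((int(a), int(b)), 1) if a < b else ((int(b), int(a)), -1)
                seen[key] = seen.get(key, 0) + direction
                count[key] = count.get(key, 0) + 1
        # boundary edges appear once; interior edges twice with opposite signs
        return all(c <= 2 for c in count.values()) and all(
            s == 0 if count[e] == 2 else abs(s) == 1 for e, s in seen.items()
        )

    def validate(self, closed: bool = False) -> None:
        """Raise :class:`MeshError` on invalid areas, orientation or volume."""
        if np.any(self.face_areas <= 0):
            raise MeshError("all face areas must be positive")
        if not self.is_consistently_oriented():
            raise MeshError("faces are not consistently oriented")
        if closed and self.signed_volume <= 0:
            raise MeshError("closed surface must have positive signed volume")

    def with_fields(self, pressure: np.ndarray, shear: np.ndarray) -> "TriSurface":
        return TriSurface(self.vertices, self.faces, pressure, shear, dict(self.metadata))


def _triangulate_grid(nu: int, nv: int, wrap_v: bool) -> np.ndarray:
    """Triangles over a (nu x nv) vertex grid, optionally wrapping in v."""
    faces = []
    nv_eff = nv if wrap_v else nv - 1
    for i in range(nu - 1):
        for j in range(nv_eff):
            j1 = (j + 1) % nv
            a = i * nv + j
            b = i * nv + j1
            c = (i + 1) * nv + j
            d = (i + 1) * nv + j1
            faces.append((a, b, d))
            faces.append((a, d, c))
    return np.asarray(faces, dtype=np.int64)


def gen_tube_mesh(
    radius: float,
    length_or_angle: float,
    kind: str = "straight",
    n_circumferential: int = 64,
    n_axial: int = 64,
    bend_radius: float | None = None,
) -> TriSurface:
    """Lateral surface of a straight tube or a circular-arc bend.

    ``kind="straight"`` builds a cylinder of length ``length_or_angle`` (m)
    along +z starting at z=0. ``kind="bend"`` builds a torus segment swept
    through ``length_or_angle`` degrees in the x-y plane with centreline
    radius ``bend_radius``. Normals point away from the centreline (outward
    from the lumen); end caps are not meshed.
    """
    if radius <= 0:
        raise MeshError(f"radius must be positive, got {radius}")
    if n_circumferential < 8 or n_axial < 8:
        raise MeshError("resolution floor is 8 x 8")

    theta = np.linspace(0.0, 2.0 * np.pi, n_circumferential, endpoint=False)
    if kind == "straight":
        length = float(length_or_angle)
        if length <= 0:
            raise MeshError(f"length must be positive, got {length}")
        z = np.linspace(0.0, length, n_axial + 1)
        ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        verts = np.concatenate(
            [np.column_stack([ring, np.full(len(theta), zi)]) for zi in z]
        )
        faces = _triangulate_grid(n_axial + 1, n_circumferential, wrap_v=True)
        mesh = TriSurface(
            verts,
            faces,
            metadata={"kind": "straight", "radius": radius, "length": length,
                      "axis": (0.0, 0.0, 1.0), "origin": (0.0, 0.0, 0.0)},
        )
    elif kind == "bend":
        if bend_radius is None or bend_radius <= radius:
            raise MeshError("bend requires bend_radius > tube radius")
        angle = math.radians(float(length_or_angle))
        if angle <= 0:
            raise MeshError("bend angle must be positive")
        u = np.linspace(0.0, angle, n_axial + 1)
        verts = []
        for ui in u:
            rad_dir = np.array([math.cos(ui), math.sin(ui), 0.0])
            centre = bend_radius * rad_dir
            for th in theta:
                # local outward direction: radial in-plane + vertical
                offset = radius * (math.cos(th) * rad_dir + math.sin(th) * np.array([0.0, 0.0, 1.0]))
                verts.append(centre + offset)
        verts = np.asarray(verts)
        faces = _triangulate_grid(n_axial + 1, n_circumferential, wrap_v=True)
        mesh = TriSurface(
            verts,
            faces,
            metadata={"kind": "bend", "radius": radius, "bend_radius": bend_radius,
                      "angle_deg": float(length_or_angle)},
        )
    else:
        raise MeshError(f"unknown tube kind {kind!r}")

    # orient all faces outward (away from the centreline)
    mesh = _orient_outward(mesh)
    return mesh


def _orient_outward(mesh: TriSurface) -> TriSurface:
    """Flip faces whose normal points toward the tube centreline."""
    centroids = mesh.face_centroids
    kind = mesh.metadata.get("kind")
    if kind == "straight":
        outward = centroids - np.array([0.0, 0.0, 1.0]) * centroids[:, 2:3]
    elif kind == "bend":
        bend_r = mesh.metadata["bend_radius"]
        inplane = centroids.copy()
        inplane[:, 2] = 0.0
        norms = np.linalg.norm(inplane, axis=1, keepdims=True)
        centreline = bend_r * inplane / norms
        centreline[:, 2] = 0.0
        outward = centroids - centreline
    else:
        return mesh
    flip = np.einsum("ij,ij->i", mesh.face_normals, outward) < 0
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriSurface(mesh.vertices, faces, mesh.face_pressure, mesh.face_shear, mesh.metadata)


def gen_closed_sphere(radius: float, refinement: int = 3) -> TriSurface:
    """Watertight icosphere with outward normals (oracle geometry)."""
    if radius <= 0:
        raise MeshError(f"radius must be positive, got {radius}")
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
    mesh = TriSurface(np.asarray(ico.vertices), np.asarray(ico.faces),
                      metadata={"kind": "sphere", "radius": radius})
    if mesh.signed_volume < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


def assign_uniform_pressure(mesh: TriSurface, p: float) -> TriSurface:
    """Constant pressure field, zero shear, on every face."""
    if not np.isfinite(p):
        raise MeshError(f"pressure must be finite, got {p}")
    n = len(mesh.faces)
    return mesh.with_fields(np.full(n, float(p)), np.zeros((n, 3)))


def assign_poiseuille_fields(
    mesh: TriSurface, Q: float, mu: float, inlet_pressure: float
) -> TriSurface:
    """Fully developed laminar tube-flow tractions on a straight tube.

    Pressure falls linearly along the axis with total drop
    ``8*mu*L*Q/(pi*r^4)``; wall shear has uniform magnitude
    ``4*mu*Q/(pi*r^3)`` directed along the flow axis (tangent to the wall).
    """
    if mesh.metadata.get("kind") != "straight":
        raise MeshError("Poiseuille fields require a straight tube mesh")
    r = mesh.metadata["radius"]
    length = mesh.metadata["length"]
    grad = 8.0 * mu * Q / (math.pi * r**4)  # Pa per metre
    tau_w = 4.0 * mu * Q / (math.pi * r**3)
    z = mesh.face_centroids[:, 2]
    pressure = inlet_pressure - grad * z
    axis = np.asarray(mesh.metadata["axis"], dtype=float)
    shear = np.tile(tau_w * axis, (len(mesh.faces), 1))
    out = mesh.with_fields(pressure, shear)
    out.metadata.update({"poiseuille_dp": grad * length, "poiseuille_tau_w": tau_w})
    return out
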