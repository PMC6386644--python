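"""Displacement force on a stent graft: the surface traction integral.

The net hemodynamic load that tends to migrate a stent graft is the sum of
the pressure and wall-shear-stress tractions over the graft's wetted
surface, evaluated at the systolic peak:

    DF = sum_faces [ p_f * n_f * A_f  +  tau_f * A_f ]

with n_f the unit normal pointing outward from the lumen (blood pushes the
wall outward) and A_f the face area. Fields are piecewise constant per
face, so mesh refinement — not quadrature order — controls accuracy.

The anatomical frame follows +z cranial, +x ventral (anterior), +y
patient-left; a force with negative x and positive z is directed
dorsocranial, the orientation reported for arch stent grafts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .meshes import MeshError, TriSurface
from .windkessel import PressureTrace

__all__ = [
    "ForceVector",
    "FieldError",
    "UndefinedDirectionError",
    "integrate_force",
    "systolic_peak_time",
    "classify_direction",
    "graft_surface_area",
]

#: angular margin (degrees) inside which a direction call is flagged as a
#: boundary case between octants
BOUNDARY_MARGIN_DEG = 5.0


class FieldError(ValueError):
    """Raised when a mesh lacks the traction fields the integral needs."""


class UndefinedDirectionError(ValueError):
    """Raised when asked for the direction of a zero force vector."""


@dataclass(frozen=True)
class ForceVector:
    """Integrated traction load in Newtons, anatomical frame.

    ``components = pressure_part + shear_part`` exactly; ``magnitude`` is
    the Euclidean norm of ``components``.
    """

    pressure_part: np.ndarray
    shear_part: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pressure_part", np.asarray(self.pressure_part, dtype=float))
        object.__setattr__(self, "shear_part", np.asarray(self.shear_part, dtype=float))
        if self.pressure_part.shape != (3,) or self.shear_part.shape != (3,):
            raise ValueError("force parts must be 3-vectors")

    @property
    def components(self) -> np.ndarray:
        return self.pressure_part + self.shear_part

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.components))


def integrate_force(mesh: TriSurface) -> ForceVector:
    """Integrate pressure and shear tractions over the graft surface.

    Returns the load exerted by the blood on the graft, with the pressure
    and viscous contributions reported separately.
    """
    if mesh.face_pressure is None or mesh.face_shear is None:
        raise FieldError("mesh must carry face_pressure and face_shear fields")
    areas = mesh.face_areas
    if np.any(areas <= 0):
        raise MeshError("zero-area face in mesh")
    normals = mesh.face_normals
    pressure_part = (mesh.face_pressure[:, None] * normals * areas[:, None]).sum(axis=0)
    shear_part = (mesh.face_shear * areas[:, None]).sum(axis=0)
    return ForceVector(pressure_part, shear_part)


def systolic_peak_time(trace: PressureTrace) -> float:
    """Instant of maximum pressure within the last cycle, ties to earliest."""
    if len(trace.times) == 0:
        raise ValueError("empty pressure trace")
    sl = trace.cycle_slice(trace.n_cycles - 1) if trace.n_cycles >= 1 else slice(None)
    pressures = trace.pressures[sl]
    times = trace.times[sl]
    return float(times[int(np.argmax(pressures))])


def classify_direction(f: ForceVector) -> tuple[str, bool]:
    """Anatomical label of a force vector from its (x, z) signs.

    Returns ``(label, boundary)`` where label is one of ``dorsocranial``,
    ``ventrocranial``, ``dorsocaudal``, ``ventrocaudal`` and ``boundary``
    flags vectors lying within 5 degrees of either separating plane.
    """
    v = f.components
    if f.magnitude == 0.0:
        raise UndefinedDirectionError("zero force vector has no direction")
    x, _, z = v
    sagittal = "dorso" if x < 0 else "ventro"
    axial = "cranial" if z > 0 else "caudal"
    label = sagittal + axial
    norm = f.magnitude
    margin = math.sin(math.radians(BOUNDARY_MARGIN_DEG))
    boundary = bool(abs(x) <= margin * norm or abs(z) <= margin * norm)
    return label, boundary


def graft_surface_area(mesh: TriSurface) -> float:
    """Total surface area in cm^2 (0 with a warning for an empty mesh)."""
    if len(mesh.faces) == 0:
        warnings.warn("empty mesh has zero surface area", stacklevel=2)
        return 0.0
    return mesh.total_area * units.M2_TO_CM2
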