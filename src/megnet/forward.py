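"""Forward model: magnetic lead fields in a spherical conductor.

The field of a current dipole inside a spherically symmetric volume
conductor has a closed form (the Sarvas solution).  Volume currents
contribute no radial field outside the sphere, so the external field
depends only on the dipole's tangential component — a dipole oriented
radially is magnetically silent.  The closed form makes the beamformer
chain testable against exact analytic properties (linearity, rotation
equivariance, radial silence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import HeadModel, SensorArray, SourceGrid

__all__ = ["LeadField", "sarvas_field", "compute_leadfield"]

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass(frozen=True)
class LeadField:
    """Sensor gains for unit dipoles at every grid node.

    ``matrix`` has shape (n_sensors, 3 * n_nodes): three columns per node
    give the measured field (tesla) for unit dipole moments (1 A·m) along
    x, y, z.  ``degenerate_nodes`` lists nodes whose gain had to be zeroed
    (dipole at the sphere centre, where every orientation is silent).
    """

    matrix: np.ndarray
    n_nodes: int
    degenerate_nodes: tuple[int, ...] = ()

    def node_gain(self, node: int) -> np.ndarray:
        """(n_sensors, 3) gain block for one node."""
        return self.matrix[:, 3 * node : 3 * node + 3]


def sarvas_field(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    sensor_pos: np.ndarray,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a conducting sphere.

    Parameters
    ----------
    dipole_pos : (3,)
        Dipole location in metres (inside the sphere).
    dipole_moment : (3,)
        Dipole moment in A·m.
    sensor_pos : (n, 3)
        Field points in metres (outside the sphere).
    center : (3,), optional
        Sphere centre; defaults to the origin.

    Returns
    -------
    (n, 3) array of field vectors.
    """
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    r0 = np.asarray(dipole_pos, dtype=float) - center
    q = np.asarray(dipole_moment, dtype=float)
    rv = np.atleast_2d(np.asarray(sensor_pos, dtype=float)) - center

    a_v = rv - r0                       # (n, 3)
    a = np.linalg.norm(a_v, axis=1)     # (n,)
    r = np.linalg.norm(rv, axis=1)      # (n,)
    ar = np.einsum("ij,ij->i", a_v, rv)
    r0r = rv @ r0

    F = a * (r * a + r**2 - r0r)
    gradF = ((a**2 / r + ar / a + 2 * a + 2 * r)[:, None] * rv
             - (a + 2 * r + ar / a)[:, None] * r0)
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - (rv @ qxr0)[:, None] * gradF)
    return B


def compute_leadfield(
    grid: SourceGrid, sensors: SensorArray, head: HeadModel
) -> LeadField:
    """Lead-field matrix for all grid nodes against a magnetometer array.

    Each node contributes three columns (unit dipoles along x/y/z); the
    magnetometer reading is the field projected on the sensor's coil
    orientation.  A node coinciding with the sphere centre is silent for
    every orientation; its gain is zeroed and the node index recorded.
    """
    sensors.validate_outside(head)
    n_sens, n_nodes = sensors.count, grid.n_nodes
    G = np.zeros((n_sens, 3 * n_nodes))
    eye = np.eye(3)
    degenerate: list[int] = []
    for node in range(n_nodes):
        pos = grid.positions[node]
        if np.linalg.norm(pos - head.center) < 1e-12:
            degenerate.append(node)
            warnings.warn(
                f"source node {node} lies at the sphere centre (silent); gain set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        for k in range(3):
            B = sarvas_field(pos, eye[k], sensors.positions, center=head.center)
            G[:, 3 * node + k] = np.einsum("ij,ij->i", B, sensors.orientations)
    if not np.all(np.isfinite(G)):
        raise FloatingPointError("non-finite lead-field entries")
    return LeadField(matrix=G, n_nodes=n_nodes, degenerate_nodes=tuple(degenerate))
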