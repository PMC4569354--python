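"""Head model, sensor array and source-grid geometry.

The head is modelled as a single homogeneous conducting sphere.  Source
positions live on a regular cubic lattice aligned to the sphere centre and
only lattice points strictly inside the sphere are retained, standing in
for a grey-matter-masked template grid.  Sensors (magnetometers) sit on a
spherical cap outside the head with radially oriented pickup coils.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeadModel",
    "SensorArray",
    "SourceGrid",
    "build_source_grid",
    "make_sensor_cap",
]


@dataclass(frozen=True)
class HeadModel:
    """Spherical volume conductor.

    Parameters
    ----------
    center : (3,) array-like
        Sphere centre in metres, head-centred coordinates.
    radius : float
        Sphere radius in metres; must be positive.
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.09

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("head centre must be a 3-vector")
        if not self.radius > 0:
            raise ValueError(f"head radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class SensorArray:
    """Magnetometer positions and pickup-coil orientations.

    Positions are in metres (head-centred); orientations are unit vectors
    along which the magnetic field is measured.
    """

    positions: np.ndarray
    orientations: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ori = np.asarray(self.orientations, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("sensor positions must be (n, 3)")
        if ori.shape != pos.shape:
            raise ValueError("orientations must match positions in shape")
        if pos.shape[0] < 2:
            raise ValueError("need at least 2 sensors")
        norms = np.linalg.norm(ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must have unit norm")
        if len(self.names) != pos.shape[0]:
            raise ValueError("one name per sensor required")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    def validate_outside(self, head: HeadModel) -> None:
        d = np.linalg.norm(self.positions - head.center, axis=1)
        if np.any(d <= head.radius):
            raise ValueError("all sensors must lie outside the head sphere")


@dataclass(frozen=True)
class SourceGrid:
    """Regular-lattice source space restricted to the head interior.

    ``positions`` holds only the retained (inside) lattice points, ordered
    by ``node_index`` (a contiguous 0..n-1 relabelling of the retained
    points in lexicographic lattice order).
    """

    positions: np.ndarray
    spacing: float
    inside_mask: np.ndarray
    lattice_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "inside_mask", np.asarray(self.inside_mask, dtype=bool))

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def node_index(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def adjacency(self, radius_factor: float = 1.1) -> np.ndarray:
        """Boolean spatial-neighbour matrix.

        Nodes are neighbours when their distance is below
        ``radius_factor * spacing`` (6-connectivity on the lattice for the
        default 1.1 factor).
        """
        d = np.linalg.norm(self.positions[:, None, :] - self.positions[None, :, :], axis=2)
        adj = d < radius_factor * self.spacing
        np.fill_diagonal(adj, False)
        return adj


def build_source_grid(head: HeadModel, spacing: float) -> SourceGrid:
    """Regular 3D grid covering the head volume at the given resolution.

    The lattice is aligned so a lattice point falls on the sphere centre;
    points with ``||p - center|| < radius`` (strict) are retained.

    Raises
    ------
    ValueError
        If ``spacing <= 0`` or the resulting grid is empty.
    """
    if spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {spacing}")
    n_half = int(np.floor(head.radius / spacing))
    ticks = np.arange(-n_half, n_half + 1) * spacing
    xx, yy, zz = np.meshgrid(ticks, ticks, ticks, indexing="ij")
    lattice = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]) + head.center
    inside = np.linalg.norm(lattice - head.center, axis=1) < head.radius
    if not inside.any():
        raise ValueError(
            f"empty grid: spacing {spacing} m leaves no lattice point inside "
            f"a sphere of radius {head.radius} m"
        )
    shape = (len(ticks),) * 3
    return SourceGrid(
        positions=lattice[inside],
        spacing=float(spacing),
        inside_mask=inside,
        lattice_shape=shape,
    )


def _fibonacci_cap(n: int, cap_fraction: float) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper spherical cap.

    ``cap_fraction`` is the fraction of the full sphere's solid angle the
    cap subtends (0.5 = upper hemisphere helmet).
    """
    golden = (1 + 5**0.5) / 2
    k = np.arange(n)
    # z descends from the pole through the cap only
    z = 1 - (k + 0.5) / n * 2 * cap_fraction
    phi = 2 * np.pi * k / golden
    rho = np.sqrt(np.clip(1 - z**2, 0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_sensor_cap(
    head: HeadModel,
    n_sensors: int = 275,
    radius_factor: float = 1.2,
    cap_fraction: float = 0.55,
) -> SensorArray:
    """Helmet-like magnetometer array on a spherical cap.

    Sensors sit at ``radius_factor * head.radius`` from the centre with
    radial orientations, covering the upper portion of the sphere the way
    a whole-head MEG helmet does.
    """
    if n_sensors < 2:
        raise ValueError("need at least 2 sensors")
    unit = _fibonacci_cap(n_sensors, cap_fraction)
    positions = head.center + radius_factor * head.radius * unit
    names = tuple(f"MEG{i:04d}" for i in range(n_sensors))
    return SensorArray(positions=positions, orientations=unit, names=names)
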