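"""Left-ventricular surface geometry: point-set container and clinical indices.

The LV is represented as two corresponded surface point grids (endocardium and
epicardium) sampled on a regular circumferential x longitudinal lattice running
from the apex to the basal plane.  Cavity volume and myocardial mass are
computed by closing each triangulated surface and applying the divergence
theorem; these feed the traditional remodeling indices EDV, ESV, LV mass and
ejection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Myocardial tissue density, g/ml (standard literature value).
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

ED = "ED"
ES = "ES"
ENDO = "endo"
EPI = "epi"


@dataclass(frozen=True)
class SurfaceGrid:
    """Sampling lattice of one surface: points are ordered longitudinal-major
    (apex row first, basal row last), circumferential within each row."""

    n_circumferential: int = 37
    n_longitudinal: int = 37

    def __post_init__(self) -> None:
        if self.n_circumferential < 4 or self.n_longitudinal < 4:
            raise ValueError("grid counts must be >= 4")

    @property
    def points_per_surface(self) -> int:
        return self.n_circumferential * self.n_longitudinal

    @property
    def total_points(self) -> int:
        """Both surfaces together (endo block first, then epi)."""
        return 2 * self.points_per_surface


@dataclass
class SurfacePointSet:
    """Ordered, corresponded 3D sample of the endo+epi LV surfaces at one frame.

    ``points`` is ``(2 * n_long * n_circ, 3)`` in mm: the endocardial block
    first, then the epicardial block, each ordered (longitudinal, circumferential)
    with the apex row first.  This fixed ordering is the point correspondence
    that all shape statistics rely on.
    """

    points: np.ndarray
    grid: SurfaceGrid
    frame: str = ED

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.points.shape[0] != self.grid.total_points:
            raise ValueError(
                f"point count {self.points.shape[0]} does not match grid "
                f"({self.grid.total_points} = 2 x {self.grid.n_longitudinal}"
                f" x {self.grid.n_circumferential})"
            )
        if self.frame not in (ED, ES):
            raise ValueError(f"frame must be 'ED' or 'ES', got {self.frame!r}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def surface_labels(self) -> np.ndarray:
        half = self.grid.points_per_surface
        return np.array([ENDO] * half + [EPI] * half)

    def surface(self, which: str) -> np.ndarray:
        """Points of one surface as an (n_long, n_circ, 3) lattice."""
        half = self.grid.points_per_surface
        block = self.points[:half] if which == ENDO else self.points[half:]
        return block.reshape(self.grid.n_longitudinal, self.grid.n_circumferential, 3)

    def as_vector(self) -> np.ndarray:
        """Flat shape vector (3 * N,) in fixed point order."""
        return self.points.reshape(-1)


@dataclass(frozen=True)
class ClinicalIndices:
    """Traditional remodeling indices of one case."""

    edv_ml: float
    esv_ml: float
    mass_g: float

    @property
    def ejection_fraction(self) -> float:
        return (self.edv_ml - self.esv_ml) / self.edv_ml


def _triangles_of_grid(lattice: np.ndarray) -> np.ndarray:
    """Triangulate one surface lattice and close it at the apex and basal
    rings by fan triangulation to the ring centroids.

    Returns an (n_tri, 3, 3) array of vertex coordinates with consistent
    winding, forming a closed surface.  Degenerate rings (e.g. an apex row
    whose points coincide) simply yield zero-area triangles.
    """
    n_long, n_circ, _ = lattice.shape
    a = lattice[:-1, :, :]                     # row i
    b = lattice[1:, :, :]                      # row i+1
    a_next = np.roll(a, -1, axis=1)            # (i, j+1 mod n_circ)
    b_next = np.roll(b, -1, axis=1)
    # two triangles per quad
    t1 = np.stack([a, a_next, b], axis=2)
    t2 = np.stack([a_next, b_next, b], axis=2)
    quads = np.concatenate([t1, t2], axis=2).reshape(-1, 3, 3)

    def _fan(ring: np.ndarray, flip: bool) -> np.ndarray:
        centroid = ring.mean(axis=0)
        nxt = np.roll(ring, -1, axis=0)
        c = np.broadcast_to(centroid, ring.shape)
        tri = np.stack([ring, nxt, c], axis=1)
        if flip:
            tri = tri[:, ::-1, :]
        return tri

    apex_cap = _fan(lattice[0], flip=True)
    base_cap = _fan(lattice[-1], flip=False)
    return np.concatenate([quads, apex_cap, base_cap], axis=0)


def enclosed_volume_mm3(lattice: np.ndarray) -> float:
    """Signed-volume (divergence theorem) of the closed surface built from one
    lattice; returned as a positive volume in mm^3, independent of the global
    orientation of the winding."""
    tri = _triangles_of_grid(lattice)
    if not np.all(np.isfinite(tri)):
        bad = int(np.flatnonzero(~np.isfinite(tri).all(axis=(1, 2)))[0])
        raise ValueError(f"non-finite coordinates in surface triangle {bad}")
    signed = np.einsum("ti,ti->t", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    volume = abs(float(signed.sum()))
    if volume <= 0.0:
        raise ValueError("degenerate surface: enclosed volume is zero")
    return volume


def cavity_volume(s: SurfacePointSet) -> float:
    """LV cavity (blood-pool) volume in ml from the endocardial surface.

    The endocardial lattice is triangulated and closed at the basal ring by a
    centroid fan; the signed volume follows from the divergence theorem.
    """
    return enclosed_volume_mm3(s.surface(ENDO)) / 1000.0


def lv_mass(s: SurfacePointSet) -> float:
    """Myocardial mass in g: wall volume (epi minus endo enclosed volume)
    times tissue density."""
    v_epi = enclosed_volume_mm3(s.surface(EPI))
    v_endo = enclosed_volume_mm3(s.surface(ENDO))
    if v_epi <= v_endo:
        raise ValueError(
            f"inverted surfaces: epicardial volume {v_epi / 1000:.2f} ml <= "
            f"endocardial volume {v_endo / 1000:.2f} ml"
        )
    return (v_epi - v_endo) / 1000.0 * MYOCARDIAL_DENSITY_G_PER_ML


def clinical_indices(ed: SurfacePointSet, es: SurfacePointSet) -> ClinicalIndices:
    """EDV/ESV from the two frames' cavity volumes; mass from the ED frame."""
    if ed.frame != ED or es.frame != ES:
        raise ValueError("clinical_indices expects an (ED, ES) pair in that order")
    edv = cavity_volume(ed)
    esv = cavity_volume(es)
    return ClinicalIndices(edv_ml=edv, esv_ml=esv, mass_g=lv_mass(ed))
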