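"""Axisymmetric r-z discretization of the osteotomized bone and field transfer.

The modeled domain is one cortical-bone transport segment: two tubular
fragments (cortex wall with marrow inside) separated by the distraction gap,
which is filled by the callus annulus between the endosteal and periosteal
radii.  The mesh is a structured tensor grid of 4-node quadrilaterals in the
(r, z) plane with the symmetry axis at r = 0; the gap cells inside the marrow
radius are left empty (rectangular gap domain).

Because every distraction step stretches the callus, the callus is rebuilt at
the new gap height before each step and all per-element fields are mapped
from the old mesh onto the new one by Gaussian-distance-weighted averaging of
old sample values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Geometry",
    "Mesh",
    "FieldTransferSpec",
    "build_mesh",
    "remesh",
    "transfer_fields",
]

REGION_CORTEX = 0
REGION_MARROW = 1
REGION_CALLUS = 2
REGION_NAMES = {REGION_CORTEX: "cortex", REGION_MARROW: "marrow", REGION_CALLUS: "callus"}

TAG_FREE = 0
TAG_BOTTOM_FIXED = 1
TAG_TOP_LOADED = 2
TAG_AXIS = 3


@dataclass(frozen=True)
class Geometry:
    """Dimensions of the osteotomized bone (all lengths in mm)."""

    endosteal_diameter: float = 12.0
    periosteal_diameter: float = 16.0
    initial_gap: float = 1.0
    fragment_length: float = 30.0
    current_gap: float = 1.0

    def __post_init__(self) -> None:
        if not self.periosteal_diameter > self.endosteal_diameter > 0:
            raise ValueError(
                f"need periosteal > endosteal > 0, got "
                f"{self.periosteal_diameter} / {self.endosteal_diameter}")
        if self.initial_gap <= 0:
            raise ValueError(f"initial gap must be > 0, got {self.initial_gap}")
        if self.current_gap < self.initial_gap:
            raise ValueError(
                f"current gap {self.current_gap} < initial gap {self.initial_gap}")
        if self.fragment_length < 0:
            raise ValueError(f"fragment length must be >= 0, got {self.fragment_length}")

    @property
    def r_endo(self) -> float:
        return self.endosteal_diameter / 2.0

    @property
    def r_peri(self) -> float:
        return self.periosteal_diameter / 2.0

    @property
    def annulus_area(self) -> float:
        """Cross-sectional area of the cortical wall / callus annulus (mm^2)."""
        return float(np.pi * (self.r_peri ** 2 - self.r_endo ** 2))


@dataclass(frozen=True)
class FieldTransferSpec:
    """Gaussian kernel width (mm) and sample density for mesh-to-mesh transfer."""

    sigma: float = 0.25
    sample_points_per_element: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"kernel width must be > 0, got {self.sigma}")
        if self.sample_points_per_element < 1:
            raise ValueError("need at least one sample point per element")


@dataclass
class Mesh:
    """Structured quadrilateral mesh of the axisymmetric model.

    ``nodes`` is (n_nodes, 2) with columns (r, z) in mm; ``elements`` is
    (n_elem, 4) counter-clockwise connectivity; ``region`` holds one of the
    REGION_* labels per element; ``node_tags`` one TAG_* per node.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    node_tags: np.ndarray
    geometry: Geometry

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def callus(self) -> np.ndarray:
        """Boolean mask of callus elements."""
        return self.region == REGION_CALLUS

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        """r-z plane area of each quadrilateral (shoelace formula)."""
        quad = self.nodes[self.elements]
        r, z = quad[..., 0], quad[..., 1]
        r2, z2 = np.roll(r, -1, axis=1), np.roll(z, -1, axis=1)
        return 0.5 * np.abs(np.sum(r * z2 - r2 * z, axis=1))

    def gap_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Node indices of the cortical faces bounding the gap (bottom, top)."""
        g = self.geometry
        z_lo, z_hi = g.fragment_length, g.fragment_length + g.current_gap
        r, z = self.nodes[:, 0], self.nodes[:, 1]
        on_wall = r >= g.r_endo - 1e-9
        lo = np.where(on_wall & (np.abs(z - z_lo) < 1e-9))[0]
        hi = np.where(on_wall & (np.abs(z - z_hi) < 1e-9))[0]
        return lo, hi


def _grid_lines(length: float, size: float, start: float = 0.0) -> np.ndarray:
    if length <= 0:
        return np.array([start])
    n = max(1, int(round(length / size)))
    return start + np.linspace(0.0, length, n + 1)


def build_mesh(geometry: Geometry, target_element_size: float = 0.25,
               bone_element_size: float | None = None) -> Mesh:
    """Build the structured mesh for the current gap.

    ``target_element_size`` controls the callus discretization (the gap always
    receives at least 4 element rows); the bone fragments may use a coarser
    ``bone_element_size`` (defaults to twice the callus size).
    """
    if target_element_size <= 0:
        raise ValueError(f"element size must be > 0, got {target_element_size}")
    if target_element_size > geometry.initial_gap:
        raise ValueError(
            f"element size {target_element_size} exceeds initial gap "
            f"{geometry.initial_gap}")
    if bone_element_size is None:
        bone_element_size = 2.0 * target_element_size

    g = geometry
    # Radial lines: marrow at bone size, cortical wall / callus annulus at
    # callus size so cortex and callus columns conform across the gap faces.
    r_marrow = _grid_lines(g.r_endo, bone_element_size)
    r_wall = _grid_lines(g.r_peri - g.r_endo, target_element_size, start=g.r_endo)
    r_lines = np.concatenate([r_marrow, r_wall[1:]])
    n_marrow_cols = len(r_marrow) - 1

    # Axial lines: fragments at bone size, gap with >= 4 rows at callus size.
    n_gap = max(4, int(round(g.current_gap / target_element_size)))
    z_bot = _grid_lines(g.fragment_length, bone_element_size)
    z_gap = g.fragment_length + np.linspace(0.0, g.current_gap, n_gap + 1)
    z_top = _grid_lines(g.fragment_length, bone_element_size,
                        start=g.fragment_length + g.current_gap)
    z_lines = np.concatenate([z_bot, z_gap[1:], z_top[1:]])
    gap_row_lo = len(z_bot) - 1
    gap_row_hi = gap_row_lo + n_gap  # rows [gap_row_lo, gap_row_hi) are gap rows

    nr, nz = len(r_lines), len(z_lines)
    rr, zz = np.meshgrid(r_lines, z_lines, indexing="ij")
    grid_index = np.arange(nr * nz).reshape(nr, nz)

    elems, regions = [], []
    for i in range(nr - 1):
        in_wall = r_lines[i] >= g.r_endo - 1e-9
        for j in range(nz - 1):
            in_gap = gap_row_lo <= j < gap_row_hi
            if in_gap and not in_wall:
                continue  # rectangular gap: no tissue inside the marrow radius
            elems.append((grid_index[i, j], grid_index[i + 1, j],
                          grid_index[i + 1, j + 1], grid_index[i, j + 1]))
            if in_gap:
                regions.append(REGION_CALLUS)
            elif in_wall:
                regions.append(REGION_CORTEX)
            else:
                regions.append(REGION_MARROW)

    elements = np.asarray(elems, dtype=np.int64)
    used = np.unique(elements)
    remap = -np.ones(nr * nz, dtype=np.int64)
    remap[used] = np.arange(used.size)
    elements = remap[elements]
    nodes = np.column_stack([rr.ravel()[used], zz.ravel()[used]])

    tags = np.full(nodes.shape[0], TAG_FREE, dtype=np.int8)
    z_total = 2 * g.fragment_length + g.current_gap
    tags[np.abs(nodes[:, 0]) < 1e-12] = TAG_AXIS
    tags[np.abs(nodes[:, 1]) < 1e-12] = TAG_BOTTOM_FIXED
    tags[np.abs(nodes[:, 1] - z_total) < 1e-12] = TAG_TOP_LOADED

    mesh = Mesh(nodes=nodes, elements=elements,
                region=np.asarray(regions, dtype=np.int8),
                node_tags=tags, geometry=g)
    _check_jacobians(mesh)
    return mesh


def _check_jacobians(mesh: Mesh) -> None:
    quad = mesh.nodes[mesh.elements]
    # Cross product of adjacent edge vectors at every corner must be positive
    # for a convex, counter-clockwise quadrilateral.
    for k in range(4):
        a = quad[:, (k + 1) % 4] - quad[:, k]
        b = quad[:, (k + 3) % 4] - quad[:, k]
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        if np.any(cross <= 0):
            bad = int(np.where(cross <= 0)[0][0])
            raise ValueError(f"non-positive Jacobian in element {bad}")


def remesh(old_mesh: Mesh, new_gap: float, target_element_size: float = 0.25,
           bone_element_size: float | None = None) -> Mesh:
    """Rebuild the mesh with the callus stretched to ``new_gap`` (mm)."""
    if new_gap < old_mesh.geometry.current_gap - 1e-12:
        raise ValueError(
            f"new gap {new_gap} smaller than current {old_mesh.geometry.current_gap}")
    geo = replace(old_mesh.geometry, current_gap=float(new_gap))
    return build_mesh(geo, target_element_size, bone_element_size)


def transfer_fields(old_mesh: Mesh, old_fields: dict[str, np.ndarray],
                    new_mesh: Mesh, spec: FieldTransferSpec | None = None,
                    fresh_slab_values: dict[str, float] | None = None
                    ) -> dict[str, np.ndarray]:
    """Map per-element fields from ``old_mesh`` onto ``new_mesh``.

    Every new element receives the Gaussian-distance-weighted average of old
    element sample values within 3 sigma of its centroid (weights normalized,
    so constant fields are preserved exactly); a new sample point coinciding
    with an old one takes its value directly.  New callus elements above the
    old gap top (the freshly distracted slab) are initialized from
    ``fresh_slab_values`` (field name -> value) instead of transfer.  New
    elements with no old sample within 3 sigma fall back to the nearest old
    sample (logged).
    """
    if spec is None:
        spec = FieldTransferSpec()
    for name, arr in old_fields.items():
        if np.asarray(arr).shape[0] != old_mesh.n_elements:
            raise ValueError(f"field {name!r} not defined on every old element")

    old_pts, old_owner = _sample_points(old_mesh, spec.sample_points_per_element)
    new_c = new_mesh.centroids()

    cutoff = 3.0 * spec.sigma
    d2 = ((new_c[:, None, :] - old_pts[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * spec.sigma ** 2))
    w[d2 > cutoff ** 2] = 0.0

    exact = d2 < 1e-20
    has_exact = exact.any(axis=1)
    wsum = w.sum(axis=1)
    empty = (wsum <= 0) & ~has_exact
    if np.any(empty):
        logger.warning("transfer_fields: %d new elements had no old sample "
                       "within 3 sigma; using nearest sample", int(empty.sum()))

    nearest = np.argmin(d2, axis=1)
    out: dict[str, np.ndarray] = {}
    for name, arr in old_fields.items():
        src = np.asarray(arr, dtype=float)[old_owner]
        vals = np.empty(new_mesh.n_elements, dtype=src.dtype)
        ok = wsum > 0
        vals[ok] = (w[ok] @ src) / wsum[ok]
        vals[~ok] = src[nearest[~ok]]
        # exact coincidence beats smoothing (identity on unchanged meshes)
        rows, cols = np.where(exact)
        vals[rows] = src[cols]
        out[name] = vals

    if fresh_slab_values:
        g_old = old_mesh.geometry
        z_top_old = g_old.fragment_length + g_old.current_gap
        fresh = new_mesh.callus & (new_c[:, 1] > z_top_old + 1e-9)
        for name, value in fresh_slab_values.items():
            out[name][fresh] = value
    return out


def _sample_points(mesh: Mesh, per_element: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample locations and owning-element index for field transfer."""
    if per_element == 1:
        pts = mesh.centroids()
        owner = np.arange(mesh.n_elements)
        return pts, owner
    # 2x2 Gauss points (per_element > 1 uses the 4-point rule)
    a = 1.0 / np.sqrt(3.0)
    gp = np.array([[-a, -a], [a, -a], [a, a], [-a, a]])
    quad = mesh.nodes[mesh.elements]
    pts = []
    for xi, eta in gp:
        N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                             (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
        pts.append(np.einsum("k,nkd->nd", N, quad))
    pts = np.concatenate(pts, axis=0)
    owner = np.tile(np.arange(mesh.n_elements), 4)
    return pts, owner
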