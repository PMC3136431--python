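"""Embryo-like geometries: axisymmetric revolved sections and tetrahedral
balls, with cell-compartment labels for cellularization.

The axisymmetric meshes triangulate the half-section of a sphere or
prolate ellipsoid in the (x, r) plane — x along the central (fertilization)
axis, r the distance from it — and carry 2*pi*r revolution weights, which
is equivalent to assuming fast diffusion in the azimuthal direction.  The
tetrahedral ball is built from a symmetric interior lattice plus a
latitude/longitude surface shell, so that the coordinate planes through
the center are vertex-conforming and can serve as equal-volume division
planes.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import coo_matrix
from scipy.spatial import Delaunay

__all__ = ["EmbryoMesh", "DivisionPlane", "build_mesh",
           "build_axisymmetric_mesh", "build_tet_ball"]


@dataclasses.dataclass
class DivisionPlane:
    """A flat internal no-flux boundary dividing one cell into two."""

    parent_label: int
    point: np.ndarray
    normal: np.ndarray
    daughter_labels: tuple[int, int]
    time_min: float | None = None


@dataclasses.dataclass
class EmbryoMesh:
    """Unstructured mesh with per-element volume weights and cell labels.

    ``vertices`` are in um.  For axisymmetric meshes (``kind='axisym'``)
    vertices are (x, r) with r >= 0, elements are triangles, and
    ``volumes`` include the 2*pi*r_centroid revolution factor; for
    tetrahedral meshes (``kind='tet'``) volumes are plain tet volumes.
    ``cell_labels[e]`` is the compartment (lineage) id of element ``e``;
    internal boundaries between different labels are no-flux.
    """

    kind: str
    vertices: np.ndarray
    elements: np.ndarray
    volumes: np.ndarray
    cell_labels: np.ndarray
    planes: list[DivisionPlane] = dataclasses.field(default_factory=list)
    analytic_volume: float | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.cell_labels)

    def total_volume(self, label: int | None = None) -> float:
        if label is None:
            return float(self.volumes.sum())
        return float(self.volumes[self.cell_labels == label].sum())

    def element_centroids(self) -> np.ndarray:
        return self.vertices[self.elements].mean(axis=1)

    def axial_coordinate(self) -> np.ndarray:
        """Per-vertex coordinate along the central axis (um)."""
        return self.vertices[:, 0]


def _tri_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = verts[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


def _tet_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = verts[tets]
    d = p[:, 1:] - p[:, :1]
    return np.abs(np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2]))) / 6.0


def build_axisymmetric_mesh(major_axis_mm: float, minor_axis_mm: float,
                            spacing_um: float = 20.0) -> EmbryoMesh:
    """Triangulated half-section of a prolate ellipsoid (sphere when the
    axes coincide), to be revolved about the central x-axis.

    ``major_axis_mm`` and ``minor_axis_mm`` are full axis lengths; the
    section is the region x^2/a^2 + r^2/b^2 <= 1, r >= 0 (a, b the
    semi-axes in um).
    """
    a = major_axis_mm * 1000.0 / 2.0
    b = minor_axis_mm * 1000.0 / 2.0
    h = spacing_um
    if h >= min(a, b):
        raise ValueError(f"target spacing {h} um must be well below the "
                         f"smallest semi-axis ({min(a, b)} um)")
    xs = np.arange(-a, a + 0.5 * h, h)
    rs = np.arange(0.0, b + 0.5 * h, h)
    X, R = np.meshgrid(xs, rs)
    pts = np.column_stack([X.ravel(), R.ravel()])
    # keep interior lattice points comfortably inside the arc
    inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 <= (1.0 - 0.35 * h / min(a, b)) ** 2
    pts = pts[inside]
    # boundary arc sampled at ~spacing, poles included
    arc_n = max(8, int(round(np.pi * (a + b) / 2.0 / h)))
    theta = np.linspace(0.0, np.pi, arc_n + 1)
    arc = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    allpts = np.vstack([pts, arc])
    tri = Delaunay(allpts)
    tris = tri.simplices
    areas = _tri_areas(allpts, tris)
    tris = tris[areas > 1e-6 * h * h]
    areas = _tri_areas(allpts, tris)
    r_cent = allpts[tris][:, :, 1].mean(axis=1)
    volumes = 2.0 * np.pi * r_cent * areas
    analytic = 4.0 / 3.0 * np.pi * a * b * b
    mesh = EmbryoMesh(kind="axisym", vertices=allpts, elements=tris,
                      volumes=volumes,
                      cell_labels=np.zeros(len(tris), dtype=int),
                      analytic_volume=analytic)
    err = abs(mesh.total_volume() - analytic) / analytic
    if err > 0.01:
        raise RuntimeError(f"axisymmetric mesh volume off by {err:.2%}; "
                           "refine the spacing")
    return mesh


def _sphere_surface_points(R: float, h: float) -> np.ndarray:
    """Latitude/longitude shell with ~h spacing, symmetric about the three
    coordinate planes (poles on the x-axis)."""
    n_lat = max(4, int(round(np.pi * R / h)))
    if n_lat % 2:
        n_lat += 1  # keep the equator a sample row (x-plane symmetry)
    pts = [(-R, 0.0, 0.0), (R, 0.0, 0.0)]
    for i in range(1, n_lat):
        phi = np.pi * i / n_lat  # polar angle from +x pole
        r_ring = R * np.sin(phi)
        n_az = max(4, int(round(2.0 * np.pi * r_ring / h)))
        n_az = 4 * int(np.ceil(n_az / 4))  # multiple of 4: y/z-plane symmetry
        az = 2.0 * np.pi * np.arange(n_az) / n_az
        x = np.full(n_az, R * np.cos(phi))
        pts.extend(np.column_stack([x, r_ring * np.cos(az),
                                    r_ring * np.sin(az)]))
    return np.asarray(pts)


def tet_quality(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Radius-ratio quality (3 * inradius / circumradius, 1 for regular)."""
    vols = _tet_volumes(verts, tets)
    p = verts[tets]
    # face areas
    def area(i, j, k):
        return 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1)
    A = area(1, 2, 3) + area(0, 2, 3) + area(0, 1, 3) + area(0, 1, 2)
    r_in = 3.0 * vols / A
    # circumradius from edge products (Crelle's formula is overkill; use
    # the bounding estimate via the longest edge for a monotone proxy)
    e = [np.linalg.norm(p[:, i] - p[:, j], axis=1)
         for i in range(4) for j in range(i + 1, 4)]
    longest = np.max(e, axis=0)
    return np.clip(2.0 * np.sqrt(6.0) * r_in / longest, 0.0, 1.0)


def build_tet_ball(diameter_mm: float, spacing_um: float = 30.0,
                   quality_floor: float = 0.05) -> EmbryoMesh:
    """Tetrahedral mesh of a ball, vertex-conforming to the coordinate
    planes through the center (the division planes of the first three
    cleavage rounds)."""
    R = diameter_mm * 1000.0 / 2.0
    h = spacing_um
    if h >= R:
        raise ValueError(f"target spacing {h} um must be well below the "
                         f"radius ({R} um)")
    g = np.arange(-np.floor(R / h) * h, R + 0.5 * h, h)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= R - 0.55 * h]
    surf = _sphere_surface_points(R, h)
    allpts = np.vstack([pts, surf])
    # distmesh-flavored relaxation: pull interior points toward the mean of
    # their Delaunay neighbors (surface shell fixed) to remove slivers near
    # the curved boundary, then re-triangulate
    n_int = len(pts)
    for _ in range(3):
        tri = Delaunay(allpts)
        rows = np.repeat(tri.simplices, 4, axis=1).ravel()
        cols = np.tile(tri.simplices, (1, 4)).ravel()
        keep = rows != cols
        adj = coo_matrix((np.ones(keep.sum()), (rows[keep], cols[keep])),
                         shape=(len(allpts),) * 2).tocsr()
        adj.data[:] = 1.0
        deg = np.asarray(adj.sum(axis=1)).ravel()
        mean_nb = adj @ allpts / deg[:, None]
        moved = allpts.copy()
        moved[:n_int] = 0.5 * (allpts[:n_int] + mean_nb[:n_int])
        # keep interior points interior
        rad = np.linalg.norm(moved[:n_int], axis=1)
        over = rad > R - 0.5 * h
        moved[:n_int][over] *= ((R - 0.5 * h) / rad[over])[:, None]
        allpts = moved
    tri = Delaunay(allpts)
    tets = tri.simplices
    vols = _tet_volumes(allpts, tets)
    keep = vols > 1e-9 * h ** 3
    tets, vols = tets[keep], vols[keep]
    q = tet_quality(allpts, tets)
    # surface slivers (four nearly coplanar shell points) are discarded if
    # they carry negligible volume; a genuinely bad mesh is an error
    bad = q < quality_floor
    if bad.any():
        if vols[bad].sum() > 2e-3 * vols.sum():
            hist, edges = np.histogram(q, bins=10, range=(0.0, 1.0))
            raise RuntimeError(
                "tetrahedral mesh quality floor not met; quality histogram "
                f"(bins {np.round(edges, 2).tolist()}): {hist.tolist()}")
        tets, vols = tets[~bad], vols[~bad]
    analytic = 4.0 / 3.0 * np.pi * R ** 3
    mesh = EmbryoMesh(kind="tet", vertices=allpts, elements=tets,
                      volumes=vols,
                      cell_labels=np.zeros(len(tets), dtype=int),
                      analytic_volume=analytic)
    err = abs(mesh.total_volume() - analytic) / analytic
    if err > 0.01:
        raise RuntimeError(f"tet mesh volume off by {err:.2%}; refine spacing")
    return mesh


def build_mesh(geometry: str, *, diameter_mm: float = 1.0,
               minor_axis_mm: float | None = None,
               spacing_um: float = 20.0) -> EmbryoMesh:
    """Build one of the supported geometries: ``sphere`` / ``prolate``
    (axisymmetric revolved sections) or ``tet_ball``."""
    if geometry == "sphere":
        return build_axisymmetric_mesh(diameter_mm, diameter_mm, spacing_um)
    if geometry == "prolate":
        if minor_axis_mm is None:
            minor_axis_mm = diameter_mm / 2.0
        return build_axisymmetric_mesh(diameter_mm, minor_axis_mm, spacing_um)
    if geometry == "tet_ball":
        return build_tet_ball(diameter_mm, spacing_um)
    raise ValueError(f"unknown geometry {geometry!r}")


def split_cell(mesh: EmbryoMesh, label: int, normal: np.ndarray,
               time_min: float | None = None,
               volume_tol: float = 0.01) -> DivisionPlane:
    """Insert a division plane through the centroid of cell ``label``.

    The plane is perpendicular to ``normal``; its offset along the normal
    is adjusted so the daughter volumes match as closely as the mesh
    resolution allows.  Elements are re-labeled in place (daughters get
    fresh labels); concentrations are not touched here — the solver keeps
    per-cell fields and daughters inherit the parent field as-is.
    Raises ``RuntimeError`` if no offset achieves equal volumes within
    ``volume_tol``.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    sel = np.where(mesh.cell_labels == label)[0]
    if len(sel) == 0:
        raise ValueError(f"no elements carry cell label {label}")
    vols = mesh.volumes[sel]
    if mesh.kind == "axisym":
        cents = mesh.element_centroids()[sel]
        coord = cents[:, 0] * normal[0]  # axisym planes must be x = const
        centroid_n = float((coord * vols).sum() / vols.sum())
    else:
        cents = mesh.element_centroids()[sel]
        coord = cents @ normal
        centroid_n = float((coord * vols).sum() / vols.sum())
    order = np.argsort(coord)
    cum = np.cumsum(vols[order])
    total = cum[-1]
    k = int(np.argmin(np.abs(cum - total / 2.0)))
    imbalance = abs(cum[k] - total / 2.0) / (total / 2.0)
    if imbalance > volume_tol:
        raise RuntimeError(
            f"cannot split cell {label} into equal volumes at this mesh "
            f"resolution (best imbalance {imbalance:.2%}); refine the mesh")
    offset = 0.5 * (coord[order][k] + coord[order][min(k + 1, len(order) - 1)])
    new_lo = int(mesh.cell_labels.max()) + 1
    new_hi = new_lo + 1
    side_hi = coord > offset
    mesh.cell_labels[sel[side_hi]] = new_hi
    mesh.cell_labels[sel[~side_hi]] = new_lo
    point = np.zeros(mesh.vertices.shape[1])
    point += offset * normal[: mesh.vertices.shape[1]]
    plane = DivisionPlane(parent_label=label, point=point, normal=normal,
                          daughter_labels=(new_lo, new_hi), time_min=time_min)
    mesh.planes.append(plane)
    return plane
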