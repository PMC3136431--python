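"""3D reaction-diffusion on embryo meshes, with optional cellularization.

Diffusion uses a P1 finite-element discretization (lumped mass) of each
cell compartment separately, so internal division surfaces and the outer
boundary are no-flux by construction.  Time stepping mirrors the 1D
solver: Strang splitting with half Crank-Nicolson diffusion steps around a
full fixed-step RK4 reaction step.  The half-step linear systems are
solved by sparse LU factorization, computed once per compartment topology
(a direct solve trivially meets the iterative-residual contract).

Cellularization: when the volume-averaged inactive complex
(``cycB_cdk1_YpTp``) of a cell crosses the homogeneous half-maximum
upward, a flat equal-volume division plane is inserted (alternating
orthogonal axes by lineage generation, the first perpendicular to the
fertilization axis), the compartment is split, and each daughter inherits
the concentration field as-is — no redistribution, which is what produces
unequal protein partitioning between daughters in the chaotic regime.
"""
from __future__ import annotations

import dataclasses
import time as _time
from typing import Callable

import numpy as np
from scipy.sparse import coo_matrix, diags
from scipy.sparse.linalg import splu

from .config import Geometry3D, SimConfig
from .diagnostics import DivisionRecord
from .kinetics import IDX, LimitCycleSummary
from .meshes import EmbryoMesh, build_mesh, split_cell
from .params import KineticParams
from .solver1d import _prepare, _rk4
from .triggers import INSTANTANEOUS, WaveSpec

__all__ = ["FemRegion", "assemble_diffusion_operator", "cn_step_3d",
           "Run3DResult", "run_3d", "default_plane_policy"]


def _grad_ops(verts: np.ndarray, elem: np.ndarray):
    """P1 shape-function gradients and element measures (areas/volumes)."""
    p = verts[elem]
    if elem.shape[1] == 3:  # triangles in (x, r)
        mat = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)
        det = mat[:, 0, 0] * mat[:, 1, 1] - mat[:, 0, 1] * mat[:, 1, 0]
        measure = 0.5 * np.abs(det)
        inv = np.empty_like(mat)
        inv[:, 0, 0] = mat[:, 1, 1]
        inv[:, 0, 1] = -mat[:, 0, 1]
        inv[:, 1, 0] = -mat[:, 1, 0]
        inv[:, 1, 1] = mat[:, 0, 0]
        inv /= det[:, None, None]
        ref = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
        grads = np.einsum("kd,edD->ekD", ref, inv)
    else:  # tetrahedra
        mat = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0],
                        p[:, 3] - p[:, 0]], axis=2)
        det = np.linalg.det(mat)
        measure = np.abs(det) / 6.0
        inv = np.linalg.inv(mat)
        ref = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0],
                        [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        grads = np.einsum("kd,edD->ekD", ref, inv)
    return grads, measure


class FemRegion:
    """Stiffness/mass operators and solver factorizations for one cell."""

    def __init__(self, mesh: EmbryoMesh, label: int):
        self.label = label
        sel = np.where(mesh.cell_labels == label)[0]
        if len(sel) == 0:
            raise ValueError(f"cell label {label} has no elements")
        elems = mesh.elements[sel]
        gverts = np.unique(elems)
        local = {g: i for i, g in enumerate(gverts)}
        lelems = np.vectorize(local.__getitem__)(elems)
        self.global_vertices = gverts
        self.elements = lelems
        self.coords = mesh.vertices[gverts]
        grads, measure = _grad_ops(mesh.vertices, elems)
        if mesh.kind == "axisym":
            r_cent = mesh.vertices[elems][:, :, 1].mean(axis=1)
            weight = 2.0 * np.pi * r_cent * measure
        else:
            weight = measure
        self.element_weight = weight
        nv = len(gverts)
        k_loc = np.einsum("e,ekD,elD->ekl", weight, grads, grads)
        kk = elems.shape[1]
        rows = np.repeat(lelems, kk, axis=1).ravel()
        cols = np.tile(lelems, (1, kk)).ravel()
        self.K = coo_matrix((k_loc.ravel(), (rows, cols)),
                            shape=(nv, nv)).tocsr()
        m = np.zeros(nv)
        if mesh.kind == "axisym":
            # row-sum lumping of the consistent axisymmetric mass:
            # int 2*pi*r*phi_i over a triangle = 2*pi*A*(2 r_i + r_j + r_k)/12
            r_nodes = mesh.vertices[elems][:, :, 1]
            # (2 r_i + sum_{j != i} r_j) = r_i + sum_all r_j
            contrib = 2.0 * np.pi * measure[:, None] * (
                r_nodes + r_nodes.sum(axis=1, keepdims=True)) / 12.0
            np.add.at(m, lelems.ravel(), contrib.ravel())
        else:
            np.add.at(m, lelems.ravel(), np.repeat(weight / kk, kk))
        self.M = m  # lumped mass (volume weight per vertex)
        self.volume = float(weight.sum())
        self._lu = None
        self._B = None
        self._half_dt = None
        # connectivity check: the compartment must be a single piece
        from scipy.sparse.csgraph import connected_components
        n_comp, _ = connected_components(self.K, directed=False)
        if n_comp != 1:
            raise ValueError(f"cell label {label} is disconnected "
                             f"({n_comp} components)")

    def prepare(self, D_um2_min: float, half_dt_min: float) -> None:
        """Factorize the Crank-Nicolson half-step operator."""
        c = D_um2_min * half_dt_min / 2.0
        Mdiag = diags(self.M)
        self._lu = splu((Mdiag + c * self.K).tocsc())
        self._B = (Mdiag - c * self.K).tocsr()
        self._half_dt = half_dt_min

    def diffuse_half(self, y: np.ndarray) -> np.ndarray:
        """One CN half step applied to field array (n_species, n_local)."""
        rhs = self._B @ y.T
        out = np.empty_like(y)
        for i in range(y.shape[0]):
            out[i] = self._lu.solve(rhs[:, i])
        return out

    def average(self, values: np.ndarray) -> float:
        """Volume-weighted average of a per-vertex array."""
        return float(self.M @ values / self.volume)

    def apply_operator(self, values: np.ndarray) -> np.ndarray:
        """The discrete diffusion operator (stiffness matrix) itself."""
        return self.K @ values


def assemble_diffusion_operator(mesh: EmbryoMesh, label: int = 0) -> FemRegion:
    """Discrete Laplacian (stiffness + lumped mass) for one cell of the
    mesh, with no-flux exterior and internal boundaries.  Annihilates
    constants and conserves the volume-weighted total by construction."""
    return FemRegion(mesh, label)


def cn_step_3d(region: FemRegion, y: np.ndarray, dt_min: float,
               params: KineticParams, gate: np.ndarray,
               reactions: bool = True) -> np.ndarray:
    """Strang-split step on one compartment (mirrors the 1D contract)."""
    y = region.diffuse_half(y)
    if reactions:
        y = _rk4(y, dt_min, params, gate)
    return region.diffuse_half(y)


def default_plane_policy(generation: int) -> np.ndarray:
    """Alternating orthogonal division planes: the first perpendicular to
    the fertilization (x) axis, then cycling through y and z."""
    axes = np.eye(3)
    return axes[generation % 3]


@dataclasses.dataclass
class CellTrace:
    label: int
    parent: int | None
    born_min: float
    times: list[float]
    avg_cyt: list[float]
    division_times: list[float]
    volume: float
    alive: bool = True


@dataclasses.dataclass
class Run3DResult:
    mesh: EmbryoMesh
    cells: dict[int, CellTrace]
    divisions: DivisionRecord            # per final cell
    surface_t: np.ndarray | None         # axisym: arc-node kymograph
    surface_x_mm: np.ndarray | None
    surface_cyt: np.ndarray | None
    limit_cycle: LimitCycleSummary
    config: SimConfig
    wallclock_s: float


def _surface_vertices(mesh: EmbryoMesh) -> np.ndarray:
    """Axisymmetric boundary arc vertices (on the revolved surface),
    ordered by axial coordinate."""
    v = mesh.vertices
    a = np.abs(v[:, 0]).max()
    b = v[:, 1].max()
    rho = (v[:, 0] / a) ** 2 + (v[:, 1] / b) ** 2
    idx = np.where(rho > (1.0 - 1e-6))[0]
    return idx[np.argsort(v[idx, 0])]


def run_3d(config: SimConfig, params: KineticParams | None = None,
           mesh: EmbryoMesh | None = None,
           plane_policy: Callable[[int], np.ndarray] = default_plane_policy,
           max_division_rounds: int = 3,
           precomputed=None) -> Run3DResult:
    """Full 3D embryo run: calcium-wave (or instantaneous) trigger on an
    axisymmetric or tetrahedral mesh, optional cellularization.

    Cell-compartment fields are held separately; daughters inherit the
    parent field without redistribution.  Division events are the upward
    crossings of each cell's volume-averaged ``cycB_cdk1_YpTp`` past the
    homogeneous half-maximum threshold.
    """
    if not isinstance(config.geometry, Geometry3D):
        raise ValueError("run_3d requires 3D geometry")
    p = params if params is not None else config.resolved_params()
    g = config.geometry
    if mesh is None:
        mesh = build_mesh(g.kind if g.kind != "sphere" else "sphere",
                          diameter_mm=g.diameter_mm,
                          minor_axis_mm=g.minor_axis_mm,
                          spacing_um=g.spacing_um)
    if config.cellularize and mesh.kind != "tet":
        raise ValueError("cellularization requires a tetrahedral mesh")
    summary, arrest = (precomputed if precomputed is not None
                       else _prepare(p, config.numerics))
    threshold = summary.division_threshold

    dt = config.numerics.dt_s / 60.0
    D_um2_min = p.D * 60.0
    trig = config.trigger
    if trig.kind == "spreading":
        raise NotImplementedError("the spreading trigger is a 1D protocol; "
                                  "use kind='wave' or 'instantaneous' in 3D")
    length_mm = g.diameter_mm
    # fertilization point: the -x pole; positions projected in mm
    x_origin_um = -length_mm * 1000.0 / 2.0
    wave = (WaveSpec(INSTANTANEOUS) if trig.kind == "instantaneous"
            else WaveSpec(trig.speed_mm_min, origin=(x_origin_um / 1000.0,),
                          start_time=trig.start_time_min))

    regions: dict[int, FemRegion] = {}
    fields: dict[int, np.ndarray] = {}
    gates: dict[int, np.ndarray] = {}
    generation: dict[int, int] = {}
    cells: dict[int, CellTrace] = {}
    t_now = 0.0

    def make_region(label: int, field: np.ndarray | None, parent: int | None):
        reg = FemRegion(mesh, label)
        reg.prepare(D_um2_min, dt / 2.0)
        regions[label] = reg
        if field is None:
            fields[label] = np.tile(arrest[:, None], (1, len(reg.global_vertices)))
        else:
            fields[label] = field
        cells[label] = CellTrace(label, parent, t_now, [], [], [],
                                 reg.volume)
        return reg

    make_region(0, None, None)
    generation[0] = 0

    surface_idx = _surface_vertices(mesh) if mesh.kind == "axisym" else None
    surf_t, surf_cyt = [], []

    n_steps = int(round(config.t_end_min / dt))
    stride = max(1, int(round(config.output_every_min / dt)))
    # a cell is "armed" for division only once its average has been below
    # the threshold; this keeps one division event per cycle per lineage
    # (a newborn daughter does not re-fire on the tail of the parent's
    # crossing)
    armed = {0: regions[0].average(fields[0][IDX["cycB_cdk1_YpTp"]]) < threshold}
    wall0 = _time.time()

    for k in range(n_steps + 1):
        t_now = k * dt
        if k % stride == 0:
            for label, reg in regions.items():
                avg = reg.average(fields[label][IDX["cycB_cdk1_YpTp"]])
                cells[label].times.append(t_now)
                cells[label].avg_cyt.append(avg)
            if surface_idx is not None:
                # region 0 only (axisym runs are never cellularized)
                reg = regions[0]
                inv = {g: i for i, g in enumerate(reg.global_vertices)}
                rows = [inv[gv] for gv in surface_idx]
                surf_t.append(t_now)
                surf_cyt.append(fields[0][IDX["cycB_cdk1_YpTp"]][rows].copy())
        if k == n_steps:
            break
        to_split = []
        for label, reg in list(regions.items()):
            x_mm = reg.coords[:, 0:1] / 1000.0
            gate = (np.ones(len(reg.coords))
                    if wave.speed == INSTANTANEOUS
                    else ((x_mm[:, 0] - wave.origin[0]) <=
                          float(wave.speed) * max(t_now - wave.start_time, 0.0)
                          ).astype(float))
            y = cn_step_3d(reg, fields[label], dt, p, gate)
            if not np.all(np.isfinite(y)):
                raise FloatingPointError(f"non-finite field in cell {label} "
                                         f"at t = {t_now:.2f} min")
            fields[label] = y
            avg = reg.average(y[IDX["cycB_cdk1_YpTp"]])
            # refractory: a newborn cell must complete most of a cycle
            # before it can divide again (one cleavage per cycle)
            mature = t_now - cells[label].born_min >= 0.5 * summary.period
            if armed[label] and mature and avg >= threshold:
                cells[label].division_times.append(t_now)
                armed[label] = False
                if (config.cellularize
                        and generation[label] < max_division_rounds):
                    to_split.append(label)
            elif not armed[label] and avg < threshold:
                armed[label] = True
        for label in to_split:
            normal = plane_policy(generation[label])
            plane = split_cell(mesh, label, normal, time_min=t_now)
            parent_reg = regions.pop(label)
            parent_field = fields.pop(label)
            armed.pop(label)
            cells[label].alive = False
            inv = {gv: i for i, gv in enumerate(parent_reg.global_vertices)}
            for daughter in plane.daughter_labels:
                reg = FemRegion(mesh, daughter)
                reg.prepare(D_um2_min, dt / 2.0)
                rows = [inv[gv] for gv in reg.global_vertices]
                regions[daughter] = reg
                fields[daughter] = parent_field[:, rows].copy()
                generation[daughter] = generation[label] + 1
                cells[daughter] = CellTrace(
                    daughter, label, t_now, [], [], [], reg.volume)
                armed[daughter] = (reg.average(
                    fields[daughter][IDX["cycB_cdk1_YpTp"]]) < threshold)

    live = sorted(regions)
    divisions = DivisionRecord(
        np.array(live, dtype=float),
        [np.asarray(cells[l].division_times, dtype=float) for l in live])
    return Run3DResult(
        mesh=mesh, cells=cells, divisions=divisions,
        surface_t=np.asarray(surf_t) if surface_idx is not None else None,
        surface_x_mm=(mesh.vertices[surface_idx, 0] / 1000.0
                      if surface_idx is not None else None),
        surface_cyt=np.asarray(surf_cyt) if surface_idx is not None else None,
        limit_cycle=summary, config=config,
        wallclock_s=_time.time() - wall0)
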