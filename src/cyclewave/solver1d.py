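"""1D reaction-diffusion solver and the critical-wave-speed search.

The nine-species system is integrated on an interval with no-flux or
periodic boundaries.  Diffusion is advanced by either the explicit FTCS
scheme or the implicit Crank-Nicolson scheme; the reaction term is coupled
by Strang splitting (half diffusion step, full fixed-step RK4 reaction
step, half diffusion step).  Every node starts at the CSF-arrested state
and is released by the configured trigger (calcium-wave gate, spreading
threshold latch, or instantaneously).
"""
from __future__ import annotations

import dataclasses
import time as _time

import numpy as np
from scipy.linalg import solve_banded

from .config import Geometry1D, SimConfig
from .diagnostics import DivisionRecord, classify_synchrony, division_count_map
from .kinetics import (IDX, N_SPECIES, SPECIES, LimitCycleSummary,
                       csf_arrested_state, find_limit_cycle, reaction_rhs)
from .params import KineticParams
from .triggers import (INSTANTANEOUS, ThresholdTrigger, ThresholdTriggerSpec,
                       WaveSpec, apc_gate)

__all__ = ["Grid1D", "Kymograph", "Run1DResult", "step_rd", "run_1d",
           "critical_speed_search", "CriticalSpeedResult"]


@dataclasses.dataclass(frozen=True)
class Grid1D:
    """Uniform interval grid.  ``length_mm / (dx_um/1000)`` must be an
    integer cell count; no-flux grids carry a node on each boundary."""

    length_mm: float
    dx_um: float
    bc: str = "noflux"

    def __post_init__(self):
        if self.dx_um <= 0:
            raise ValueError("dx must be positive")
        n = self.length_mm * 1000.0 / self.dx_um
        if abs(n - round(n)) > 1e-9 * max(n, 1.0):
            raise ValueError("domain length must be an integer number of cells")
        if self.bc not in ("noflux", "periodic"):
            raise ValueError(f"unknown boundary condition {self.bc!r}")

    @property
    def n_nodes(self) -> int:
        cells = int(round(self.length_mm * 1000.0 / self.dx_um))
        return cells if self.bc == "periodic" else cells + 1

    @property
    def x_mm(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.dx_um / 1000.0


@dataclasses.dataclass
class Kymograph:
    """Space-time record of selected species: ``data[name][k, j]`` is the
    concentration at output time ``t[k]`` and node ``x_mm[j]``."""

    t: np.ndarray
    x_mm: np.ndarray
    data: dict[str, np.ndarray]

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("kymograph sample times must be strictly increasing")
        for name, arr in self.data.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"kymograph of {name!r} contains non-finite values")


class _Diffusion1D:
    """Per-species diffusion sub-step operators for a fixed half step."""

    def __init__(self, grid: Grid1D, D_um2_min: float, half_dt: float,
                 method: str):
        N = grid.n_nodes
        self.N = N
        self.method = method
        self.periodic = grid.bc == "periodic"
        self.r = D_um2_min * half_dt / grid.dx_um ** 2  # explicit-Euler number
        if method == "crank_nicolson":
            rr = self.r / 2.0  # CN averages old and new Laplacians
            if self.periodic:
                from scipy.sparse import diags, identity
                from scipy.sparse.linalg import splu
                lap = diags([np.ones(N - 1), -2.0 * np.ones(N),
                             np.ones(N - 1)], [-1, 0, 1], format="lil")
                lap[0, -1] = lap[-1, 0] = 1.0
                self._lap = lap.tocsr()
                self._lu = splu((identity(N) - rr * lap).tocsc())
                self._B = (identity(N) + rr * lap).tocsr()
            else:
                # mirror-ghost (finite-volume half-cell) rows at both ends,
                # matching the explicit Laplacian so the trapezoid-weighted
                # total is conserved exactly
                self._ab = np.zeros((3, N))
                self._ab[0, 1:] = -rr
                self._ab[0, 1] = -2.0 * rr
                self._ab[1] = 1.0 + 2.0 * rr
                self._ab[2, :-1] = -rr
                self._ab[2, -2] = -2.0 * rr
                self._rr = rr

    def _laplacian(self, u: np.ndarray) -> np.ndarray:
        lap = np.empty_like(u)
        lap[:, 1:-1] = u[:, :-2] - 2.0 * u[:, 1:-1] + u[:, 2:]
        if self.periodic:
            lap[:, 0] = u[:, -1] - 2.0 * u[:, 0] + u[:, 1]
            lap[:, -1] = u[:, -2] - 2.0 * u[:, -1] + u[:, 0]
        else:  # mirror ghost nodes (no flux)
            lap[:, 0] = 2.0 * (u[:, 1] - u[:, 0])
            lap[:, -1] = 2.0 * (u[:, -2] - u[:, -1])
        return lap

    def half_step(self, y: np.ndarray) -> np.ndarray:
        if self.r == 0.0:
            return y
        if self.method == "ftcs":
            return y + self.r * self._laplacian(y)
        if self.periodic:
            out = np.empty_like(y)
            rhs = self._B @ y.T
            for i in range(y.shape[0]):
                out[i] = self._lu.solve(rhs[:, i])
            return out
        rhs = y + self._rr * self._laplacian(y)
        return solve_banded((1, 1), self._ab, rhs.T).T


def _rk4(y: np.ndarray, h: float, p: KineticParams,
         gate: np.ndarray) -> np.ndarray:
    k1 = reaction_rhs(y, p, gate)
    k2 = reaction_rhs(y + 0.5 * h * k1, p, gate)
    k3 = reaction_rhs(y + 0.5 * h * k2, p, gate)
    k4 = reaction_rhs(y + h * k3, p, gate)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def step_rd(y: np.ndarray, dt_min: float, diffusion: _Diffusion1D,
            params: KineticParams, gate: np.ndarray,
            reactions: bool = True) -> np.ndarray:
    """One combined reaction-diffusion step.

    Crank-Nicolson: Strang split — half implicit diffusion step, full
    fixed-step RK4 reaction step, half implicit diffusion step.  FTCS:
    simultaneous explicit forward-Euler update of reaction and central
    diffusion (the classical forward-time central-space scheme).
    """
    if diffusion.method == "ftcs":
        d = reaction_rhs(y, params, gate) * dt_min if reactions else 0.0
        return y + d + 2.0 * diffusion.r * diffusion._laplacian(y)
    y = diffusion.half_step(y)
    if reactions:
        y = _rk4(y, dt_min, params, gate)
    return diffusion.half_step(y)


def ftcs_stability_limit(dx_um: float, D_um2_s: float) -> float:
    """Largest stable FTCS time step, in seconds."""
    if D_um2_s == 0:
        return np.inf
    return dx_um ** 2 / (2.0 * D_um2_s)


@dataclasses.dataclass
class Run1DResult:
    kymograph: Kymograph
    divisions: DivisionRecord
    division_summary: dict
    limit_cycle: LimitCycleSummary
    arrest: np.ndarray
    config: SimConfig
    wallclock_s: float


def _prepare(params: KineticParams, numerics) -> tuple[LimitCycleSummary, np.ndarray]:
    summary = find_limit_cycle(params, rtol=numerics.rtol, atol=numerics.atol)
    if not summary.oscillatory:
        raise ValueError("parameters are not in the oscillatory regime")
    arrest = csf_arrested_state(params, summary,
                                residual_tol=numerics.arrest_residual_tol)
    return summary, arrest.as_array()


def run_1d(config: SimConfig, params: KineticParams | None = None,
           precomputed: tuple[LimitCycleSummary, np.ndarray] | None = None,
           initial_field: np.ndarray | None = None,
           ) -> Run1DResult:
    """Integrate a full 1D embryo run.

    Every node starts at the CSF-arrested state (or at ``initial_field``,
    shape (9, n_nodes), e.g. for perturbation-growth studies); the
    configured trigger releases nodes into the full kinetics; the
    kymograph is recorded on the output schedule and division events are
    extracted with the homogeneous half-maximum threshold.
    """
    if not isinstance(config.geometry, Geometry1D):
        raise ValueError("run_1d requires 1D interval geometry")
    p = params if params is not None else config.resolved_params()
    grid = Grid1D(config.geometry.length_mm, config.geometry.dx_um,
                  config.geometry.bc)
    num = config.numerics
    if num.method == "ftcs":
        limit = ftcs_stability_limit(grid.dx_um, p.D)
        if num.dt_s > limit:
            raise ValueError(f"FTCS unstable: dt = {num.dt_s} s exceeds the "
                             f"stability limit {limit:.3f} s for dx = "
                             f"{grid.dx_um} um, D = {p.D} um^2/s")
    summary, arrest = (precomputed if precomputed is not None
                       else _prepare(p, num))

    dt = num.dt_s / 60.0
    D_um2_min = p.D * 60.0
    diffusion = _Diffusion1D(grid, D_um2_min, dt / 2.0, num.method)
    x = grid.x_mm
    if initial_field is not None:
        y = np.array(initial_field, dtype=float)
        if y.shape != (N_SPECIES, grid.n_nodes):
            raise ValueError(f"initial_field must have shape "
                             f"{(N_SPECIES, grid.n_nodes)}, got {y.shape}")
    else:
        y = np.tile(arrest[:, None], (1, grid.n_nodes))

    trig = config.trigger
    wave = None
    latch = None
    if trig.kind == "instantaneous":
        wave = WaveSpec(INSTANTANEOUS)
    elif trig.kind == "wave":
        wave = WaveSpec(trig.speed_mm_min, origin=(0.0,),
                        start_time=trig.start_time_min)
    else:
        latch = ThresholdTrigger(
            ThresholdTriggerSpec(trig.threshold_factor, trig.active_fraction),
            x, arrest[IDX["cycB_cdk1_Tp"]])

    n_steps = int(round(config.t_end_min / dt))
    stride = max(1, int(round(config.output_every_min / dt)))
    rec_idx = [IDX[name] for name in config.record_species]
    kymo = {name: [] for name in config.record_species}
    out_t = []
    pos1d = x[:, None]  # wave projection expects (n, dim)

    t0 = _time.time()
    for k in range(n_steps + 1):
        t_min = k * dt
        if k % stride == 0:
            for name, i in zip(config.record_species, rec_idx):
                kymo[name].append(y[i].copy())
            out_t.append(t_min)
            if not np.all(np.isfinite(y)):
                bad = np.argwhere(~np.isfinite(y))
                raise FloatingPointError(
                    f"non-finite value at t = {t_min:.2f} min, species "
                    f"{SPECIES[bad[0][0]]}, node {bad[0][1]}")
        if k == n_steps:
            break
        if latch is not None:
            gate = latch.update(y[IDX["cycB_cdk1_Tp"]])
        else:
            gate = apc_gate(pos1d, t_min, wave)
        y = step_rd(y, dt, diffusion, p, gate)

    kymograph = Kymograph(np.array(out_t), x,
                          {n: np.array(v) for n, v in kymo.items()})
    rec, div_summary = division_count_map(
        kymograph.t, kymograph.data["cycB_cdk1_YpTp"],
        summary.division_threshold, positions=x)
    return Run1DResult(kymograph, rec, div_summary, summary, arrest, config,
                       _time.time() - t0)


@dataclasses.dataclass
class CriticalSpeedResult:
    """Outcome of the critical-wave-speed bisection."""

    v_c: float | None          # mm/min; None if no finite critical speed
    status: str                # "ok" | "below_minimum_chaotic_size"
    bracket: tuple[float, float] | None
    probes: list[tuple[float, bool]]  # (speed, synchronous)

    @property
    def transit_time_min(self) -> float | None:
        return None if self.v_c is None else self._length / self.v_c

    _length: float = 1.0


def critical_speed_search(config: SimConfig, v_lo, v_hi: float,
                          rel_tol: float = 0.02,
                          params: KineticParams | None = None,
                          ) -> CriticalSpeedResult:
    """Bisection for the slowest calcium-wave speed that still yields
    synchronous oscillations.

    Each probe runs the configured simulation (the paper-style protocol is
    a 12-hour window) and classifies it with the left/right-half criterion:
    equal mean division counts and corresponding division times within 10%
    of the period.  ``v_lo`` must classify asynchronous and ``v_hi``
    synchronous.  Asynchrony can occupy a *band* of speeds (very slow waves
    sometimes re-synchronize), so ``v_lo`` may be a sequence of candidate
    anchors, probed in order until one classifies asynchronous; the search
    then brackets the upper edge of the asynchronous band.  If every
    candidate synchronizes the result carries status
    ``"below_minimum_chaotic_size"`` — small domains synchronize at any
    speed.  Raises ``ValueError`` if the endpoints do not bracket.
    """
    candidates = ([float(v_lo)] if np.isscalar(v_lo)
                  else [float(v) for v in v_lo])
    if not all(0 < v < v_hi for v in candidates):
        raise ValueError("need 0 < v_lo < v_hi")
    p = params if params is not None else config.resolved_params()
    pre = _prepare(p, config.numerics)
    period = pre[0].period
    probes: list[tuple[float, bool]] = []

    from .config import Geometry3D
    mesh3d = None
    if isinstance(config.geometry, Geometry3D):
        from .meshes import build_mesh
        g = config.geometry
        mesh3d = build_mesh(g.kind, diameter_mm=g.diameter_mm,
                            minor_axis_mm=g.minor_axis_mm,
                            spacing_um=g.spacing_um)

    def synchronous(v: float) -> bool:
        cfg = config.model_copy(update={
            "trigger": config.trigger.model_copy(update={
                "kind": "wave", "speed_mm_min": v})})
        if mesh3d is not None:
            from .solver3d import run_3d
            res3 = run_3d(cfg, params=p, mesh=mesh3d, precomputed=pre)
            divisions, _ = division_count_map(
                res3.surface_t, res3.surface_cyt,
                pre[0].division_threshold, positions=res3.surface_x_mm)
        else:
            divisions = run_1d(cfg, params=p, precomputed=pre).divisions
        # classify the settled behavior: skip both the wave transit and the
        # first half of the run, so the verdict reflects whether the medium
        # relaxes to synchrony or descends into chaos, not the unavoidable
        # initial phase lag imprinted by the front
        transit = config.geometry.length_mm / v
        start = min(max(transit, 0.5 * config.t_end_min),
                    0.75 * config.t_end_min)
        ok = classify_synchrony(divisions, period,
                                window=(start, config.t_end_min))
        probes.append((v, ok))
        return ok

    anchor = next((v for v in candidates if not synchronous(v)), None)
    if anchor is None:
        return CriticalSpeedResult(None, "below_minimum_chaotic_size", None,
                                   probes)
    if not synchronous(v_hi):
        raise ValueError(f"endpoints do not bracket: v_hi = {v_hi} mm/min is "
                         "not synchronous; widen the bracket")
    lo, hi = anchor, v_hi
    while (hi - lo) / hi > 2.0 * rel_tol:
        mid = np.sqrt(lo * hi)
        if synchronous(mid):
            hi = mid
        else:
            lo = mid
    result = CriticalSpeedResult(float(np.sqrt(lo * hi)), "ok", (lo, hi),
                                 probes)
    result._length = config.geometry.length_mm
    return result
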