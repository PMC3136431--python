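"""The well-mixed nine-species embryonic cell-cycle oscillator.

Species (all concentrations; regulators are fractions of their totals):

======================  ====================================================
``cycB_free``           free cyclin B
``cycB_cdk1``           cyclin B-Cdk1 complex, unphosphorylated
``cycB_cdk1_Yp``        complex with the inhibitory Tyr-15 phosphate
``cycB_cdk1_Tp``        complex with the activating Thr phosphate — this is
                        active Cdk1, whose peak defines metaphase
``cycB_cdk1_YpTp``      doubly phosphorylated, inactive complex; its upward
                        half-maximum crossing defines a division event
``cdc25_active``        active Cdc25 (removes the Tyr-15 phosphate)
``wee1_active``         active Wee1 (adds the Tyr-15 phosphate)
``plx1_active``         active Plx1 (activates APC)
``apc_active``          active APC (destroys cyclin-containing species)
======================  ====================================================

The wiring implements the classic relaxation-oscillator architecture: dual
positive feedback (active Cdk1 activates Cdc25 and inactivates Wee1) makes
Cdk1 activation switch-like, and delayed negative feedback (Cdk1 -> Plx1 ->
APC -> cyclin destruction) resets the switch.  Ahead of fertilization the
cytostatic factor (CSF) interrupts the negative feedback: the rate equation
of active APC is gated off entirely, freezing ``apc_active`` at its current
value (see :func:`csf_arrested_state`).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import solve_ivp

from .params import KineticParams

__all__ = [
    "SPECIES", "N_SPECIES", "SpeciesState", "LimitCycleSummary",
    "reaction_derivatives", "reaction_rhs", "integrate_homogeneous",
    "find_limit_cycle", "csf_arrested_state", "tune_ks_for_period",
]

SPECIES: tuple[str, ...] = (
    "cycB_free", "cycB_cdk1", "cycB_cdk1_Yp", "cycB_cdk1_Tp",
    "cycB_cdk1_YpTp", "cdc25_active", "wee1_active", "plx1_active",
    "apc_active",
)
N_SPECIES = len(SPECIES)

#: indices of the cyclin-containing species (targets of APC destruction)
CYCLIN_SPECIES = (0, 1, 2, 3, 4)

IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclasses.dataclass(frozen=True)
class SpeciesState:
    """Concentrations of the nine species at one point."""

    cycB_free: float
    cycB_cdk1: float
    cycB_cdk1_Yp: float
    cycB_cdk1_Tp: float
    cycB_cdk1_YpTp: float
    cdc25_active: float
    wee1_active: float
    plx1_active: float
    apc_active: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_SPECIES,):
            raise ValueError(f"expected a length-{N_SPECIES} state vector, "
                             f"got shape {y.shape}")
        return cls(*y.tolist())

    def validate(self, params: KineticParams | None = None) -> None:
        """Raise ``ValueError`` naming the offending field if the state is
        negative, non-finite, or an active pool exceeds its total."""
        for name in SPECIES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"species {name!r} is not finite: {v!r}")
            if v < 0.0:
                raise ValueError(f"species {name!r} is negative: {v!r}")
        if params is not None:
            tol = 1e-9
            for name, total in (("cdc25_active", params.cdc25_total),
                                ("wee1_active", params.wee1_total),
                                ("plx1_active", params.plx1_total),
                                ("apc_active", params.apc_total)):
                if getattr(self, name) > total * (1.0 + tol):
                    raise ValueError(
                        f"active pool {name!r} = {getattr(self, name)!r} "
                        f"exceeds its total {total!r}")


def _hill(x: np.ndarray, K: float, n: float) -> np.ndarray:
    xn = (np.maximum(x, 0.0) / K) ** n
    return xn / (1.0 + xn)


def reaction_rhs(y: np.ndarray, p: KineticParams,
                 apc_gate: np.ndarray | float = 1.0) -> np.ndarray:
    """Vectorized time derivatives for state array ``y`` of shape (9, ...).

    ``apc_gate`` multiplies the entire rate equation of active APC: 1 gives
    the full post-fertilization kinetics, 0 freezes APC (CSF-arrested /
    ahead of the calcium-wave front).  The spatial solvers call this with a
    per-node gate array.
    """
    B, C00, CY, CT, CYT, c25, w1, plx, apc = y
    v_wee = p.k_wee1_basal + p.k_wee1_act * w1
    v_25 = p.k_cdc25_basal + p.k_cdc25_act * c25
    deg = p.kdest * apc
    d = np.empty_like(y)
    # cyclin synthesis, Cdk1 binding, APC-mediated destruction
    d[0] = p.ks - p.k_bind * B + p.k_unbind * C00 - deg * B
    # the four phospho-forms of the cyclin B-Cdk1 complex
    d[1] = (p.k_bind * B - p.k_unbind * C00
            - v_wee * C00 + v_25 * CY
            - p.k_cak * C00 + p.k_pp * CT - deg * C00)
    d[2] = v_wee * C00 - v_25 * CY - p.k_cak * CY + p.k_pp * CYT - deg * CY
    d[3] = p.k_cak * C00 - p.k_pp * CT - v_wee * CT + v_25 * CYT - deg * CT
    d[4] = p.k_cak * CY - p.k_pp * CYT + v_wee * CT - v_25 * CYT - deg * CYT
    # regulators: Cdk1-driven (de)activation, first-order reversion
    d[5] = (p.kc25_on * _hill(CT, p.K_cdc25, p.n_cdc25) * (p.cdc25_total - c25)
            - p.kc25_off * c25)
    d[6] = (p.kwee_on * (p.wee1_total - w1)
            - p.kwee_off * _hill(CT, p.K_wee1, p.n_wee1) * w1)
    d[7] = (p.kplx_on * _hill(CT, p.K_plx, p.n_plx) * (p.plx1_total - plx)
            - p.kplx_off * plx)
    d[8] = apc_gate * (p.kapc_on * _hill(plx, p.K_apc, p.n_apc)
                       * (p.apc_total - apc) - p.kapc_off * apc)
    return d


def reaction_derivatives(state: SpeciesState, params: KineticParams,
                         apc_gate: float = 1.0) -> SpeciesState:
    """Per-species time derivatives for a single validated state."""
    state.validate(params)
    d = reaction_rhs(state.as_array(), params, apc_gate)
    return SpeciesState(*d.tolist())


@dataclasses.dataclass
class Trajectory:
    """A time-stamped homogeneous trajectory: ``y[i, k]`` is species ``i``
    at time ``t[k]`` (minutes)."""

    t: np.ndarray
    y: np.ndarray

    def species(self, name: str) -> np.ndarray:
        return self.y[IDX[name]]


def integrate_homogeneous(state0: SpeciesState | np.ndarray,
                          params: KineticParams,
                          t_end: float,
                          t_eval: np.ndarray | None = None,
                          apc_gate: float = 1.0,
                          rtol: float = 1e-8,
                          atol: float = 1e-10) -> Trajectory:
    """Integrate the well-mixed system with an adaptive embedded
    Runge-Kutta pair (Dormand-Prince 4(5)).

    Output is sampled on ``t_eval`` (default: every 0.05 min).  Raises
    ``RuntimeError`` carrying the failure time if the integrator cannot
    proceed.
    """
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    if isinstance(state0, SpeciesState):
        state0.validate(params)
        y0 = state0.as_array()
    else:
        y0 = np.asarray(state0, dtype=float)
        SpeciesState.from_array(y0).validate(params)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, int(round(t_end / 0.05)) + 1)
    sol = solve_ivp(lambda t, y: reaction_rhs(y, params, apc_gate),
                    (0.0, t_end), y0, t_eval=t_eval, method="RK45",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t = {sol.t[-1]:.4f} min: "
                           f"{sol.message}")
    return Trajectory(sol.t, sol.y)


def upward_crossings(t: np.ndarray, s: np.ndarray, threshold: float) -> np.ndarray:
    """Times where ``s`` crosses ``threshold`` upward, linearly interpolated."""
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    below = s[:-1] < threshold
    above = s[1:] >= threshold
    i = np.where(below & above)[0]
    frac = (threshold - s[i]) / (s[i + 1] - s[i])
    return t[i] + frac * (t[i + 1] - t[i])


@dataclasses.dataclass(frozen=True)
class LimitCycleSummary:
    """Shape of one settled oscillation cycle.

    ``period`` is the mean interval between upward half-maximum crossings
    of the inactive, doubly phosphorylated complex; ``metaphase_time`` is
    the time of the active-Cdk1 peak within the cycle (measured from the
    crossing that opens the cycle); ``division_threshold`` is the
    half-maximum of ``cycB_cdk1_YpTp`` used as the division criterion.
    """

    period: float
    metaphase_time: float
    species_min: dict[str, float]
    species_max: dict[str, float]
    division_threshold: float
    metaphase_state: SpeciesState
    oscillatory: bool = True

    def __post_init__(self):
        if self.oscillatory:
            if not self.period > 0:
                raise ValueError("period must be positive")
            lo = self.species_min["cycB_cdk1_YpTp"]
            hi = self.species_max["cycB_cdk1_YpTp"]
            if not (lo < self.division_threshold < hi):
                raise ValueError("division threshold must lie strictly "
                                 "between the species extrema")


def find_limit_cycle(params: KineticParams,
                     burn_in_cycles: int = 10,
                     measure_cycles: int = 6,
                     period_guess: float = 40.0,
                     amplitude_floor: float = 1e-3,
                     rtol: float = 1e-8,
                     atol: float = 1e-10) -> LimitCycleSummary:
    """Characterize the free-running limit cycle.

    The system is integrated past transients (``burn_in_cycles`` times the
    period guess), the period is measured as the mean interval between
    successive upward half-maximum crossings of ``cycB_cdk1_YpTp`` over at
    least ``measure_cycles`` cycles, and per-species extrema plus the
    metaphase point (peak of active Cdk1) are recorded.

    Damped or non-oscillatory kinetics are reported as a summary with
    ``oscillatory=False`` (period ``nan``), not as an exception.
    """
    t_end = (burn_in_cycles + measure_cycles + 2) * period_guess
    y0 = np.zeros(N_SPECIES)
    y0[IDX["wee1_active"]] = params.wee1_total
    traj = integrate_homogeneous(y0, params, t_end, rtol=rtol, atol=atol)
    burn = burn_in_cycles * period_guess
    m = traj.t >= burn
    tt, yy = traj.t[m], traj.y[:, m]
    s = yy[IDX["cycB_cdk1_YpTp"]]
    lo, hi = s.min(), s.max()
    threshold = 0.5 * (lo + hi)
    not_oscillating = LimitCycleSummary(
        period=float("nan"), metaphase_time=float("nan"),
        species_min={n: float(yy[i].min()) for i, n in enumerate(SPECIES)},
        species_max={n: float(yy[i].max()) for i, n in enumerate(SPECIES)},
        division_threshold=threshold if lo < threshold < hi else float("nan"),
        metaphase_state=SpeciesState.from_array(yy[:, -1]),
        oscillatory=False)
    if hi - lo < amplitude_floor:
        return not_oscillating
    crossings = upward_crossings(tt, s, threshold)
    if len(crossings) < measure_cycles + 1:
        return not_oscillating
    intervals = np.diff(crossings)
    # shrinking peak-to-peak amplitude marks damped oscillations
    if intervals.std() > 0.2 * intervals.mean():
        return not_oscillating
    period = float(intervals[-measure_cycles:].mean())
    # metaphase: active-Cdk1 peak within the last full cycle
    t0, t1 = crossings[-2], crossings[-1]
    win = (tt >= t0) & (tt <= t1)
    ct = yy[IDX["cycB_cdk1_Tp"], win]
    i_peak = int(np.argmax(ct))
    metaphase_time = float(tt[win][i_peak] - t0)
    metaphase_state = SpeciesState.from_array(yy[:, np.where(win)[0][i_peak]])
    return LimitCycleSummary(
        period=period,
        metaphase_time=metaphase_time,
        species_min={n: float(yy[i].min()) for i, n in enumerate(SPECIES)},
        species_max={n: float(yy[i].max()) for i, n in enumerate(SPECIES)},
        division_threshold=float(threshold),
        metaphase_state=metaphase_state,
    )


def csf_arrested_state(params: KineticParams,
                       summary: LimitCycleSummary | None = None,
                       horizon: float = 5000.0,
                       residual_tol: float = 1e-8) -> SpeciesState:
    """Pre-fertilization steady state under cytostatic-factor arrest.

    Starting from the metaphase point of the limit cycle, the CSF-modified
    system — the active-APC rate equation gated off, freezing ``apc_active``
    at its metaphase value — is integrated until every derivative magnitude
    falls below ``residual_tol``.  Raises ``RuntimeError`` carrying the
    residual norm if the state has not converged within ``horizon`` minutes.
    """
    if summary is None:
        summary = find_limit_cycle(params)
    if not summary.oscillatory:
        raise ValueError("cannot arrest: parameters are not oscillatory")
    y = summary.metaphase_state.as_array()
    t_done = 0.0
    chunk = 500.0
    while t_done < horizon:
        traj = integrate_homogeneous(y, params, chunk, apc_gate=0.0,
                                     rtol=1e-10, atol=1e-12)
        y = traj.y[:, -1]
        t_done += chunk
        residual = float(np.abs(reaction_rhs(y, params, 0.0)).max())
        if residual < residual_tol:
            state = SpeciesState.from_array(y)
            state.validate(params)
            return state
    raise RuntimeError(f"CSF arrest did not converge within {horizon} min; "
                       f"residual derivative norm {residual:.3e}")


def tune_ks_for_period(params: KineticParams, target_period: float,
                       rel_tol: float = 1e-3,
                       max_iter: int = 12) -> KineticParams:
    """Find the cyclin synthesis rate giving a requested period.

    Exploits the near-inverse proportionality T ~ 1/ks for the initial
    secant steps and polishes with a bracketed root find.  Used e.g. for
    the short-period (Drosophila-like) regime.
    """
    def T_of(ks: float, guess: float) -> float:
        s = find_limit_cycle(params.replace(ks=ks), period_guess=guess)
        if not s.oscillatory:
            raise RuntimeError(f"no limit cycle at ks = {ks:.4g}")
        return s.period

    ks = params.ks
    T = T_of(ks, 40.0)
    for _ in range(max_iter):
        if abs(T - target_period) <= rel_tol * target_period:
            return params.replace(ks=ks)
        ks_new = ks * T / target_period
        ks, T = ks_new, T_of(ks_new, max(target_period, 10.0))
    raise RuntimeError(f"period tuning did not converge: T = {T:.4g} at "
                       f"ks = {ks:.4g}")
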