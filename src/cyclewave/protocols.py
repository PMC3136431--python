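"""Canonical study protocols.

Each function runs one of the package's headline computations at a fixed,
documented problem size (grid spacing, time step, classification window)
chosen so the full battery completes on a single desktop CPU; the methods
note records these sizes and the convergence checks that guard them.  The
acceptance script and the acceptance test suite both call these functions,
so reported numbers and asserted numbers are computed identically.
"""
from __future__ import annotations

import numpy as np

from .config import Geometry1D, Geometry3D, Numerics, SimConfig, TriggerConfig
from .diagnostics import (correlation_length, division_count_map,
                          frequency_doubling_index, space_time_correlation)
from .kinetics import csf_arrested_state, find_limit_cycle, tune_ks_for_period
from .params import KineticParams, default_params
from .solver1d import critical_speed_search, run_1d
from .solver3d import run_3d

__all__ = [
    "prepare", "homogeneous_period", "first_division_sphere",
    "fast_wave_division_counts", "critical_speed_1mm",
    "minimum_chaotic_size_bounds", "prolate_critical_transit",
    "drosophila_transit_ratio", "chaos_structure",
    "slow_wave_cellularization", "SLOW_WAVE_3D_MM_MIN",
]

#: "slow" calcium wave for the cellularization protocol, chosen well below
#: this model's own critical speed (~0.07 mm/min for the 1 mm embryo)
SLOW_WAVE_3D_MM_MIN = 0.02

_NUM = Numerics(dt_s=2.0)

#: slow-speed anchor candidates for the critical-speed searches (mm/min);
#: asynchrony occupies a band, so several slow speeds are probed in order
ANCHORS = (0.04, 0.015, 0.06, 0.025, 0.008)


def prepare(params: KineticParams | None = None):
    p = params if params is not None else default_params()
    lc = find_limit_cycle(p)
    arrest = csf_arrested_state(p, lc)
    return p, (lc, arrest.as_array())


def homogeneous_period(params: KineticParams | None = None) -> float:
    """Free-running inter-division interval (min) from a pure ODE run."""
    p = params if params is not None else default_params()
    return find_limit_cycle(p).period


def first_division_sphere(params=None, precomputed=None,
                          speed_mm_min: float = 0.25,
                          spacing_um: float = 30.0) -> float:
    """Time of the first surface division (min after fertilization) on the
    1 mm sphere (axisymmetric) under a 1 mm / 4 min calcium wave."""
    p, pre = (params, precomputed) if precomputed else prepare(params)
    cfg = SimConfig(geometry=Geometry3D(kind="sphere", diameter_mm=1.0,
                                        spacing_um=spacing_um),
                    trigger=TriggerConfig(kind="wave",
                                          speed_mm_min=speed_mm_min),
                    numerics=_NUM, t_end_min=75.0, output_every_min=0.25)
    res = run_3d(cfg, params=p, precomputed=pre)
    rec, _ = division_count_map(res.surface_t, res.surface_cyt,
                                pre[0].division_threshold,
                                positions=res.surface_x_mm)
    return float(min(tj[0] for tj in rec.times if len(tj)))


def fast_wave_division_counts(params=None, precomputed=None,
                              speed_mm_min: float = 0.4) -> np.ndarray:
    """Per-position division counts of the fast-wave 1 mm 1D embryo over
    8 hours."""
    p, pre = (params, precomputed) if precomputed else prepare(params)
    cfg = SimConfig(geometry=Geometry1D(length_mm=1.0, dx_um=20.0),
                    trigger=TriggerConfig(kind="wave",
                                          speed_mm_min=speed_mm_min),
                    numerics=_NUM, t_end_min=480.0, output_every_min=0.25)
    res = run_1d(cfg, params=p, precomputed=pre)
    return res.divisions.counts


def _search_cfg(length_mm: float, t_end: float = 360.0) -> SimConfig:
    return SimConfig(geometry=Geometry1D(length_mm=length_mm, dx_um=20.0),
                     trigger=TriggerConfig(kind="wave", speed_mm_min=0.1),
                     numerics=_NUM, t_end_min=t_end, output_every_min=0.5)


def critical_speed_1mm(params=None, length_mm: float = 1.0,
                       v_hi: float = 0.3, rel_tol: float = 0.1):
    """Critical calcium-wave speed of the 1D embryo (6-hour classification
    runs, slow-anchor scan then bisection).  ``v_c`` is in mm/min."""
    p = params if params is not None else default_params()
    return critical_speed_search(_search_cfg(length_mm), ANCHORS, v_hi,
                                 rel_tol=rel_tol, params=p)


def minimum_chaotic_size_bounds(params=None,
                                lengths=(0.3, 0.52, 1.0)) -> dict:
    """Which embryo lengths synchronize at any wave speed: for each length
    the status of a search over the slow-anchor grid."""
    p = params if params is not None else default_params()
    out = {}
    for L in lengths:
        res = critical_speed_search(_search_cfg(L), ANCHORS, 0.3,
                                    rel_tol=0.15, params=p)
        out[L] = res.status
    return out


def prolate_critical_transit(params=None) -> float | None:
    """Critical transit time (min) of the 1 x 0.5 mm prolate embryo
    (axisymmetric 3D, 6-hour classification runs)."""
    p = params if params is not None else default_params()
    cfg = SimConfig(geometry=Geometry3D(kind="prolate", diameter_mm=1.0,
                                        minor_axis_mm=0.5, spacing_um=40.0),
                    trigger=TriggerConfig(kind="wave", speed_mm_min=0.1),
                    numerics=_NUM, t_end_min=360.0, output_every_min=0.5)
    res = critical_speed_search(cfg, ANCHORS, 0.4, rel_tol=0.1, params=p)
    return None if res.v_c is None else 1.0 / res.v_c


def drosophila_transit_ratio(params=None) -> dict:
    """Short-period (T = 10 min) regime: tune the cyclin synthesis rate,
    then measure the critical transit time relative to the period."""
    p = params if params is not None else default_params()
    p10 = tune_ks_for_period(p, 10.0)
    T = find_limit_cycle(p10, period_guess=10.0).period
    res = critical_speed_search(_search_cfg(1.0), ANCHORS, 0.8, rel_tol=0.1,
                                params=p10)
    transit = None if res.v_c is None else 1.0 / res.v_c
    return {"period_min": T, "transit_min": transit,
            "transit_over_period": None if transit is None else transit / T}


def chaos_structure(params=None, precomputed=None,
                    speed_mm_min: float = SLOW_WAVE_3D_MM_MIN,
                    t_end: float = 600.0,
                    window=(200.0, 600.0)) -> dict:
    """The 6 mm periodic chaotic run: correlation length (1/e convention),
    division-count heterogeneity, and the frequency-doubling index of the
    pooled inter-division intervals (None if the chaotic regime yields too
    few division events for a stable estimate)."""
    p, pre = (params, precomputed) if precomputed else prepare(params)
    cfg = SimConfig(geometry=Geometry1D(length_mm=6.0, dx_um=10.0,
                                        bc="periodic"),
                    trigger=TriggerConfig(kind="wave",
                                          speed_mm_min=speed_mm_min),
                    numerics=_NUM, t_end_min=t_end, output_every_min=1.0)
    res = run_1d(cfg, params=p, precomputed=pre)
    S = res.kymograph.data["cycB_cdk1_YpTp"]
    surf = space_time_correlation(res.kymograph.t, S, 0.01, window,
                                  periodic=True, max_dx=3.0, max_dt=120.0)
    xi = correlation_length(surf)
    rec = res.divisions.in_window(*window)
    try:
        fd = frequency_doubling_index(rec.times)
    except ValueError:
        fd = None
    counts = res.divisions.counts
    return {"xi_mm": xi, "heterogeneity": int(counts.max() - counts.min()),
            "counts_min": int(counts.min()), "counts_max": int(counts.max()),
            "frequency_doubling": fd}


def slow_wave_cellularization(params=None, precomputed=None,
                              speed_mm_min: float = SLOW_WAVE_3D_MM_MIN,
                              t_end: float = 320.0,
                              spacing_um: float = 70.0) -> dict:
    """Cellularized tetrahedral 1 mm embryo under a slow wave: ordering of
    the second cleavage round (distal vs proximal hemisphere) and whether
    any lineage stops dividing while others continue."""
    p, pre = (params, precomputed) if precomputed else prepare(params)
    cfg = SimConfig(geometry=Geometry3D(kind="tet_ball", diameter_mm=1.0,
                                        spacing_um=spacing_um),
                    trigger=TriggerConfig(kind="wave",
                                          speed_mm_min=speed_mm_min),
                    numerics=Numerics(dt_s=2.5), t_end_min=t_end,
                    output_every_min=1.0, cellularize=True)
    res = run_3d(cfg, params=p, precomputed=pre)
    # the first cleavage splits the embryo across the fertilization axis:
    # daughter labels 1 (proximal, x < plane) and 2 (distal, x > plane)
    t_proximal = res.cells[1].division_times[0] if res.cells[1].division_times else None
    t_distal = res.cells[2].division_times[0] if res.cells[2].division_times else None
    live = [c for c in res.cells.values() if c.alive]
    last_div = [max(c.division_times) if c.division_times else c.born_min
                for c in live]
    window = 2.5 * pre[0].period
    arrested = [t_end - t > window for t in last_div]
    dividing = [t_end - t <= window for t in last_div]
    return {
        "second_round_proximal_min": t_proximal,
        "second_round_distal_min": t_distal,
        "distal_leads_by_min": (None if t_proximal is None or t_distal is None
                                else t_proximal - t_distal),
        "n_cells": len(live),
        "any_lineage_arrested": bool(any(arrested) and any(dividing)),
    }
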