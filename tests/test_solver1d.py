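"""1D reaction-diffusion solver: schemes, conservation, triggers, chaos."""
import numpy as np
import pytest

from cyclewave.config import Geometry1D, Numerics, SimConfig, TriggerConfig
from cyclewave.kinetics import IDX, N_SPECIES, integrate_homogeneous
from cyclewave.solver1d import (Grid1D, _Diffusion1D, critical_speed_search,
                                ftcs_stability_limit, run_1d, step_rd)


def make_config(length=1.0, dx=20.0, dt=2.0, t_end=120.0, method="crank_nicolson",
                trigger=None, bc="noflux", out_every=0.25):
    return SimConfig(
        geometry=Geometry1D(length_mm=length, dx_um=dx, bc=bc),
        trigger=trigger or TriggerConfig(kind="instantaneous"),
        numerics=Numerics(dt_s=dt, method=method),
        t_end_min=t_end, output_every_min=out_every)


def trapezoid_weights(n, periodic):
    w = np.ones(n)
    if not periodic:
        w[0] = w[-1] = 0.5
    return w


def test_grid_requires_commensurate_spacing():
    with pytest.raises(ValueError):
        Grid1D(length_mm=1.0, dx_um=33.0)
    assert Grid1D(length_mm=1.0, dx_um=20.0).n_nodes == 51
    assert Grid1D(length_mm=1.0, dx_um=20.0, bc="periodic").n_nodes == 50


def test_uniform_field_stays_uniform(params, prepared):
    """No trigger gradient: spatial symmetry is preserved to round-off."""
    _, arrest = prepared
    grid = Grid1D(1.0, 20.0)
    diff = _Diffusion1D(grid, params.D * 60.0, (1.0 / 60.0) / 2.0,
                        "crank_nicolson")
    y = np.tile(arrest[:, None], (1, grid.n_nodes))
    gate = np.ones(grid.n_nodes)
    for _ in range(1000):
        y = step_rd(y, 1.0 / 60.0, diff, params, gate)
    assert np.abs(y - y[:, :1]).max() < 1e-9 * np.abs(y).max()


@pytest.mark.parametrize("bc", ["noflux", "periodic"])
@pytest.mark.parametrize("method", ["crank_nicolson", "ftcs"])
def test_diffusion_only_conserves_total(params, rng, bc, method):
    """Reactions off: each species' discrete total is conserved to 1e-10
    relative over 1000 steps."""
    grid = Grid1D(1.0, 20.0, bc)
    dt = 0.2 / 60.0  # s in minutes, safely below the FTCS limit
    diff = _Diffusion1D(grid, params.D * 60.0, dt / 2.0, method)
    y = rng.uniform(0.5, 2.0, (N_SPECIES, grid.n_nodes))
    w = trapezoid_weights(grid.n_nodes, bc == "periodic")
    tot0 = y @ w
    for _ in range(1000):
        y = step_rd(y, dt, diff, params, np.ones(grid.n_nodes),
                    reactions=False)
    np.testing.assert_allclose(y @ w, tot0, rtol=1e-10)


def test_zero_diffusion_matches_homogeneous_ode(params, prepared):
    """D = 0: every node follows the well-mixed trajectory within 0.1%
    over one period."""
    lc, arrest = prepared
    p0 = params.replace(D=0.0)
    cfg = make_config(t_end=lc.period, dt=1.0)
    res = run_1d(cfg, params=p0, precomputed=prepared)
    ref = integrate_homogeneous(arrest, p0, lc.period,
                                t_eval=res.kymograph.t)
    cyt = res.kymograph.data["cycB_cdk1_YpTp"]
    scale = ref.species("cycB_cdk1_YpTp").max()
    err = np.abs(cyt - ref.species("cycB_cdk1_YpTp")[:, None]).max()
    assert err < 1e-3 * scale


def test_ftcs_stability_checked_up_front(params, prepared):
    limit = ftcs_stability_limit(20.0, params.D)
    cfg = make_config(method="ftcs", dt=2.0 * limit, t_end=10.0)
    with pytest.raises(ValueError, match="FTCS"):
        run_1d(cfg, params=params, precomputed=prepared)


def test_ftcs_and_crank_nicolson_agree(params, prepared):
    """Division times agree within 1% between the two schemes in the
    synchronous regime."""
    t_end = 130.0
    res = {}
    for method in ("crank_nicolson", "ftcs"):
        cfg = make_config(method=method, dt=2.0, t_end=t_end)
        res[method] = run_1d(cfg, params=params, precomputed=prepared)
    for j in (0, 25, 50):
        a = res["crank_nicolson"].divisions.times[j]
        b = res["ftcs"].divisions.times[j]
        assert len(a) == len(b) >= 3
        np.testing.assert_allclose(a, b, rtol=0.01)


def test_refinement_convergence(params, prepared):
    """Halving dt, and separately dx, moves division times < 1%."""
    base = run_1d(make_config(dt=2.0, dx=20.0, t_end=100.0), params=params,
                  precomputed=prepared)
    half_dt = run_1d(make_config(dt=1.0, dx=20.0, t_end=100.0), params=params,
                     precomputed=prepared)
    half_dx = run_1d(make_config(dt=2.0, dx=10.0, t_end=100.0), params=params,
                     precomputed=prepared)
    t0 = base.divisions.times[0]
    np.testing.assert_allclose(half_dt.divisions.times[0], t0, rtol=0.01)
    np.testing.assert_allclose(half_dx.divisions.times[0][: len(t0)], t0,
                               rtol=0.01)


def test_instantaneous_equals_whole_domain_spreading(params, prepared):
    """With the whole domain initially active, the spreading trigger and
    the instantaneous wave produce identical trajectories."""
    cfg_a = make_config(t_end=60.0)
    cfg_b = make_config(t_end=60.0, trigger=TriggerConfig(
        kind="spreading", active_fraction=1.0))
    a = run_1d(cfg_a, params=params, precomputed=prepared)
    b = run_1d(cfg_b, params=params, precomputed=prepared)
    np.testing.assert_allclose(a.kymograph.data["cycB_cdk1_YpTp"],
                               b.kymograph.data["cycB_cdk1_YpTp"],
                               rtol=1e-12, atol=1e-12)


def test_spreading_trigger_propagates_as_traveling_front(params, prepared):
    """Seeding the terminal 10% of the embryo lets activity spread across
    the whole domain at a roughly constant velocity via diffusion and the
    4x threshold latch, with chaos (not uniform divisions) in its wake."""
    cfg = make_config(t_end=200.0, out_every=1.0, trigger=TriggerConfig(
        kind="spreading", threshold_factor=4.0, active_fraction=0.1))
    cfg = cfg.model_copy(update={"record_species": ["cycB_cdk1_YpTp",
                                                    "cycB_cdk1_Tp"]})
    res = run_1d(cfg, params=params, precomputed=prepared)
    ct = res.kymograph.data["cycB_cdk1_Tp"]
    threshold = cfg.trigger.threshold_factor * res.arrest[3]
    reached = (ct >= threshold).any(axis=0)
    assert reached.all()  # the latch front crosses the whole embryo
    t_first = res.kymograph.t[np.argmax(ct >= threshold, axis=0)]
    # front arrives later the farther from the seeded (right) end
    sampled = t_first[::10]
    assert np.all(np.diff(sampled) < 0.0)
    # the seeded end divides first; the chaotic wake is not uniform (the
    # arrested bulk drains cyclin from the small active region, so early
    # division counts stay low — Fig-1-style spread is chaotic, not clean)
    counts = res.divisions.counts
    assert counts[-1] >= 1
    assert counts[0] <= counts[-1]
    assert counts.max() - counts.min() >= 1


def test_slow_wave_perturbations_amplify(params, prepared):
    """In the slow-wave (irregular) regime a 1e-6 relative perturbation of
    one node's free cyclin is amplified by orders of magnitude, in sharp
    contrast to the synchronous regime where perturbations only decay.
    The perturbed node is the one released at t = 0: ahead of the front
    the arrested medium is strongly contracting and would erase the
    perturbation before the wave arrives."""
    lc, arrest = prepared
    cfg = make_config(dx=20.0, dt=2.0, t_end=420.0, trigger=TriggerConfig(
        kind="wave", speed_mm_min=1.0 / 60.0), out_every=2.0)
    n = int(cfg.geometry.length_mm * 1000 / cfg.geometry.dx_um) + 1
    y0 = np.tile(arrest[:, None], (1, n))
    y1 = y0.copy()
    y1[IDX["cycB_free"], 0] *= 1.0 + 1e-6
    a = run_1d(cfg, params=params, precomputed=prepared, initial_field=y0)
    b = run_1d(cfg, params=params, precomputed=prepared, initial_field=y1)
    diff = np.abs(a.kymograph.data["cycB_cdk1_YpTp"]
                  - b.kymograph.data["cycB_cdk1_YpTp"])
    t = a.kymograph.t
    early = diff[(t > 40.0) & (t < 120.0)].max()
    late = diff[t > 240.0].max()
    assert early > 0.0
    assert late > 1e3 * early


def test_identical_configs_reproduce_bitwise(params, prepared):
    cfg = make_config(t_end=45.0)
    a = run_1d(cfg, params=params, precomputed=prepared)
    b = run_1d(cfg, params=params, precomputed=prepared)
    assert np.array_equal(a.kymograph.data["cycB_cdk1_YpTp"],
                          b.kymograph.data["cycB_cdk1_YpTp"])


def test_critical_speed_requires_bracketing(params):
    cfg = make_config(t_end=360.0, trigger=TriggerConfig(
        kind="wave", speed_mm_min=0.1), out_every=0.5)
    with pytest.raises(ValueError, match="bracket"):
        # both endpoints below the critical speed: neither synchronizes
        critical_speed_search(cfg, 0.04, 0.06, params=params)


def test_small_domain_below_minimum_chaotic_size(params):
    """A short embryo synchronizes even for very slow waves."""
    cfg = make_config(length=0.3, t_end=200.0, trigger=TriggerConfig(
        kind="wave", speed_mm_min=0.1))
    res = critical_speed_search(cfg, 0.01, 0.5, params=params)
    assert res.status == "below_minimum_chaotic_size"
    assert res.v_c is None
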