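"""Embryo meshes, finite-element diffusion and cellularized 3D runs."""
import numpy as np
import pytest

from cyclewave.config import Geometry3D, Numerics, SimConfig, TriggerConfig
from cyclewave.kinetics import integrate_homogeneous
from cyclewave.meshes import build_mesh, split_cell, tet_quality
from cyclewave.solver3d import FemRegion, assemble_diffusion_operator, run_3d


@pytest.fixture(scope="module")
def sphere_mesh():
    return build_mesh("sphere", diameter_mm=1.0, spacing_um=20.0)


@pytest.fixture(scope="module")
def tet_mesh():
    return build_mesh("tet_ball", diameter_mm=1.0, spacing_um=60.0)


def test_sphere_volume_matches_analytic(sphere_mesh):
    analytic = np.pi * 1000.0 ** 3 / 6.0  # pi d^3 / 6, d = 1 mm in um
    assert sphere_mesh.total_volume() == pytest.approx(analytic, rel=0.01)


def test_prolate_volume_matches_analytic():
    m = build_mesh("prolate", diameter_mm=1.0, minor_axis_mm=0.5,
                   spacing_um=20.0)
    analytic = np.pi * 1000.0 ** 3 / 24.0  # (4/3) pi a b^2, a=500, b=250
    assert m.total_volume() == pytest.approx(analytic, rel=0.01)


def test_tet_ball_volume_and_quality(tet_mesh):
    analytic = np.pi * 1000.0 ** 3 / 6.0
    assert tet_mesh.total_volume() == pytest.approx(analytic, rel=0.01)
    assert tet_quality(tet_mesh.vertices, tet_mesh.elements).min() > 0.04


def test_degenerate_spacing_rejected():
    with pytest.raises(ValueError):
        build_mesh("sphere", diameter_mm=0.1, spacing_um=200.0)


def test_operator_annihilates_constants(sphere_mesh):
    reg = assemble_diffusion_operator(sphere_mesh)
    const = np.full(len(reg.global_vertices), 3.7)
    out = reg.apply_operator(const)
    assert np.abs(out).max() < 1e-10 * np.abs(reg.K.data).max()


@pytest.mark.parametrize("mesh_name", ["sphere_mesh", "tet_mesh"])
def test_diffusion_conserves_weighted_total(mesh_name, request, rng):
    reg = FemRegion(request.getfixturevalue(mesh_name), 0)
    reg.prepare(600.0, 1.0 / 60.0)
    y = rng.uniform(0.5, 2.0, (2, len(reg.global_vertices)))
    tot0 = y @ reg.M
    for _ in range(1000):
        y = reg.diffuse_half(y)
    np.testing.assert_allclose(y @ reg.M, tot0, rtol=1e-8)
    assert np.all(np.isfinite(y))


def test_thin_rod_axial_decay_matches_reduced_1d_operator():
    """A high-aspect prolate behaves like a 1D rod of varying
    cross-section: the slowest axial mode decays at the smallest nonzero
    eigenvalue of the reduced operator (A u')' / A, computed here by an
    independent finite-difference eigensolve, within 2%."""
    from scipy.linalg import eigh
    a, b = 500.0, 25.0  # semi-axes, um
    # independent 1D reference: generalized eigenproblem K u = lam B u
    n = 400
    xe = np.linspace(-a, a, n + 1)
    xc = 0.5 * (xe[:-1] + xe[1:])
    dx = xe[1] - xe[0]
    area = np.pi * b ** 2 * np.clip(1.0 - (xc / a) ** 2, 1e-12, None)
    a_face = np.pi * b ** 2 * np.clip(1.0 - (xe[1:-1] / a) ** 2, 0.0, None)
    K = np.zeros((n, n))
    for i in range(n - 1):
        K[i, i] += a_face[i] / dx
        K[i + 1, i + 1] += a_face[i] / dx
        K[i, i + 1] -= a_face[i] / dx
        K[i + 1, i] -= a_face[i] / dx
    B = np.diag(area * dx)
    lam = eigh(K, B, eigvals_only=True)
    lam1 = lam[1]  # smallest nonzero (slowest odd mode)

    m = build_mesh("prolate", diameter_mm=1.0, minor_axis_mm=2 * b / 1000.0,
                   spacing_um=12.0)
    reg = FemRegion(m, 0)
    D = 600.0  # um^2/min
    dt_half = 0.5  # min; decay times are ~100 min, CN error ~ (lam*dt)^2
    reg.prepare(D, dt_half)
    x = reg.coords[:, 0]
    y = (x / a)[None, :]

    def amplitude(u):
        return float(reg.M @ (u * x))

    for _ in range(100):  # 50 min: let faster modes die out
        y = reg.diffuse_half(y)
    a0 = amplitude(y[0])
    n_steps = 200
    for _ in range(n_steps):
        y = reg.diffuse_half(y)
    a1 = amplitude(y[0])
    rate = -np.log(a1 / a0) / (n_steps * dt_half)
    assert rate == pytest.approx(D * lam1, rel=0.02)


def test_uniform_gate_keeps_field_uniform(params, prepared, sphere_mesh):
    cfg = SimConfig(geometry=Geometry3D(kind="sphere", spacing_um=20.0),
                    trigger=TriggerConfig(kind="instantaneous"),
                    numerics=Numerics(dt_s=2.0), t_end_min=30.0,
                    output_every_min=1.0)
    res = run_3d(cfg, params=params, mesh=sphere_mesh, precomputed=prepared)
    cyt = res.surface_cyt
    assert np.abs(cyt - cyt[:, :1]).max() < 1e-6 * np.abs(cyt).max()


def test_zero_diffusion_matches_homogeneous_ode(params, prepared, sphere_mesh):
    lc, arrest = prepared
    p0 = params.replace(D=0.0)
    cfg = SimConfig(geometry=Geometry3D(kind="sphere", spacing_um=20.0),
                    trigger=TriggerConfig(kind="instantaneous"),
                    numerics=Numerics(dt_s=2.0), t_end_min=lc.period,
                    output_every_min=0.5)
    res = run_3d(cfg, params=p0, mesh=sphere_mesh, precomputed=prepared)
    ref = integrate_homogeneous(arrest, p0, lc.period,
                                t_eval=np.asarray(res.cells[0].times))
    avg = np.asarray(res.cells[0].avg_cyt)
    scale = ref.species("cycB_cdk1_YpTp").max()
    assert np.abs(avg - ref.species("cycB_cdk1_YpTp")).max() < 1e-3 * scale


def test_instantaneous_wave_divides_surface_synchronously(params, prepared,
                                                          sphere_mesh):
    from cyclewave.diagnostics import division_count_map
    lc, _ = prepared
    cfg = SimConfig(geometry=Geometry3D(kind="sphere", spacing_um=20.0),
                    trigger=TriggerConfig(kind="instantaneous"),
                    numerics=Numerics(dt_s=2.0), t_end_min=25.0,
                    output_every_min=0.25)
    res = run_3d(cfg, params=params, mesh=sphere_mesh, precomputed=prepared)
    rec, _ = division_count_map(res.surface_t, res.surface_cyt,
                                lc.division_threshold)
    firsts = np.array([tj[0] for tj in rec.times])
    assert firsts.max() - firsts.min() <= cfg.output_every_min


def test_axisym_and_tet_first_division_agree(params, prepared, tet_mesh,
                                             sphere_mesh):
    """Revolved-section and tetrahedral discretizations of the same sphere
    agree on the first division time within 2%."""
    out = {}
    for name, mesh, kind in (("axi", sphere_mesh, "sphere"),
                             ("tet", tet_mesh, "tet_ball")):
        cfg = SimConfig(
            geometry=Geometry3D(kind=kind, spacing_um=60.0),
            trigger=TriggerConfig(kind="wave", speed_mm_min=0.25),
            numerics=Numerics(dt_s=2.0), t_end_min=25.0,
            output_every_min=0.25)
        res = run_3d(cfg, params=params, mesh=mesh, precomputed=prepared)
        out[name] = res.cells[0].division_times[0]
    assert out["tet"] == pytest.approx(out["axi"], rel=0.02)


def test_mesh_refinement_convergence(params, prepared):
    """Halving the axisymmetric spacing moves the first division < 1%."""
    t_first = {}
    for spacing in (40.0, 20.0):
        cfg = SimConfig(geometry=Geometry3D(kind="sphere",
                                            spacing_um=spacing),
                        trigger=TriggerConfig(kind="wave",
                                              speed_mm_min=0.25),
                        numerics=Numerics(dt_s=2.0), t_end_min=25.0,
                        output_every_min=0.25)
        res = run_3d(cfg, params=params, precomputed=prepared)
        t_first[spacing] = res.cells[0].division_times[0]
    assert t_first[20.0] == pytest.approx(t_first[40.0], rel=0.01)


def test_equal_volume_division_planes(tet_mesh):
    """Three alternating-axis cleavages produce eight near-equal cells."""
    import copy
    mesh = copy.deepcopy(tet_mesh)
    plane = split_cell(mesh, 0, [1.0, 0.0, 0.0])
    v = [mesh.total_volume(l) for l in plane.daughter_labels]
    assert abs(v[0] - v[1]) / (v[0] + v[1]) < 0.01
    for lbl, normal in ((plane.daughter_labels[0], [0, 1, 0]),
                        (plane.daughter_labels[1], [0, 1, 0])):
        p2 = split_cell(mesh, lbl, normal)
        for l2 in p2.daughter_labels:
            split_cell(mesh, l2, [0, 0, 1])
    finals = mesh.labels
    vols = np.array([mesh.total_volume(l) for l in finals])
    assert len(finals) == 8
    assert vols.max() / vols.min() < 1.1
    total = tet_mesh.total_volume()
    assert vols.sum() == pytest.approx(total, rel=1e-9)


def test_daughters_conserve_independently(tet_mesh, rng):
    """After cellularization, diffusion conserves each daughter's total
    separately (internal no-flux)."""
    import copy
    mesh = copy.deepcopy(tet_mesh)
    plane = split_cell(mesh, 0, [1.0, 0.0, 0.0])
    totals = {}
    for lbl in plane.daughter_labels:
        reg = FemRegion(mesh, lbl)
        reg.prepare(600.0, 1.0 / 60.0)
        y = rng.uniform(0.5, 2.0, (1, len(reg.global_vertices)))
        t0 = y @ reg.M
        for _ in range(200):
            y = reg.diffuse_half(y)
        np.testing.assert_allclose(y @ reg.M, t0, rtol=1e-8)
        totals[lbl] = float(t0[0])
    assert totals[plane.daughter_labels[0]] != totals[plane.daughter_labels[1]]


def test_three_division_rounds_make_eight_cells(params, prepared):
    """A fast wave with cellularization yields 8 synchronous cells after
    three cleavage rounds."""
    cfg = SimConfig(geometry=Geometry3D(kind="tet_ball", spacing_um=70.0),
                    trigger=TriggerConfig(kind="wave", speed_mm_min=0.25),
                    numerics=Numerics(dt_s=2.5), t_end_min=110.0,
                    output_every_min=1.0, cellularize=True)
    res = run_3d(cfg, params=params, precomputed=prepared)
    assert len(res.divisions.times) == 8
    vols = np.array([res.cells[l].volume
                     for l in sorted(res.cells) if res.cells[l].alive])
    assert vols.max() / vols.min() < 1.15
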