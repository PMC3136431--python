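"""Synthetic spatio-temporal fixtures with known structure.

These generators emulate oscillatory fields with prescribed period,
wavelength and correlation structure, so the chaos diagnostics can be
validated against closed-form expectations independently of the PDE
solver.  Construction parameters are embedded in the returned metadata
(and in file metadata when written to disk).
"""
from __future__ import annotations

import numpy as np

from .solver1d import Kymograph

__all__ = ["plane_wave_field", "exponential_correlation_field",
           "bimodal_event_train", "uniform_field", "generate_fixture"]


def _axes(L_mm: float, dx_mm: float, t_end: float, dt: float):
    x = np.arange(0.0, L_mm, dx_mm)
    t = np.arange(0.0, t_end + dt / 2, dt)
    return t, x


def plane_wave_field(L_mm: float = 2.0, dx_mm: float = 0.01,
                     t_end: float = 200.0, dt: float = 0.5,
                     wavelength_mm: float = 0.5, period_min: float = 40.0,
                     amplitude: float = 1.0, offset: float = 2.0):
    """S(x, t) = offset + A cos(k x - w t): a traveling plane wave whose
    space-time correlation is exactly cos(k dx - w dt)."""
    t, x = _axes(L_mm, dx_mm, t_end, dt)
    k = 2.0 * np.pi / wavelength_mm
    w = 2.0 * np.pi / period_min
    S = offset + amplitude * np.cos(k * x[None, :] - w * t[:, None])
    kymo = Kymograph(t, x, {"cycB_cdk1_YpTp": S})
    return kymo, {"kind": "plane-wave", "k_per_mm": k, "omega_per_min": w,
                  "wavelength_mm": wavelength_mm, "period_min": period_min}


def exponential_correlation_field(L_mm: float = 6.0, dx_mm: float = 0.01,
                                  t_end: float = 400.0, dt: float = 1.0,
                                  xi_mm: float = 0.25, seed: int = 0):
    """Stationary Gaussian field, white in time, with spatial correlation
    exp(-|dx| / xi) synthesized spectrally on a periodic domain."""
    t, x = _axes(L_mm, dx_mm, t_end, dt)
    n = len(x)
    rng = np.random.default_rng(seed)
    q = 2.0 * np.pi * np.fft.rfftfreq(n, d=dx_mm)
    # Lorentzian spectrum <=> exponential correlation
    spectrum = 2.0 * xi_mm / (1.0 + (q * xi_mm) ** 2)
    amp = np.sqrt(spectrum / dx_mm / 2.0)
    white = rng.standard_normal((len(t), len(q))) + \
        1j * rng.standard_normal((len(t), len(q)))
    white[:, 0] = white[:, 0].real * np.sqrt(2.0)
    S = np.fft.irfft(amp * white, n=n, axis=1) * n / np.sqrt(n)
    kymo = Kymograph(t, x, {"cycB_cdk1_YpTp": S})
    return kymo, {"kind": "exponential-correlation", "xi_mm": xi_mm,
                  "seed": seed, "periodic": True}


def bimodal_event_train(n_traces: int = 5, n_pairs: int = 12,
                        interval_short: float = 20.0,
                        interval_long: float = 40.0,
                        t0: float = 10.0):
    """Division-time trains with strictly alternating short/long intervals
    (the frequency-doubling signature; dominant interval ratio = long/short)."""
    times = []
    for _ in range(n_traces):
        iv = np.tile([interval_short, interval_long], n_pairs)
        times.append(t0 + np.cumsum(iv))
    return times, {"kind": "bimodal-event-train",
                   "ratio": interval_long / interval_short,
                   "n_events": n_traces * 2 * n_pairs}


def uniform_field(L_mm: float = 1.0, dx_mm: float = 0.01,
                  t_end: float = 100.0, dt: float = 0.5,
                  period_min: float = 40.0, amplitude: float = 1.0):
    """Spatially uniform oscillation: correlation never decays in space."""
    t, x = _axes(L_mm, dx_mm, t_end, dt)
    S = 2.0 + amplitude * np.cos(2.0 * np.pi * t / period_min)[:, None] \
        * np.ones(len(x))[None, :]
    kymo = Kymograph(t, x, {"cycB_cdk1_YpTp": S})
    return kymo, {"kind": "uniform", "period_min": period_min}


_KINDS = {"plane-wave": plane_wave_field,
          "exponential-correlation": exponential_correlation_field,
          "bimodal-event-train": bimodal_event_train,
          "uniform": uniform_field}


def generate_fixture(kind: str, seed: int = 0, **params):
    """Dispatch by fixture kind; deterministic given the seed."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from "
                         f"{sorted(_KINDS)}")
    if kind == "exponential-correlation":
        params.setdefault("seed", seed)
    return _KINDS[kind](**params)
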