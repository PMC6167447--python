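"""Independent numerical oracles used by the test suite.

The brute-force transform evaluates the defining integral directly as a
fine midpoint Riemann sum over the wavelet support, per shift -- a path
fully independent of the engine's convolution of differenced running
integrals.
"""

from __future__ import annotations

import numpy as np

from wavetrait.spectra_io import N_BANDS, WL_MIN
from wavetrait.wavelet_bank import evaluate_psi, psi_callable, registry_by_name


def _is_sampled(spec) -> bool:
    return spec.kind in ("orthogonal", "biorthogonal") or spec.family == "Meyer"


def brute_force_cwt(f: np.ndarray, name: str, scale_exponent: int,
                    shifts, du_exponent: int = 13) -> np.ndarray:
    """Midpoint Riemann sum of Int f(t) a^-1/2 conj(psi)((t-b)/a) dt.

    ``f`` is piecewise constant on 1-nm cells centred at the integer
    wavelengths and zero outside the measured range.  Complex psi yields
    the modulus, matching the engine's realization.
    """
    spec = registry_by_name()[name]
    a = 2 ** scale_exponent
    if _is_sampled(spec):
        sw = evaluate_psi(spec, 10)
        glo, ghi = sw.grid[0], sw.grid[-1]
    else:
        glo, ghi = spec.support
    c = 0.5 * (glo + ghi)
    du = 2.0 ** -du_exponent
    u = np.arange(glo - c, ghi - c, du) + du / 2
    if _is_sampled(spec):
        psi_u = np.interp(u + c, sw.grid, sw.psi)
    else:
        psi_u = psi_callable(spec)(u + c)
    psi_u = np.conj(psi_u)
    out = np.empty(len(shifts), complex)
    for i, b in enumerate(shifts):
        t = b + a * u
        k = np.floor(t - (WL_MIN - 0.5)).astype(int)
        fv = np.where((k >= 0) & (k < N_BANDS), f[np.clip(k, 0, N_BANDS - 1)], 0.0)
        out[i] = np.sqrt(a) * np.sum(fv * psi_u) * du
    if spec.is_complex:
        return np.abs(out)
    return out.real


def brute_force_ols(x: np.ndarray, y: np.ndarray, refinements: int = 6):
    """Nested grid search minimising the sum of squared residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    span_s = 4 * (np.ptp(y) / max(np.ptp(x), 1e-12) + 1.0)
    span_i = 4 * (np.abs(y).max() + 1.0)
    s0, i0 = 0.0, 0.0
    for _ in range(refinements):
        ss = np.linspace(s0 - span_s, s0 + span_s, 41)
        ii = np.linspace(i0 - span_i, i0 + span_i, 41)
        S, I = np.meshgrid(ss, ii, indexing="ij")
        sse = ((y[None, None, :] - S[..., None] * x[None, None, :] - I[..., None]) ** 2).sum(-1)
        k = np.unravel_index(np.argmin(sse), sse.shape)
        s0, i0 = float(ss[k[0]]), float(ii[k[1]])
        span_s /= 10.0
        span_i /= 10.0
    return s0, i0
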