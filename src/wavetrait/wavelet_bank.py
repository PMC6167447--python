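"""Registry and numerical evaluation of the 108 candidate mother wavelets.

The screening pipeline ranks every mother wavelet of 15 classical families:
Haar, Daubechies (db2-db20), Symlets (sym2-sym17), Coiflets (coif1-coif5),
biorthogonal and reverse-biorthogonal spline pairs, Meyer, Mexican hat,
Morlet, Gaussian derivatives, and the complex Gaussian / Shannon /
frequency-B-spline / Morlet families -- 108 functions in total.

Evaluation contract
-------------------
``evaluate_psi`` renders psi on a uniform grid of step ``2**-J`` over the
wavelet's support.  Compactly supported orthogonal and biorthogonal
wavelets have no closed form; their samples come from the cascade
(successive refinement) algorithm driven by the family's filter
coefficients.  The remaining families are evaluated from their textbook
closed forms; the continuous Meyer wavelet is synthesised from its
analytic Fourier spectrum by direct quadrature.  Normalisation follows the
common toolbox convention (unit L2 norm for cascade output, textbook
constants otherwise).  Any consistent rescaling of psi only rescales
wavelet coefficients linearly and therefore leaves every downstream R^2
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt

__all__ = [
    "WaveletSpec",
    "SampledWavelet",
    "UnknownWaveletError",
    "build_registry",
    "registry_by_name",
    "family_of",
    "evaluate_psi",
    "psi_callable",
    "registry_frame",
]

#: families whose psi is produced by the cascade algorithm
_CASCADE_KINDS = {"orthogonal", "biorthogonal"}

_BIOR_ORDERS = [
    (1, 1), (1, 3), (1, 5),
    (2, 2), (2, 4), (2, 6), (2, 8),
    (3, 1), (3, 3), (3, 5), (3, 7), (3, 9),
    (4, 4), (5, 5), (6, 8),
]
_SHAN_PARAMS = [(1, 0.1), (1, 0.5), (1, 1), (1, 1.5), (2, 3)]
_FBSP_PARAMS = [(1, 1, 0.5), (1, 1, 1), (1, 1, 1.5), (2, 1, 0.1), (2, 1, 0.5), (2, 1, 1)]
_CMOR_PARAMS = [(1, 0.4), (1, 0.5), (1, 1), (1, 1.5), (2, 0.1), (2, 0.5)]


class UnknownWaveletError(KeyError):
    """Requested name is not in the registry."""


@dataclass(frozen=True)
class WaveletSpec:
    """One named mother wavelet.

    ``kind`` selects the psi-evaluation path: ``orthogonal`` and
    ``biorthogonal`` go through the cascade algorithm, the two
    ``closed-form-*`` kinds through direct evaluation.  ``support`` is the
    (truncated) support interval of psi in natural wavelet units.
    """

    name: str
    family: str
    kind: str  # orthogonal | biorthogonal | closed-form-real | closed-form-complex
    params: dict = field(default_factory=dict, compare=False)
    support: tuple[float, float] = (0.0, 0.0)

    @property
    def is_complex(self) -> bool:
        return self.kind == "closed-form-complex"


@dataclass
class SampledWavelet:
    """psi sampled on a uniform grid at resolution ``2**-J``.

    ``integrated_psi`` is the running cumulative-trapezoid integral of psi
    along the grid (zero at the left end).
    """

    spec: WaveletSpec
    grid: np.ndarray
    psi: np.ndarray
    integrated_psi: np.ndarray
    resolution_exponent: int

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else str(x)


def _cascade_support(pywt_name: str) -> tuple[float, float]:
    w = pywt.Wavelet(pywt_name)
    return (0.0, float(max(len(w.dec_lo), len(w.rec_lo)) - 1))


@lru_cache(maxsize=1)
def build_registry() -> tuple[WaveletSpec, ...]:
    """Enumerate all 108 candidate mother wavelets across 15 families.

    Building twice yields identical names in identical order.
    """
    specs: list[WaveletSpec] = []

    def add(name, family, kind, params, support):
        specs.append(WaveletSpec(name, family, kind, params, support))

    add("haar", "Haar", "orthogonal", {}, _cascade_support("haar"))
    for n in range(2, 21):
        add(f"db{n}", "Daubechies", "orthogonal", {"N": n}, _cascade_support(f"db{n}"))
    for n in range(2, 18):
        add(f"sym{n}", "Symlets", "orthogonal", {"N": n}, _cascade_support(f"sym{n}"))
    for n in range(1, 6):
        add(f"coif{n}", "Coiflets", "orthogonal", {"N": n}, _cascade_support(f"coif{n}"))
    for nr, nd in _BIOR_ORDERS:
        add(f"bior{nr}.{nd}", "Biorthogonal", "biorthogonal",
            {"Nr": nr, "Nd": nd}, _cascade_support(f"bior{nr}.{nd}"))
    for nr, nd in _BIOR_ORDERS:
        add(f"rbio{nr}.{nd}", "Reverse biorthogonal", "biorthogonal",
            {"Nr": nr, "Nd": nd}, _cascade_support(f"rbio{nr}.{nd}"))
    add("meyr", "Meyer", "closed-form-real", {}, (-8.0, 8.0))
    add("mexh", "Mexican hat", "closed-form-real", {}, (-8.0, 8.0))
    add("morl", "Morlet", "closed-form-real", {}, (-8.0, 8.0))
    for n in range(1, 9):
        add(f"cgau{n}", "Complex Gaussian", "closed-form-complex", {"N": n}, (-5.0, 5.0))
    for fb, fc in _SHAN_PARAMS:
        add(f"shan{_fmt(fb)}-{_fmt(fc)}", "Complex Shannon", "closed-form-complex",
            {"Fb": fb, "Fc": fc}, (-20.0, 20.0))
    for m, fb, fc in _FBSP_PARAMS:
        add(f"fbsp{_fmt(m)}-{_fmt(fb)}-{_fmt(fc)}", "Complex frequency B-spline",
            "closed-form-complex", {"M": m, "Fb": fb, "Fc": fc}, (-20.0, 20.0))
    for fb, fc in _CMOR_PARAMS:
        add(f"cmor{_fmt(fb)}-{_fmt(fc)}", "Complex Morlet", "closed-form-complex",
            {"Fb": fb, "Fc": fc}, (-8.0, 8.0))
    add("dmey", "Discrete Meyer", "orthogonal", {}, _cascade_support("dmey"))
    for n in range(1, 9):
        add(f"gaus{n}", "Gaussian", "closed-form-real", {"N": n}, (-5.0, 5.0))
    return tuple(specs)


@lru_cache(maxsize=1)
def registry_by_name() -> dict[str, WaveletSpec]:
    return {s.name: s for s in build_registry()}


def family_of(name: str) -> str:
    return _lookup(name).family


def _lookup(name: str) -> WaveletSpec:
    try:
        return registry_by_name()[name]
    except KeyError:
        valid = ", ".join(sorted(registry_by_name()))
        raise UnknownWaveletError(
            f"unknown wavelet {name!r}; valid names: {valid}"
        ) from None


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _psi_mexh(t):
    # second-derivative-of-Gaussian wavelet, unit L2 norm
    return (2.0 / (np.sqrt(3.0) * np.pi ** 0.25)) * (1.0 - t * t) * np.exp(-t * t / 2.0)


def _psi_morl(t):
    return np.exp(-t * t / 2.0) * np.cos(5.0 * t)


def _hermite(n: int, t: np.ndarray) -> np.ndarray:
    c = np.zeros(n + 1)
    c[n] = 1.0
    return np.polynomial.hermite.hermval(t, c)


@lru_cache(maxsize=None)
def _gaus_norm(n: int) -> float:
    t = np.linspace(-5.0, 5.0, 1 << 16)
    f = _hermite(n, t) * np.exp(-t * t)
    return float(np.sqrt(np.trapezoid(f * f, t)))


def _psi_gaus(n: int):
    # Nth derivative of exp(-t^2); sign follows the common toolbox
    # convention (an extra (-1)^floor(N/2) relative to the bare derivative)
    sign = (-1.0) ** (n + n // 2)

    def psi(t):
        return sign * _hermite(n, np.asarray(t)) * np.exp(-np.asarray(t) ** 2) / _gaus_norm(n)

    return psi


@lru_cache(maxsize=None)
def _cgau_poly(n: int) -> np.polynomial.Polynomial:
    # d^n/dt^n exp(-it - t^2) = P_n(t) exp(-it - t^2)
    p = np.polynomial.Polynomial([1.0 + 0.0j])
    lin = np.polynomial.Polynomial([-1.0j, -2.0])
    for _ in range(n):
        p = p.deriv() + lin * p
    return p


@lru_cache(maxsize=None)
def _cgau_norm(n: int) -> float:
    t = np.linspace(-5.0, 5.0, 1 << 16)
    f = _cgau_poly(n)(t) * np.exp(-1j * t - t * t)
    return float(np.sqrt(np.trapezoid(np.abs(f) ** 2, t)))


def _psi_cgau(n: int):
    def psi(t):
        t = np.asarray(t, float)
        return _cgau_poly(n)(t) * np.exp(-1j * t - t * t) / _cgau_norm(n)

    return psi


def _psi_shan(fb: float, fc: float):
    def psi(t):
        t = np.asarray(t, float)
        return np.sqrt(fb) * np.sinc(fb * t) * np.exp(2j * np.pi * fc * t)

    return psi


def _psi_fbsp(m: int, fb: float, fc: float):
    def psi(t):
        t = np.asarray(t, float)
        return np.sqrt(fb) * np.sinc(fb * t / m) ** m * np.exp(2j * np.pi * fc * t)

    return psi


def _psi_cmor(fb: float, fc: float):
    def psi(t):
        t = np.asarray(t, float)
        return (np.pi * fb) ** -0.5 * np.exp(-t * t / fb) * np.exp(2j * np.pi * fc * t)

    return psi


def _meyer_amplitude(w: np.ndarray) -> np.ndarray:
    """Real amplitude of the Meyer spectrum on positive frequencies."""

    def nu(x):
        x = np.clip(x, 0.0, 1.0)
        return x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)

    a = np.zeros_like(w)
    band1 = (w >= 2 * np.pi / 3) & (w <= 4 * np.pi / 3)
    band2 = (w > 4 * np.pi / 3) & (w <= 8 * np.pi / 3)
    a[band1] = np.sin(np.pi / 2 * nu(3 * w[band1] / (2 * np.pi) - 1))
    a[band2] = np.cos(np.pi / 2 * nu(3 * w[band2] / (4 * np.pi) - 1))
    return a


_MEYER_NW = 1 << 12


def _psi_meyer(t):
    """Continuous Meyer wavelet by quadrature of its analytic spectrum."""
    t = np.atleast_1d(np.asarray(t, float))
    w = np.linspace(2 * np.pi / 3, 8 * np.pi / 3, _MEYER_NW)
    amp = _meyer_amplitude(w)
    # psi(t) = (1/pi) * Int A(w) cos(w t) dw  (even, peak at t = 0)
    phase = np.outer(t, w)
    vals = np.trapezoid(amp * np.cos(phase), w, axis=1) / np.pi
    return vals


def psi_callable(spec: WaveletSpec):
    """Vectorised closed-form psi(t) for a non-cascade wavelet."""
    if spec.kind in _CASCADE_KINDS:
        raise ValueError(f"{spec.name}: cascade wavelets have no closed form")
    fam = spec.family
    if fam == "Mexican hat":
        return _psi_mexh
    if fam == "Morlet":
        return _psi_morl
    if fam == "Gaussian":
        return _psi_gaus(spec.params["N"])
    if fam == "Complex Gaussian":
        return _psi_cgau(spec.params["N"])
    if fam == "Complex Shannon":
        return _psi_shan(spec.params["Fb"], spec.params["Fc"])
    if fam == "Complex frequency B-spline":
        return _psi_fbsp(spec.params["M"], spec.params["Fb"], spec.params["Fc"])
    if fam == "Complex Morlet":
        return _psi_cmor(spec.params["Fb"], spec.params["Fc"])
    if fam == "Meyer":
        return _psi_meyer
    raise ValueError(f"no closed form registered for family {fam!r}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _cumtrapz(y: np.ndarray, dx: float) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum((y[1:] + y[:-1]) * (dx / 2.0))
    return out


@lru_cache(maxsize=256)
def _evaluate_cached(name: str, J: int) -> SampledWavelet:
    spec = _lookup(name)
    if spec.kind in _CASCADE_KINDS:
        w = pywt.Wavelet(name)
        out = w.wavefun(level=J)
        if len(out) == 3:  # orthogonal: (phi, psi, x)
            _, psi, x = out
        else:  # biorthogonal: use the decomposition wavelet of the pair
            _, psi, _, _, x = out
        grid = np.asarray(x, float)
        psi = np.asarray(psi, float)
    else:
        lo, hi = spec.support
        step = 2.0 ** -J
        n = int(round((hi - lo) / step)) + 1
        grid = lo + step * np.arange(n)
        psi = psi_callable(spec)(grid)
    dx = float(grid[1] - grid[0])
    return SampledWavelet(
        spec=spec,
        grid=grid,
        psi=psi,
        integrated_psi=_cumtrapz(psi, dx),
        resolution_exponent=J,
    )


def evaluate_psi(spec: WaveletSpec | str, resolution_exponent: int = 10) -> SampledWavelet:
    """Sample psi at resolution ``2**-J`` over its support.

    ``resolution_exponent`` (J) must be at least 6.  Unknown names raise
    :class:`UnknownWaveletError` listing the valid names.
    """
    if resolution_exponent < 6:
        raise ValueError("resolution_exponent must be >= 6")
    name = spec if isinstance(spec, str) else spec.name
    _lookup(name)
    return _evaluate_cached(name, resolution_exponent)


def registry_frame():
    """Registry dump (name, family, params, kind, support) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "name": s.name,
            "family": s.family,
            "kind": s.kind,
            "params": ";".join(f"{k}={_fmt(v)}" for k, v in s.params.items()),
            "support_lo": s.support[0],
            "support_hi": s.support[1],
        }
        for s in build_registry()
    ]
    return pd.DataFrame(rows)
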