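"""Noise-free forward signal models: ADC, IVIM, DKI and three-compartment VERDICT.

All models are isotropic and return the diffusion-weighted signal normalized
to the unweighted (b = 0) signal, so every value lies in (0, 1].  b-values
are in ms/um^2, diffusivities in um^2/ms, radii in um (see
:mod:`prostadiff.scheme` for the unit conventions).

The VERDICT model decomposes the prostate signal into three non-exchanging
water populations::

    S = f_VASC * S_astrosticks(d_VASC)      vascular, randomly oriented sticks
      + f_IC   * S_sphere(R, d_IC)          intracellular, restricted in spheres
      + f_EES  * S_ball(d_EES)              extracellular-extravascular, Gaussian

with f_VASC + f_IC + f_EES = 1.  The intra-sphere and intra-stick
diffusivities are fixed constants of the model (four free parameters:
f_IC, f_EES, R, d_EES); a cellularity index f_IC / R^3 is derived.
The restricted sphere signal uses the Gaussian phase distribution (GPD)
approximation for impermeable spheres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .scheme import GAMMA, AcquisitionScheme, Measurement

logger = logging.getLogger("prostadiff")

#: fixed intracellular (intra-sphere) diffusivity, um^2/ms
D_IC_DEFAULT = 2.0
#: fixed vascular (intra-stick) pseudo-diffusivity, um^2/ms
D_VASC_DEFAULT = 8.0

#: number of terms kept in the GPD sphere series (converged: 20 vs 40 roots
#: changes the signal by < 1e-8 over the clinical regime)
N_SPHERE_ROOTS = 20

# rad/(ms um) per T/m: gamma [rad/s/T] * G [T/m] * 1e-9 -> rad ms^-1 um^-1
_GAMMA_MS_UM = GAMMA * 1e-9


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ADCParams:
    """Mono-exponential apparent diffusion coefficient model; ``d`` in um^2/ms."""

    d: float

    def __post_init__(self):
        if not self.d > 0:
            raise ValueError(f"ADC d must be > 0, got {self.d}")


@dataclass(frozen=True)
class IVIMParams:
    """Biexponential intravoxel incoherent motion model.

    ``f`` is the fast ('vascular') signal fraction, ``D`` the slow tissue
    diffusivity and ``Dstar`` the pseudo-diffusivity *excess* of the fast
    compartment (which decays as exp(-b (D + D*))).
    """

    f: float
    D: float
    Dstar: float

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"IVIM f must be in [0, 1], got {self.f}")
        if not (self.D > 0 and self.Dstar > 0):
            raise ValueError("IVIM D and Dstar must be > 0")


@dataclass(frozen=True)
class DKIParams:
    """Mean-signal diffusion kurtosis model: diffusivity ``D_K`` and excess kurtosis ``K``."""

    D_K: float
    K: float

    def __post_init__(self):
        if not self.D_K > 0:
            raise ValueError("DKI D_K must be > 0")
        if self.K < 0:
            raise ValueError("DKI K must be >= 0")


@dataclass(frozen=True)
class VERDICTParams:
    """Three-compartment VERDICT parameters; f_VASC is stored as the residual."""

    f_IC: float
    f_EES: float
    R: float
    d_EES: float
    d_IC: float = D_IC_DEFAULT
    d_VASC: float = D_VASC_DEFAULT

    def __post_init__(self):
        for name in ("f_IC", "f_EES"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.f_IC + self.f_EES > 1.0 + 1e-12:
            raise ValueError(
                f"f_IC + f_EES = {self.f_IC + self.f_EES:g} exceeds 1; "
                "signal fractions must sum to 1 with f_VASC >= 0"
            )
        if not self.R > 0:
            raise ValueError("sphere radius R must be > 0")
        if not self.d_EES > 0:
            raise ValueError("d_EES must be > 0")

    @property
    def f_VASC(self) -> float:
        return max(0.0, 1.0 - self.f_IC - self.f_EES)

    @property
    def cellularity(self) -> float:
        """Density-like composite index f_IC / R^3, um^-3."""
        return self.f_IC / self.R**3


# ---------------------------------------------------------------------------
# Gaussian compartments
# ---------------------------------------------------------------------------


def _check_b(b):
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be >= 0")
    return b


def adc_signal(b, p: ADCParams | float):
    """S = exp(-b d): isotropic Gaussian displacement distribution."""
    d = p.d if isinstance(p, ADCParams) else float(p)
    b = _check_b(b)
    return np.exp(-b * d)


def ball_signal(b, d_EES: float):
    """Gaussian isotropic ('ball') compartment; identical contract to :func:`adc_signal`."""
    return adc_signal(b, d_EES)


def ivim_signal(b, p: IVIMParams):
    """S = f exp(-b (D + D*)) + (1 - f) exp(-b D): two non-exchanging pools."""
    b = _check_b(b)
    return p.f * np.exp(-b * (p.D + p.Dstar)) + (1.0 - p.f) * np.exp(-b * p.D)


def dki_signal(b, p: DKIParams):
    """S = exp(-b D_K + b^2 D_K^2 K / 6): quadratic kurtosis correction to the log-signal.

    Evaluated as written for all b; the expression turns non-monotone for
    b > 3 / (D_K K), which is logged as a warning rather than clipped.
    """
    b = _check_b(b)
    if p.K > 0:
        b_limit = 3.0 / (p.D_K * p.K)
        if np.any(b > b_limit):
            logger.warning(
                "DKI signal evaluated beyond its convexity bound "
                "(b > 3/(D_K K) = %.3g ms/um^2); expression is non-monotone there",
                b_limit,
            )
    return np.exp(-b * p.D_K + b**2 * p.D_K**2 * p.K / 6.0)


def astrosticks_signal(b, d_VASC: float):
    """Orientation-averaged signal of randomly oriented sticks.

    S = sqrt(pi / (4 b d)) * erf(sqrt(b d)); the b d -> 0 limit (S -> 1) is
    evaluated by series to avoid 0/0.
    """
    b = _check_b(b)
    if not d_VASC > 0:
        raise ValueError("d_VASC must be > 0")
    bd = b * d_VASC
    out = np.empty_like(bd)
    small = bd < 1e-6
    # erf(x)/x -> 2/sqrt(pi) (1 - x^2/3 + ...) : S = 1 - bd/3 + O(bd^2)
    out[small] = 1.0 - bd[small] / 3.0
    x = np.sqrt(bd[~small])
    out[~small] = np.sqrt(np.pi) / 2.0 * erf(x) / x
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# restricted sphere (GPD approximation)
# ---------------------------------------------------------------------------


def _bessel_deriv_condition(x: float) -> float:
    # j1'(x) = 0  <=>  2 x cos x + (x^2 - 2) sin x = 0 (x > 0)
    return 2.0 * x * np.cos(x) + (x * x - 2.0) * np.sin(x)


@lru_cache(maxsize=None)
def sphere_roots(n_roots: int = N_SPHERE_ROOTS) -> np.ndarray:
    """First ``n_roots`` positive roots x_m of d/dx j1(x) = 0 (x = alpha R).

    One root lies in each interval (m pi, (m+1) pi); each is bracketed and
    polished to 1e-12 by Brent's method.
    """
    roots = np.empty(n_roots)
    for m in range(n_roots):
        # x = 0 is a trivial root; near 0 the condition cancels to 0.0 in
        # floating point, so the first bracket starts away from the origin
        lo = 0.5 if m == 0 else m * np.pi + 1e-9
        hi = (m + 1) * np.pi - 1e-9
        roots[m] = brentq(_bessel_deriv_condition, lo, hi, xtol=1e-12, rtol=1e-15)
    return roots


def sphere_gpd_signal(
    m: Measurement | None = None,
    R=None,
    d_IC: float = D_IC_DEFAULT,
    *,
    G=None,
    delta: float | None = None,
    Delta: float | None = None,
    n_roots: int = N_SPHERE_ROOTS,
):
    """Restricted-diffusion signal of water inside impermeable spheres (GPD).

    The Gaussian-phase-distribution attenuation for a PGSE pair (G, delta,
    Delta) and sphere radius R is::

        ln S = -2 (gamma G)^2 * sum_m  N_m / (d^2 alpha_m^6 (alpha_m^2 R^2 - 2))
        N_m  = 2 d alpha_m^2 delta - 2
               + 2 exp(-d alpha_m^2 delta) + 2 exp(-d alpha_m^2 Delta)
               - exp(-d alpha_m^2 (Delta - delta)) - exp(-d alpha_m^2 (Delta + delta))

    where alpha_m = x_m / R and the x_m are the positive roots of the sphere
    boundary condition j1'(x) = 0.  Vectorized over ``R``.

    Accepts either a :class:`Measurement` (first positional argument) or
    explicit ``G`` (T/m), ``delta``/``Delta`` (ms) keywords.
    """
    if isinstance(m, Measurement):
        G, delta, Delta = m.G, m.delta, m.Delta
    elif m is not None and G is None:
        G = m  # positional G
    if G is None or delta is None or Delta is None or R is None:
        raise TypeError("sphere_gpd_signal requires (G, delta, Delta) and R")
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("G must be >= 0")
    if not (0 < delta < Delta):
        raise ValueError("require 0 < delta < Delta")
    R_arr = np.atleast_1d(np.asarray(R, dtype=float))
    if np.any(R_arr <= 0):
        raise ValueError("sphere radius R must be > 0")
    if not d_IC > 0:
        raise ValueError("d_IC must be > 0")

    x = sphere_roots(n_roots)  # (M,)
    alpha2 = (x[None, :] / R_arr[:, None]) ** 2  # (N, M), um^-2
    ad = d_IC * alpha2  # ms^-1
    num = (
        2.0 * ad * delta
        - 2.0
        + 2.0 * np.exp(-ad * delta)
        + 2.0 * np.exp(-ad * Delta)
        - np.exp(-ad * (Delta - delta))
        - np.exp(-ad * (Delta + delta))
    )
    denom = d_IC**2 * alpha2**3 * (alpha2 * R_arr[:, None] ** 2 - 2.0)
    series = np.sum(num / denom, axis=1)  # um^2 ms^2
    if not np.all(np.isfinite(series)):
        raise FloatingPointError("sphere GPD series did not evaluate to finite values")
    lnS = -2.0 * (_GAMMA_MS_UM**2) * series  # per G^2
    S = np.exp(lnS * G**2) if G.ndim else np.exp(lnS * float(G) ** 2)
    S = S if np.ndim(R) else float(np.squeeze(S))
    return S


def verdict_signal(m: Measurement, p: VERDICTParams):
    """Fraction-weighted sum of the astrosticks, sphere and ball compartment signals."""
    s_vasc = astrosticks_signal(m.b, p.d_VASC)
    s_ic = sphere_gpd_signal(m, p.R, p.d_IC)
    s_ees = ball_signal(m.b, p.d_EES)
    return p.f_VASC * s_vasc + p.f_IC * s_ic + p.f_EES * s_ees


# ---------------------------------------------------------------------------
# batch evaluation over a scheme (used by the simulator and the NLLS oracle)
# ---------------------------------------------------------------------------

MODEL_PARAM_NAMES = {
    "ADC": ("d",),
    "IVIM": ("f", "D", "Dstar"),
    "DKI": ("D_K", "K"),
    "VERDICT": ("f_IC", "f_EES", "R", "d_EES"),
}


def batch_signals(
    model: str,
    scheme: AcquisitionScheme,
    params: np.ndarray,
    d_IC: float = D_IC_DEFAULT,
    d_VASC: float = D_VASC_DEFAULT,
) -> np.ndarray:
    """Noise-free signals for ``params`` (n, p) over every scheme row -> (n, len(scheme)).

    Column order of ``params`` follows ``MODEL_PARAM_NAMES[model]``.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    b = scheme.b[None, :]  # (1, M)
    if model == "ADC":
        (d,) = params.T
        return np.exp(-b * d[:, None])
    if model == "IVIM":
        f, D, Dstar = params.T
        return f[:, None] * np.exp(-b * (D + Dstar)[:, None]) + (1.0 - f[:, None]) * np.exp(
            -b * D[:, None]
        )
    if model == "DKI":
        D_K, K = params.T
        bD = b * D_K[:, None]
        return np.exp(-bD + bD**2 * K[:, None] / 6.0)
    if model == "VERDICT":
        f_IC, f_EES, R, d_EES = params.T
        f_VASC = np.clip(1.0 - f_IC - f_EES, 0.0, 1.0)
        out = np.empty((params.shape[0], len(scheme)))
        for j, meas in enumerate(scheme):
            s_v = astrosticks_signal(np.full_like(R, meas.b), d_VASC)
            s_i = (
                np.ones_like(R)
                if meas.G == 0
                else np.asarray(sphere_gpd_signal(meas, R, d_IC))
            )
            s_e = np.exp(-meas.b * d_EES)
            out[:, j] = f_VASC * s_v + f_IC * s_i + f_EES * s_e
        return out
    raise ValueError(f"unknown model {model!r}; expected one of {tuple(MODEL_PARAM_NAMES)}")
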