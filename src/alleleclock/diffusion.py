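"""Mean allelic age and sojourn-time densities under genic selection.

A variant observed today at population frequency ``x`` arose by mutation at
some frequency ``p0`` (for a new mutation, the limit ``p0 -> 0``).  Conditional
on the current frequency, the expected time the trajectory spent per unit
frequency at each past frequency ``y`` -- the *sojourn-time density* -- is the
Green's function of the Wright-Fisher diffusion with genic selection,
conditioned on the allele currently segregating.  Integrating the density over
``y`` gives the mean allelic age.

Conventions
-----------
* Selection is *genic* (additive, no dominance): a heterozygote carries
  fitness ``1 + s`` and a homozygote ``1 + 2s``.
* ``gamma = 2 * N * s`` is the scaled selection coefficient, the natural
  parameter of the diffusion; negative values are deleterious.
* Time is measured in units of ``2N`` generations.  Multiply by ``2 * N_ref``
  to convert to generations (`mean_age_generations`).
* The population size is constant.  Demographic change breaks the exact
  gamma <-> -gamma symmetry and is handled by forward simulation
  (:mod:`alleleclock.simulate`), not here.

With scale function ``S(z) = (1 - exp(-2*gamma*z)) / (2*gamma)`` and loss
probability ``h(z) = (S(1) - S(z)) / S(1)``, time reversal of the diffusion
(the h-transform by ``h``) gives the age-sojourn density for a new mutation
currently at frequency ``x``::

    t(y) = 2 S(y) (S(1) - S(y)) exp(2 gamma y) / (S(1) y (1 - y)),   y <= x
    t(y) = 2 S(x) (S(1) - S(y))^2 exp(2 gamma y)
           / (S(1) (S(1) - S(x)) y (1 - y)),                         y >  x

Both branches are evaluated in log space so that ``|gamma|`` up to
:data:`GAMMA_MAX` is supported without overflow.  The density is exactly
symmetric under ``gamma -> -gamma``, is flat (equal to 2) below ``x`` in the
neutral case, and integrates to the Kimura-Ohta neutral mean age
``-2 [x / (1 - x)] ln x`` when ``gamma = 0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "GAMMA_MAX",
    "SelectionParams",
    "FrequencyGrid",
    "SojournProfile",
    "QuadratureWarning",
    "sojourn_density",
    "sojourn_profile",
    "mean_age",
    "mean_age_generations",
    "new_mutation_flux_density",
    "expected_age_in_bin",
]

#: Largest supported |gamma|.  Beyond this the log-space evaluation is still
#: finite but the density is so concentrated near the boundary that fixed
#: quadrature tolerances are no longer meaningful.
GAMMA_MAX = 200.0


class QuadratureWarning(UserWarning):
    """Raised as a warning when a requested tolerance was not achieved."""


@dataclass(frozen=True)
class SelectionParams:
    """Scaled selection coefficient and an optional reference size.

    Parameters
    ----------
    gamma:
        ``2 N s`` for genic (additive) selection; sign encodes direction,
        negative = deleterious.  Must be finite and ``|gamma| <= GAMMA_MAX``.
    N_ref:
        Reference diploid population size.  Only used to convert results
        from diffusion units (2N generations) to generations.
    """

    gamma: float
    N_ref: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if abs(self.gamma) > GAMMA_MAX:
            raise ValueError(
                f"|gamma| = {abs(self.gamma)} exceeds supported range {GAMMA_MAX}"
            )


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing frequencies in the open interval (0, 1)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if pts[0] <= 0.0 or pts[-1] >= 1.0:
            raise ValueError("grid points must lie strictly inside (0, 1)")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def resolution(self) -> float:
        return float(np.max(np.diff(self.points)))

    @classmethod
    def regular(cls, n: int = 1000, eps: float = 1e-6) -> "FrequencyGrid":
        return cls(np.linspace(eps, 1.0 - eps, n))

    @classmethod
    def log_spaced(cls, n: int = 1000, eps: float = 1e-6) -> "FrequencyGrid":
        """Grid dense near both endpoints (log-spaced towards 0 and 1)."""
        half = n // 2
        lo = np.geomspace(eps, 0.5, half, endpoint=False)
        hi = 1.0 - np.geomspace(eps, 0.5, n - half)[::-1]
        return cls(np.unique(np.concatenate([lo, hi])))


@dataclass
class SojournProfile:
    """Mean sojourn time per unit frequency, conditional on current frequency.

    ``density[i]`` is the expected time (units of 2N generations) spent per
    unit frequency at past frequency ``y[i]`` by an allele currently at
    frequency ``x_current`` under scaled selection ``gamma``.
    """

    x_current: float
    gamma: float
    y: np.ndarray
    density: np.ndarray
    p0: float = 0.0
    meta: dict = field(default_factory=dict)

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.y))


# ---------------------------------------------------------------------------
# log-space building blocks


def _log1mexp(u: np.ndarray) -> np.ndarray:
    """log|1 - exp(-u)|, stable for u of either sign and large magnitude."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    pos = u > 0
    with np.errstate(divide="ignore"):
        out[pos] = np.log1p(-np.exp(-u[pos]))
        neg = ~pos
        out[neg] = -u[neg] + np.log1p(-np.exp(u[neg]))
    return out


def _log_scale_diff(a, b, gamma: float) -> np.ndarray:
    """log(S(b) - S(a)) for b > a, with S the scale function (S' = exp(-2*gamma*z)).

    S(b) - S(a) = exp(-2*gamma*a) * (1 - exp(-2*gamma*(b-a))) / (2*gamma),
    which is positive for every sign of gamma.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    g2 = 2.0 * gamma
    return -g2 * a + _log1mexp(g2 * (b - a)) - math.log(abs(g2))


def sojourn_density(
    x: float, y: np.ndarray, gamma: float, p0: float = 0.0
) -> np.ndarray:
    """Age-sojourn density at past frequencies ``y`` for an allele now at ``x``.

    Units: time in 2N generations per unit frequency.  ``p0`` is the origin
    frequency; the default 0 is the new-mutation limit.  For ``p0 > 0`` the
    density is the expected occupation since the trajectory last left ``p0``
    (exactly the allelic age in the ``p0 -> 0`` limit); it is reported for
    ``y > p0`` and set to 0 below the origin frequency.
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"current frequency x={x} outside (0, 1)")
    if not 0.0 <= p0 < x:
        raise ValueError("p0 must satisfy 0 <= p0 < x")
    if abs(gamma) > GAMMA_MAX:
        raise ValueError(f"|gamma| exceeds supported range {GAMMA_MAX}")
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("past frequencies must lie strictly inside (0, 1)")

    log_b = np.log(y) + np.log1p(-y)
    out = np.zeros_like(y)
    live = y > p0
    yl = y[live]

    # below ~1e-8 the selected-branch exponentials underflow; the neutral
    # limit is exact to O(gamma) there
    if abs(gamma) < 1e-8:
        gamma = 0.0
    if gamma == 0.0:
        below = yl <= x
        res = np.empty_like(yl)
        res[below] = 2.0 * (yl[below] - p0) * (1.0 - yl[below]) / (
            (1.0 - p0) * yl[below] * (1.0 - yl[below])
        )
        ab = ~below
        res[ab] = (
            2.0 * (x - p0) * (1.0 - yl[ab]) ** 2
            / ((1.0 - p0) * (1.0 - x) * yl[ab] * (1.0 - yl[ab]))
        )
        out[live] = res
        return out

    g2 = 2.0 * gamma
    lsd_p0_1 = float(_log_scale_diff(p0, 1.0, gamma))
    lsd_x_1 = float(_log_scale_diff(x, 1.0, gamma))
    lsd_p0_x = float(_log_scale_diff(p0, x, gamma))
    lsd_y_1 = _log_scale_diff(yl, 1.0, gamma)

    below = yl <= x
    log_t = np.empty_like(yl)
    log_t[below] = (
        math.log(2.0)
        + _log_scale_diff(p0, yl[below], gamma)
        + lsd_y_1[below]
        - lsd_p0_1
        + g2 * yl[below]
        - log_b[live][below]
    )
    ab = ~below
    log_t[ab] = (
        math.log(2.0)
        + lsd_p0_x
        + 2.0 * lsd_y_1[ab]
        - lsd_p0_1
        - lsd_x_1
        + g2 * yl[ab]
        - log_b[live][ab]
    )
    out[live] = np.exp(log_t)
    return out


def sojourn_profile(
    x: float,
    sel: SelectionParams,
    grid: FrequencyGrid | None = None,
    p0: float = 0.0,
    rel_tol: float = 1e-4,
) -> SojournProfile:
    """Evaluate the sojourn density of `sojourn_density` on a grid.

    The trapezoid integral of the returned profile is compared with the
    adaptive-quadrature mean age; if they disagree by more than ``rel_tol``
    (relative), a :class:`QuadratureWarning` reports the achieved tolerance.
    """
    if grid is None:
        grid = FrequencyGrid.log_spaced(2000)
    dens = sojourn_density(x, grid.points, sel.gamma, p0=p0)
    profile = SojournProfile(
        x_current=x, gamma=sel.gamma, y=grid.points, density=dens, p0=p0
    )
    age = mean_age(x, sel, p0=p0)
    achieved = abs(profile.integral() - age) / age if age > 0 else 0.0
    profile.meta["mean_age"] = age
    profile.meta["grid_integral_rel_error"] = achieved
    if achieved > rel_tol:
        warnings.warn(
            f"grid too coarse: trapezoid integral deviates from mean age by "
            f"{achieved:.2e} (requested {rel_tol:.0e})",
            QuadratureWarning,
            stacklevel=2,
        )
    return profile


def mean_age(
    x: float, sel: SelectionParams, p0: float = 0.0, rel_tol: float = 1e-4
) -> float:
    """Mean age of an allele at current frequency ``x``, in 2N generations.

    Equals the integral of the sojourn density over past frequencies.  For
    gamma = 0 and p0 = 0 this reduces to the classical
    ``-2 [x / (1 - x)] ln x``.
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"current frequency x={x} outside (0, 1)")
    gamma = sel.gamma

    def f(yv: float) -> float:
        return float(sojourn_density(x, np.array([yv]), gamma, p0=p0)[0])

    lo, err_lo = integrate.quad(f, p0, x, limit=200)
    hi, err_hi = integrate.quad(f, x, 1.0, limit=200)
    total = lo + hi
    err = err_lo + err_hi
    if total > 0 and err / total > rel_tol:
        raise ArithmeticError(
            f"quadrature for mean age did not converge: achieved relative "
            f"error {err / total:.2e}, requested {rel_tol:.0e}"
        )
    return total


def mean_age_generations(x: float, sel: SelectionParams, p0: float = 0.0) -> float:
    """Mean age in generations; requires ``sel.N_ref``."""
    if sel.N_ref is None:
        raise ValueError("N_ref is required to convert to generations")
    return 2.0 * sel.N_ref * mean_age(x, sel, p0=p0)


def new_mutation_flux_density(y: np.ndarray, gamma: float) -> np.ndarray:
    """Unnormalized stationary frequency density of segregating alleles.

    Under recurrent mutation with constant influx, the expected number of
    alleles observed at frequency ``y`` is proportional to the sojourn density
    of a new mutation, ``(S(1) - S(y)) exp(2 gamma y) / (y (1 - y))`` up to a
    gamma-dependent constant.  Used to weight theory predictions when they are
    compared with simulated alleles binned by frequency.
    """
    y = np.asarray(y, dtype=float)
    if gamma == 0.0:
        return 1.0 / y
    log_w = (
        _log_scale_diff(y, 1.0, gamma)
        + 2.0 * gamma * y
        - np.log(y)
        - np.log1p(-y)
    )
    # normalise arbitrarily at the midpoint to keep values in float range
    return np.exp(log_w - np.max(log_w))


def expected_age_in_bin(lo: float, hi: float, gamma: float, n_grid: int = 400) -> float:
    """Flux-weighted mean age over a frequency bin, in 2N generations.

    This is the theoretical counterpart of averaging the ages of simulated
    alleles whose frequency falls in ``[lo, hi)``: ages at each frequency are
    weighted by the stationary density of alleles at that frequency.
    """
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("bin must satisfy 0 < lo < hi < 1")
    sel = SelectionParams(gamma)
    y = np.linspace(lo, hi, n_grid)
    ages = np.array([mean_age(float(v), sel) for v in y])
    w = new_mutation_flux_density(y, gamma)
    return float(np.trapezoid(ages * w, y) / np.trapezoid(w, y))
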