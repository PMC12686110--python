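"""Response-time distribution families and the additive-increment parameterization.

Five right-tail-capable families are supported for the latent RT components
of a parametric RT-extended MPT model:

==================  =======================================  =================
family              parameters (order)                       units
==================  =======================================  =================
shifted_wald        mu (location/scale), lam (shape), shift  ms, -, ms
ex_gaussian         tau (exp mean), sigma (SD), shift (mu)   ms, ms, ms
shifted_lognormal   mu (log-scale), sigma (log-SD), shift    log-ms, -, ms
normal              mu (mean), sigma (SD)                    ms, ms
shifted_gamma       theta (scale), k (shape), shift          ms, -, ms
==================  =======================================  =================

The three latent components (fast, medium, slow) share one base vector plus
non-negative additive increments: the medium component adds ``(d1, s1)`` and
the slow component ``(d1 + d2, s1 + s2)`` to the location-type and
shape/SD-type parameter respectively, while the shift (or ex-Gaussian
Gaussian mean) is identical across components.  Constraint schemes restrict
which increments are free:

* ``R1`` - all four increments free,
* ``R2`` - only location-type increments free (s1 = s2 = 0),
* ``R3`` - only shape-type increments free (d1 = d2 = 0),
* ``EQ`` - all increments zero: a single shared RT distribution.

Fitted parameters are box-constrained to [0.001, 1000]; increment positivity
is what enforces the fast < medium < slow ordering of component RTs.

The log-density hot path is implemented directly in numpy (the ex-Gaussian
via the erfcx-stable log form); CDFs and samplers delegate to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import erfc, erfcx, gammaln

#: Box constraint applied to every fitted distribution parameter.
PARAM_BOUNDS = (0.001, 1000.0)

FAMILY_NAMES = (
    "shifted_wald",
    "ex_gaussian",
    "shifted_lognormal",
    "normal",
    "shifted_gamma",
)

SCHEMES = ("R1", "R2", "R3", "EQ")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Family:
    """Static description of one RT distribution family."""

    name: str
    param_names: tuple[str, ...]
    d_index: int  # which slot receives the location-type increments
    s_index: int  # which slot receives the shape/SD-type increments
    shift_index: int | None  # slot held fixed across components (None: normal)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- densities -------------------------------------------------------

    def logpdf(self, t, params: Sequence[float]) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.name == "shifted_wald":
            mu, lam, delta = params
            x = t - delta
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(
                    x > 0,
                    0.5 * (np.log(lam) - _LOG_2PI)
                    - 1.5 * np.log(np.where(x > 0, x, 1.0))
                    - lam * (x - mu) ** 2 / (2.0 * mu**2 * np.where(x > 0, x, 1.0)),
                    -np.inf,
                )
            return out
        if self.name == "ex_gaussian":
            tau, sigma, mu = params
            z = (t - mu) / sigma
            u = sigma / tau
            # f = (1/(2 tau)) exp(u^2/2 - u z) erfc((u - z)/sqrt(2))
            #   = (1/(2 tau)) exp(-z^2/2)    erfcx((u - z)/sqrt(2))
            w = (u - z) / np.sqrt(2.0)
            # log erfcx(w): erfcx overflows for large negative w, where
            # erfc(w) ~ 2, so switch to w^2 + log(erfc(w)) there; for w >= 0
            # erfcx only underflows at +inf, where the clip keeps log finite.
            neg = w < 0.0
            log_erfcx = np.where(
                neg,
                np.where(neg, w, 0.0) ** 2 + np.log(erfc(np.where(neg, w, 0.0))),
                np.log(np.maximum(erfcx(np.where(neg, 0.0, w)), 1e-300)),
            )
            return -np.log(2.0 * tau) - 0.5 * z**2 + log_erfcx
        if self.name == "shifted_lognormal":
            mu, sigma, delta = params
            x = t - delta
            with np.errstate(divide="ignore", invalid="ignore"):
                lx = np.log(np.where(x > 0, x, 1.0))
                out = np.where(
                    x > 0,
                    -lx - np.log(sigma) - 0.5 * _LOG_2PI - (lx - mu) ** 2 / (2.0 * sigma**2),
                    -np.inf,
                )
            return out
        if self.name == "normal":
            mu, sigma = params
            z = (t - mu) / sigma
            return -0.5 * z**2 - np.log(sigma) - 0.5 * _LOG_2PI
        if self.name == "shifted_gamma":
            theta, k, delta = params
            x = t - delta
            with np.errstate(divide="ignore", invalid="ignore"):
                lx = np.log(np.where(x > 0, x, 1.0))
                out = np.where(
                    x > 0,
                    (k - 1.0) * lx - np.where(x > 0, x, 1.0) / theta - k * np.log(theta) - gammaln(k),
                    -np.inf,
                )
            return out
        raise AssertionError(self.name)

    def pdf(self, t, params: Sequence[float]) -> np.ndarray:
        return np.exp(self.logpdf(t, params))

    # -- scipy delegation ------------------------------------------------

    def frozen(self, params: Sequence[float]):
        """The matching frozen scipy.stats distribution."""
        if self.name == "shifted_wald":
            mu, lam, delta = params
            return stats.invgauss(mu / lam, loc=delta, scale=lam)
        if self.name == "ex_gaussian":
            tau, sigma, mu = params
            return stats.exponnorm(tau / sigma, loc=mu, scale=sigma)
        if self.name == "shifted_lognormal":
            mu, sigma, delta = params
            return stats.lognorm(sigma, loc=delta, scale=np.exp(mu))
        if self.name == "normal":
            mu, sigma = params
            return stats.norm(mu, sigma)
        if self.name == "shifted_gamma":
            theta, k, delta = params
            return stats.gamma(k, loc=delta, scale=theta)
        raise AssertionError(self.name)

    def cdf(self, t, params: Sequence[float]) -> np.ndarray:
        return self.frozen(params).cdf(np.asarray(t, dtype=float))

    def support_lower(self, params: Sequence[float]) -> float:
        if self.name in ("shifted_wald", "shifted_lognormal", "shifted_gamma"):
            return float(params[2])
        return -np.inf


FAMILIES: dict[str, Family] = {
    "shifted_wald": Family("shifted_wald", ("mu", "lam", "shift"), 0, 1, 2),
    "ex_gaussian": Family("ex_gaussian", ("tau", "sigma", "shift"), 0, 1, 2),
    "shifted_lognormal": Family("shifted_lognormal", ("mu", "sigma", "shift"), 0, 1, 2),
    "normal": Family("normal", ("mu", "sigma"), 0, 1, None),
    "shifted_gamma": Family("shifted_gamma", ("theta", "k", "shift"), 0, 1, 2),
}


def get_family(family: str | Family) -> Family:
    if isinstance(family, Family):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown RT family {family!r}; expected one of {FAMILY_NAMES}"
        ) from None


@dataclass(frozen=True)
class IncrementSet:
    """Additive increments (d1, d2, s1, s2) under a constraint scheme."""

    d1: float = 0.0
    d2: float = 0.0
    s1: float = 0.0
    s2: float = 0.0
    scheme: str = "R1"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        for name in ("d1", "d2", "s1", "s2"):
            if getattr(self, name) < 0:
                raise ValueError(f"increment {name} must be non-negative")
        if self.scheme in ("R3", "EQ") and (self.d1 != 0 or self.d2 != 0):
            raise ValueError(f"scheme {self.scheme} requires d1 = d2 = 0")
        if self.scheme in ("R2", "EQ") and (self.s1 != 0 or self.s2 != 0):
            raise ValueError(f"scheme {self.scheme} requires s1 = s2 = 0")

    def as_dict(self) -> dict[str, float]:
        return {"d1": self.d1, "d2": self.d2, "s1": self.s1, "s2": self.s2,
                "scheme": self.scheme}


def component_params(
    family: str | Family,
    base: Sequence[float],
    increments: IncrementSet,
    component: str,
    check_bounds: bool = True,
) -> np.ndarray:
    """Concrete parameter vector of one latent RT component.

    fast -> base unchanged; medium -> base + (d1, s1); slow -> base +
    (d1 + d2, s1 + s2); the shift slot is never incremented.
    """
    fam = get_family(family)
    base = np.asarray(base, dtype=float)
    if base.shape != (fam.n_params,):
        raise ValueError(
            f"{fam.name} expects {fam.n_params} parameters {fam.param_names}, got {base!r}"
        )
    out = base.copy()
    if component == "fast":
        pass
    elif component == "medium":
        out[fam.d_index] += increments.d1
        out[fam.s_index] += increments.s1
    elif component == "slow":
        out[fam.d_index] += increments.d1 + increments.d2
        out[fam.s_index] += increments.s1 + increments.s2
    else:
        raise ValueError(f"unknown component {component!r}")
    if check_bounds:
        lo, hi = PARAM_BOUNDS
        if np.any(out < lo) or np.any(out > hi):
            raise ValueError(
                f"{fam.name} {component} parameters {out} fall outside [{lo}, {hi}]"
            )
    return out


def density(family: str | Family, params: Sequence[float], t) -> np.ndarray:
    """Density (per ms) of an RT family at t; zero outside the support."""
    return get_family(family).pdf(t, params)


def sample(
    family: str | Family,
    params: Sequence[float],
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n i.i.d. RTs (ms) from a family; reproducible given a seed."""
    if n < 0:
        raise ValueError("n must be non-negative")
    fam = get_family(family)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    return np.asarray(fam.frozen(params).rvs(size=n, random_state=rng), dtype=float)


def wald_moments(params: Sequence[float]) -> tuple[float, float]:
    """Closed-form (mean, variance) of the shifted Wald: (shift + mu, mu^3 / lam)."""
    mu, lam, delta = params
    if mu <= 0 or lam <= 0:
        raise ValueError("shifted Wald requires mu > 0 and lam > 0")
    return delta + mu, mu**3 / lam


def moment_start(family: str | Family, rts: np.ndarray) -> np.ndarray:
    """Method-of-moments starting values for the fast-component base vector."""
    fam = get_family(family)
    rts = np.asarray(rts, dtype=float)
    m, v = float(np.mean(rts)), float(np.var(rts))
    v = max(v, 1.0)
    lo, hi = PARAM_BOUNDS
    if fam.name == "normal":
        return np.clip([m, np.sqrt(v)], lo, hi)
    tmin = float(np.min(rts))
    delta = max(lo, min(0.9 * tmin, tmin - 1.0))
    mm = max(m - delta, 1.0)
    if fam.name == "shifted_wald":
        return np.clip([mm, mm**3 / v, delta], lo, hi)
    if fam.name == "shifted_gamma":
        return np.clip([v / mm, mm**2 / v, delta], lo, hi)
    if fam.name == "shifted_lognormal":
        s2 = np.log1p(v / mm**2)
        return np.clip([np.log(mm) - s2 / 2.0, np.sqrt(s2), delta], lo, hi)
    if fam.name == "ex_gaussian":
        tau = max(0.8 * np.sqrt(v), 1.0)
        sigma = np.sqrt(max(v - tau**2, 25.0))
        return np.clip([tau, sigma, m - tau], lo, hi)
    raise AssertionError(fam.name)


def default_increment_start(family: str | Family) -> tuple[float, float]:
    """Modest (d, s) starting increments on each family's natural scale."""
    fam = get_family(family)
    return {
        "shifted_wald": (10.0, 10.0),
        "ex_gaussian": (10.0, 5.0),
        "shifted_lognormal": (0.05, 0.05),
        "normal": (10.0, 5.0),
        "shifted_gamma": (5.0, 0.2),
    }[fam.name]
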