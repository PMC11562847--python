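"""Candidate probability families for gene-expression vectors.

Sixteen continuous families are supported: normal, Student t, Pareto,
double Weibull, generalized extreme value, Laplace, Cauchy, chi-square,
exponential, exponential power, gamma, beta, log-normal, log-gamma,
uniform, and a K-component Gaussian mixture.  Each family exposes a
density, log-density, CDF, sampler, and a maximum-likelihood (or, for the
mixture, expectation-maximization) parameter estimator.

Families whose support does not cover the data are handled by a recorded,
invertible affine preprocessing transform ``y = a*x + b`` (a > 0): e.g.
strictly-positive families shift data containing zeros into (0, inf), and
the beta family min-max rescales into an interior slice of [0, 1].  All
densities, CDFs and likelihoods reported by this module are on the
*original* data scale (the transform Jacobian ``a`` is applied), so fits
from different families are directly comparable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "Family",
    "FAMILY_ORDER",
    "Transform",
    "ParamVector",
    "FitOutcome",
    "FitOptions",
    "ParameterError",
    "DegenerateDataError",
    "TooFewSamplesError",
    "LOG_FLOOR",
    "MIN_OBS",
    "n_params",
    "support_interval",
    "pdf",
    "log_pdf",
    "cdf",
    "sample",
    "fit_parameters",
]

#: Floor returned by :func:`log_pdf` where the density is zero or underflows.
LOG_FLOOR = math.log(1e-300)

#: Minimum number of observations accepted by :func:`fit_parameters`.
MIN_OBS = 8

_EPS_SHIFT = 1e-6
_BETA_DELTA = 1e-6


class ParameterError(ValueError):
    """A ParamVector violates its family's parameter domain."""


class DegenerateDataError(ValueError):
    """Input data are degenerate for the requested fit (e.g. constant)."""


class TooFewSamplesError(ValueError):
    """Fewer observations than the fitting minimum."""


class Family(str, Enum):
    """The candidate distribution families, in canonical table order."""

    NORMAL = "normal"
    T = "t"
    PARETO = "pareto"
    DWEIBULL = "dweibull"
    GENEXTREME = "genextreme"
    LAPLACE = "laplace"
    CAUCHY = "cauchy"
    CHI2 = "chi2"
    EXPON = "expon"
    EXPONPOW = "exponpow"
    GAMMA = "gamma"
    BETA = "beta"
    LOGNORM = "lognorm"
    LOGGAMMA = "loggamma"
    UNIFORM = "uniform"
    GAUSSIAN_MIXTURE = "gaussian_mixture"


FAMILY_ORDER: tuple[Family, ...] = tuple(Family)

# Free-parameter counts entering the BIC penalty.  The mixture count is
# 3K - 1 (K means, K scales, K - 1 free weights) and is resolved at fit
# time; the table value is for the default K = 2.
_N_PARAMS: dict[Family, int] = {
    Family.NORMAL: 2,
    Family.T: 3,
    Family.PARETO: 2,
    Family.DWEIBULL: 3,
    Family.GENEXTREME: 3,
    Family.LAPLACE: 2,
    Family.CAUCHY: 2,
    Family.CHI2: 1,
    Family.EXPON: 1,
    Family.EXPONPOW: 3,
    Family.GAMMA: 2,
    Family.BETA: 2,
    Family.LOGNORM: 2,
    Family.LOGGAMMA: 2,
    Family.UNIFORM: 2,
    Family.GAUSSIAN_MIXTURE: 5,
}

# (lower, upper, lower_closed, upper_closed) on the *transformed* scale;
# None means unbounded.  Data-dependent bounds (pareto's A, uniform's
# [alpha, beta]) are enforced by the density itself.
_SUPPORT: dict[Family, tuple[float | None, float | None, bool, bool]] = {
    Family.NORMAL: (None, None, False, False),
    Family.T: (None, None, False, False),
    Family.PARETO: (0.0, None, False, False),
    Family.DWEIBULL: (0.0, None, False, False),
    Family.GENEXTREME: (None, None, False, False),
    Family.LAPLACE: (None, None, False, False),
    Family.CAUCHY: (None, None, False, False),
    Family.CHI2: (0.0, None, False, False),
    Family.EXPON: (0.0, None, False, False),
    Family.EXPONPOW: (None, None, False, False),
    Family.GAMMA: (0.0, None, False, False),
    Family.BETA: (0.0, 1.0, True, True),
    Family.LOGNORM: (0.0, None, False, False),
    Family.LOGGAMMA: (1.0, None, True, False),
    Family.UNIFORM: (None, None, True, True),
    Family.GAUSSIAN_MIXTURE: (None, None, False, False),
}

# Families requiring strictly positive data (shift preprocessing).
_POSITIVE_FAMILIES = frozenset(
    {
        Family.PARETO,
        Family.DWEIBULL,
        Family.CHI2,
        Family.EXPON,
        Family.GAMMA,
        Family.LOGNORM,
    }
)


def n_params(family: Family, mixture_k: int = 2) -> int:
    """Number of free parameters ``k`` entering the BIC penalty."""
    if family is Family.GAUSSIAN_MIXTURE:
        return 3 * mixture_k - 1
    return _N_PARAMS[family]


def support_interval(family: Family) -> tuple[float | None, float | None, bool, bool]:
    """Support of the family on the transformed scale.

    Returns ``(lower, upper, lower_closed, upper_closed)``; ``None`` bounds
    are infinite.
    """
    return _SUPPORT[family]


@dataclass(frozen=True)
class Transform:
    """Invertible affine preprocessing ``y = a*x + b`` with ``a > 0``."""

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and math.isfinite(self.a) and math.isfinite(self.b)):
            raise ParameterError(f"invalid transform a={self.a}, b={self.b}")

    @property
    def is_identity(self) -> bool:
        return self.a == 1.0 and self.b == 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.a * x + self.b

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return (y - self.b) / self.a


@dataclass(frozen=True)
class ParamVector:
    """One family's fitted parameters plus the recorded preprocessing.

    ``values`` is ordered per the family's parameter names (see
    :func:`param_names`).  ``transform`` maps original data ``x`` to the
    scale on which the base density is parameterized.
    """

    family: Family
    values: tuple[float, ...]
    transform: Transform = field(default_factory=Transform)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def validate(self) -> "ParamVector":
        _handler(self.family).validate(self.values)
        return self

    # -- JSON serialization (bit-exact round trip via repr-float JSON) ----
    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "values": list(self.values),
            "transform": {"a": self.transform.a, "b": self.transform.b},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ParamVector":
        tr = d.get("transform") or {}
        return cls(
            family=Family(d["family"]),
            values=tuple(d["values"]),
            transform=Transform(a=tr.get("a", 1.0), b=tr.get("b", 0.0)),
        )

    @classmethod
    def from_json(cls, s: str) -> "ParamVector":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class FitOptions:
    """Options controlling parameter estimation."""

    seed: int = 0
    mixture_k: int = 2
    em_max_iter: int = 200
    em_tol: float = 1e-6
    min_obs: int = MIN_OBS


@dataclass
class FitOutcome:
    """Result of fitting one family to one data vector."""

    params: ParamVector
    loglik: float
    k: int
    n: int
    converged: bool = True
    n_iter: int | None = None
    loglik_trace: tuple[float, ...] | None = None


# ---------------------------------------------------------------------------
# Per-family handlers
# ---------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def _finite(values: Sequence[float]) -> bool:
    return all(math.isfinite(v) for v in values)


class _Handler:
    """Adapter between a Family and its scipy (or custom) backend."""

    names: tuple[str, ...] = ()

    def validate(self, v: tuple[float, ...]) -> None:
        _require(len(v) == len(self.names), f"expected {len(self.names)} parameters")
        _require(_finite(v), "non-finite parameter")

    def frozen(self, v: tuple[float, ...]):
        raise NotImplementedError

    def fit(self, y: np.ndarray, opt: FitOptions) -> tuple[float, ...]:
        raise NotImplementedError

    def transform_for(self, x: np.ndarray) -> Transform:
        return Transform()


class _Normal(_Handler):
    names = ("mu", "sigma")

    def validate(self, v):
        super().validate(v)
        _require(v[1] > 0, "sigma must be > 0")

    def frozen(self, v):
        return stats.norm(loc=v[0], scale=v[1])

    def fit(self, y, opt):
        mu = float(np.mean(y))
        sigma = float(np.std(y))
        if sigma <= 0:
            raise DegenerateDataError("zero variance")
        return (mu, sigma)


class _T(_Handler):
    # Location-scale t fitted on standardized data; the standardization is
    # recorded as the transform so densities live on the original scale.
    names = ("df", "loc", "scale")

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0 and v[2] > 0, "df and scale must be > 0")

    def frozen(self, v):
        return stats.t(df=v[0], loc=v[1], scale=v[2])

    def fit(self, y, opt):
        df, loc, scale = stats.t.fit(y)
        if not (df > 0 and scale > 0 and np.isfinite(df)):
            raise DegenerateDataError("t fit failed")
        return (float(df), float(loc), float(scale))

    def transform_for(self, x):
        sd = float(np.std(x))
        if sd <= 0:
            raise DegenerateDataError("zero variance")
        m = float(np.mean(x))
        return Transform(a=1.0 / sd, b=-m / sd)


def _positive_shift(x: np.ndarray) -> Transform:
    lo = float(np.min(x))
    if lo <= 0:
        return Transform(a=1.0, b=_EPS_SHIFT - lo)
    return Transform()


class _Pareto(_Handler):
    # f(x) = beta * A^beta / x^(beta+1), x >= A.  Closed-form MLE.
    names = ("beta", "A")

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0 and v[1] > 0, "beta and A must be > 0")

    def frozen(self, v):
        return stats.pareto(b=v[0], scale=v[1])

    def fit(self, y, opt):
        A = float(np.min(y))
        if A <= 0:
            raise DegenerateDataError("pareto requires positive data")
        s = float(np.sum(np.log(y / A)))
        if s <= 0:
            raise DegenerateDataError("pareto shape undefined (constant data)")
        beta = len(y) / s
        return (beta, A)

    transform_for = staticmethod(_positive_shift)


class _DWeibull(_Handler):
    # Exponentiated Weibull on x > 0:
    # f(x) = (k1*k2/lam) (x/lam)^(k1-1) e^{-(x/lam)^k1} [1-e^{-(x/lam)^k1}]^(k2-1)
    names = ("lam", "k1", "k2")

    def validate(self, v):
        super().validate(v)
        _require(all(p > 0 for p in v), "lam, k1, k2 must be > 0")

    def frozen(self, v):
        lam, k1, k2 = v
        return stats.exponweib(a=k2, c=k1, loc=0.0, scale=lam)

    def fit(self, y, opt):
        a, c, _loc, scale = stats.exponweib.fit(y, floc=0)
        if not (a > 0 and c > 0 and scale > 0):
            raise DegenerateDataError("dweibull fit failed")
        return (float(scale), float(c), float(a))

    transform_for = staticmethod(_positive_shift)


def _gev_pwm_start(y: np.ndarray) -> tuple[float, float, float] | None:
    """Hosking probability-weighted-moment starting values (scipy c, loc, scale)."""
    ys = np.sort(y)
    n = len(ys)
    j = np.arange(1.0, n + 1.0)
    b0 = ys.mean()
    b1 = float(np.sum((j - 1) / (n - 1) * ys) / n)
    b2 = float(np.sum((j - 1) * (j - 2) / ((n - 1) * (n - 2)) * ys) / n)
    denom = 3 * b2 - b0
    if denom == 0:
        return None
    z = (2 * b1 - b0) / denom - math.log(2) / math.log(3)
    k = 7.8590 * z + 2.9554 * z * z  # scipy shape c = k
    if not math.isfinite(k) or abs(k) > 1.5:
        return None
    try:
        g1 = special.gamma(1 + k)
        if abs(k) < 1e-8:
            sigma = (2 * b1 - b0) / math.log(2)
            mu = b0 - sigma * 0.5772156649015329
        else:
            sigma = (2 * b1 - b0) * k / (g1 * (1 - 2.0 ** (-k)))
            mu = b0 - sigma * (1 - g1) / k
    except (OverflowError, ValueError):
        return None
    if not (sigma > 0 and math.isfinite(sigma) and math.isfinite(mu)):
        return None
    return (k, mu, sigma)


class _GenExtreme(_Handler):
    # Stored in the (mu, sigma, xi) convention; scipy's shape is c = -xi.
    names = ("mu", "sigma", "xi")

    def validate(self, v):
        super().validate(v)
        _require(v[1] > 0, "sigma must be > 0")

    def frozen(self, v):
        mu, sigma, xi = v
        return stats.genextreme(c=-xi, loc=mu, scale=sigma)

    def fit(self, y, opt):
        start = _gev_pwm_start(y)
        if start is not None:
            c0, mu0, sig0 = start
            c, loc, scale = stats.genextreme.fit(y, c0, loc=mu0, scale=sig0)
        else:
            c, loc, scale = stats.genextreme.fit(y)
        if not (scale > 0 and np.isfinite(c)):
            raise DegenerateDataError("genextreme fit failed")
        return (float(loc), float(scale), float(-c))


class _Laplace(_Handler):
    names = ("mu", "lam")

    def validate(self, v):
        super().validate(v)
        _require(v[1] > 0, "lam must be > 0")

    def frozen(self, v):
        return stats.laplace(loc=v[0], scale=v[1])

    def fit(self, y, opt):
        mu = float(np.median(y))
        lam = float(np.mean(np.abs(y - mu)))
        if lam <= 0:
            raise DegenerateDataError("zero dispersion")
        return (mu, lam)


class _Cauchy(_Handler):
    names = ("lam", "mu")  # scale, location

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0, "lam must be > 0")

    def frozen(self, v):
        return stats.cauchy(loc=v[1], scale=v[0])

    def fit(self, y, opt):
        q1, med, q3 = np.percentile(y, [25, 50, 75])
        half_iqr = max((q3 - q1) / 2.0, 1e-12)
        loc, scale = stats.cauchy.fit(y, loc=med, scale=half_iqr)
        if scale <= 0:
            raise DegenerateDataError("cauchy fit failed")
        return (float(scale), float(loc))


class _Chi2(_Handler):
    names = ("m",)

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0, "df must be > 0")

    def frozen(self, v):
        return stats.chi2(df=v[0])

    def fit(self, y, opt):
        df, _loc, _scale = stats.chi2.fit(y, floc=0, fscale=1)
        if not (df > 0 and np.isfinite(df)):
            raise DegenerateDataError("chi2 fit failed")
        return (float(df),)

    transform_for = staticmethod(_positive_shift)


class _Expon(_Handler):
    names = ("lam",)  # rate

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0, "lam must be > 0")

    def frozen(self, v):
        return stats.expon(scale=1.0 / v[0])

    def fit(self, y, opt):
        m = float(np.mean(y))
        if m <= 0:
            raise DegenerateDataError("non-positive mean")
        return (1.0 / m,)

    transform_for = staticmethod(_positive_shift)


class _ExponPow(_Handler):
    # Generalized error density
    # f(x) = 1/(2 a b^(1/b) Gamma(1/b + 1)) exp(-(1/b)|(x-mu)/a|^b),
    # i.e. scipy gennorm with scale s = a * b^(1/b).
    names = ("b", "a", "mu")

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0 and v[1] > 0, "b and a must be > 0")

    def frozen(self, v):
        b, a, mu = v
        return stats.gennorm(beta=b, loc=mu, scale=a * b ** (1.0 / b))

    def fit(self, y, opt):
        beta, loc, scale = stats.gennorm.fit(y)
        if not (beta > 0 and scale > 0):
            raise DegenerateDataError("exponpow fit failed")
        a = scale / beta ** (1.0 / beta)
        return (float(beta), float(a), float(loc))


class _Gamma(_Handler):
    names = ("alpha", "beta")  # shape, rate

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0 and v[1] > 0, "alpha and beta must be > 0")

    def frozen(self, v):
        return stats.gamma(a=v[0], scale=1.0 / v[1])

    def fit(self, y, opt):
        a, _loc, scale = stats.gamma.fit(y, floc=0)
        if not (a > 0 and scale > 0):
            raise DegenerateDataError("gamma fit failed")
        return (float(a), 1.0 / float(scale))

    transform_for = staticmethod(_positive_shift)


class _Beta(_Handler):
    names = ("alpha", "beta")

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0 and v[1] > 0, "alpha and beta must be > 0")

    def frozen(self, v):
        return stats.beta(a=v[0], b=v[1])

    def fit(self, y, opt):
        a, b, _loc, _scale = stats.beta.fit(y, floc=0, fscale=1)
        if not (a > 0 and b > 0):
            raise DegenerateDataError("beta fit failed")
        return (float(a), float(b))

    def transform_for(self, x):
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise DegenerateDataError("constant data")
        if lo >= _BETA_DELTA and hi <= 1 - _BETA_DELTA:
            return Transform()
        a = (1 - 2 * _BETA_DELTA) / (hi - lo)
        return Transform(a=a, b=_BETA_DELTA - a * lo)


class _LogNorm(_Handler):
    names = ("mu", "sigma")  # of ln X

    def validate(self, v):
        super().validate(v)
        _require(v[1] > 0, "sigma must be > 0")

    def frozen(self, v):
        return stats.lognorm(s=v[1], scale=math.exp(v[0]))

    def fit(self, y, opt):
        ly = np.log(y)
        mu = float(np.mean(ly))
        sigma = float(np.std(ly))
        if sigma <= 0:
            raise DegenerateDataError("zero log-variance")
        return (mu, sigma)

    transform_for = staticmethod(_positive_shift)


class _ExpGammaDist:
    """X = exp(Y), Y ~ Gamma(alpha, rate beta); support x >= 1.

    f(x) = beta^alpha / Gamma(alpha) * (ln x)^(alpha-1) * x^-(beta+1).
    """

    def __init__(self, alpha: float, beta: float):
        self.alpha = alpha
        self.beta = beta
        self._g = stats.gamma(a=alpha, scale=1.0 / beta)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, -np.inf)
        ok = x >= 1
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.log(x, where=ok, out=np.zeros_like(x))
            out[ok] = (self._g.logpdf(lx[ok]) - lx[ok])
        # x == 1 -> ln x = 0: gamma logpdf handles the boundary itself
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape)
        ok = x >= 1
        out[ok] = self._g.cdf(np.log(x[ok]))
        return out

    def rvs(self, size, random_state):
        return np.exp(self._g.rvs(size=size, random_state=random_state))


class _LogGamma(_Handler):
    names = ("alpha", "beta")

    def validate(self, v):
        super().validate(v)
        _require(v[0] > 0 and v[1] > 0, "alpha and beta must be > 0")

    def frozen(self, v):
        return _ExpGammaDist(v[0], v[1])

    def fit(self, y, opt):
        # MLE for X is the gamma MLE on ln X (the extra -sum(ln x) term is
        # parameter-free).
        z = np.log(y)
        if np.ptp(z) <= 0:
            raise DegenerateDataError("constant data")
        a, _loc, scale = stats.gamma.fit(z, floc=0)
        if not (a > 0 and scale > 0):
            raise DegenerateDataError("loggamma fit failed")
        return (float(a), 1.0 / float(scale))

    def transform_for(self, x):
        lo = float(np.min(x))
        target = 1.0 + _EPS_SHIFT
        if lo < target:
            return Transform(a=1.0, b=target - lo)
        return Transform()


class _Uniform(_Handler):
    names = ("alpha", "beta")

    def validate(self, v):
        super().validate(v)
        _require(v[1] > v[0], "beta must exceed alpha")

    def frozen(self, v):
        return stats.uniform(loc=v[0], scale=v[1] - v[0])

    def fit(self, y, opt):
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi <= lo:
            raise DegenerateDataError("constant data")
        return (lo, hi)


class _MixtureDist:
    """Frozen K-component 1-D Gaussian mixture."""

    def __init__(self, means, sigmas, weights):
        self.means = np.asarray(means, dtype=float)
        self.sigmas = np.asarray(sigmas, dtype=float)
        self.weights = np.asarray(weights, dtype=float)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        comp = (
            np.log(self.weights)
            - 0.5 * math.log(2 * math.pi)
            - np.log(self.sigmas)
            - 0.5 * ((x[..., None] - self.means) / self.sigmas) ** 2
        )
        return special.logsumexp(comp, axis=-1)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sigmas
        return np.sum(self.weights * special.ndtr(z), axis=-1)

    def rvs(self, size, random_state):
        rng = random_state
        comp = rng.choice(len(self.weights), size=size, p=self.weights)
        return rng.normal(self.means[comp], self.sigmas[comp])


def _em_gmm(
    y: np.ndarray, k: int, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """Deterministic 1-D Gaussian-mixture EM (quantile initialization)."""
    n = len(y)
    means = np.percentile(y, [100.0 * (i + 0.5) / k for i in range(k)])
    sd = float(np.std(y))
    sigma_floor = max(sd, 1e-12) * 1e-4
    sigmas = np.full(k, max(sd / k, sigma_floor))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        log_comp = (
            np.log(weights)
            - 0.5 * math.log(2 * math.pi)
            - np.log(sigmas)
            - 0.5 * ((y[:, None] - means) / sigmas) ** 2
        )
        log_mix = special.logsumexp(log_comp, axis=1)
        ll = float(np.sum(log_mix))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        resp = np.exp(log_comp - log_mix[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * y[:, None]).sum(axis=0) / nk
        var = (resp * (y[:, None] - means) ** 2).sum(axis=0) / nk
        sigmas = np.sqrt(np.maximum(var, sigma_floor**2))
    order = np.argsort(means)
    return means[order], sigmas[order], weights[order], trace, converged


class _Mixture(_Handler):
    # values layout for K components: (mu_1..mu_K, sigma_1..sigma_K, w_1..w_{K-1})
    names = ()  # variable arity

    @staticmethod
    def _unpack(v: tuple[float, ...]):
        if (len(v) + 1) % 3 != 0:
            raise ParameterError("mixture parameter vector has wrong arity")
        k = (len(v) + 1) // 3
        means = np.array(v[:k])
        sigmas = np.array(v[k : 2 * k])
        w_free = np.array(v[2 * k :])
        weights = np.append(w_free, 1.0 - w_free.sum())
        return means, sigmas, weights

    def validate(self, v):
        _require(_finite(v), "non-finite parameter")
        means, sigmas, weights = self._unpack(tuple(v))
        _require(bool(np.all(sigmas > 0)), "mixture sigmas must be > 0")
        _require(bool(np.all(weights >= -1e-8)), "mixture weights must be >= 0")
        _require(abs(weights.sum() - 1.0) <= 1e-8, "mixture weights must sum to 1")

    def frozen(self, v):
        means, sigmas, weights = self._unpack(v)
        return _MixtureDist(means, sigmas, np.clip(weights, 0.0, 1.0))

    def fit(self, y, opt):
        means, sigmas, weights, trace, converged = _em_gmm(
            y, opt.mixture_k, opt.em_max_iter, opt.em_tol
        )
        values = tuple(means) + tuple(sigmas) + tuple(weights[:-1])
        self._last_trace = trace
        self._last_converged = converged
        return values


_HANDLERS: dict[Family, _Handler] = {
    Family.NORMAL: _Normal(),
    Family.T: _T(),
    Family.PARETO: _Pareto(),
    Family.DWEIBULL: _DWeibull(),
    Family.GENEXTREME: _GenExtreme(),
    Family.LAPLACE: _Laplace(),
    Family.CAUCHY: _Cauchy(),
    Family.CHI2: _Chi2(),
    Family.EXPON: _Expon(),
    Family.EXPONPOW: _ExponPow(),
    Family.GAMMA: _Gamma(),
    Family.BETA: _Beta(),
    Family.LOGNORM: _LogNorm(),
    Family.LOGGAMMA: _LogGamma(),
    Family.UNIFORM: _Uniform(),
    Family.GAUSSIAN_MIXTURE: _Mixture(),
}


def _handler(family: Family) -> _Handler:
    return _HANDLERS[Family(family)]


def param_names(family: Family) -> tuple[str, ...]:
    """Ordered parameter names for a family (mixture uses a K-dependent layout)."""
    return _handler(family).names


# ---------------------------------------------------------------------------
# Public evaluation API
# ---------------------------------------------------------------------------


def _as_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return np.atleast_1d(arr), arr.ndim == 0


def pdf(params: ParamVector, x) -> np.ndarray | float:
    """Density of the fitted family evaluated on the original data scale.

    Off-support points yield 0.  The recorded preprocessing transform and
    its Jacobian are applied.
    """
    params.validate()
    arr, scalar = _as_array(x)
    y = params.transform.forward(arr)
    with np.errstate(all="ignore"):
        out = params.transform.a * _handler(params.family).frozen(params.values).pdf(y)
    out = np.where(np.isfinite(out) | (out == np.inf), out, 0.0)
    out = np.where(out < 0, 0.0, out)
    return float(out[0]) if scalar else out


def log_pdf(params: ParamVector, x) -> np.ndarray | float:
    """Log-density on the original data scale, floored at ``LOG_FLOOR``.

    Where the density is zero (off support) or underflows, the configured
    floor ln(1e-300) is returned instead of ``-inf`` so that sums of
    log-densities stay finite.
    """
    params.validate()
    arr, scalar = _as_array(x)
    y = params.transform.forward(arr)
    with np.errstate(all="ignore"):
        out = _handler(params.family).frozen(params.values).logpdf(y) + math.log(
            params.transform.a
        )
    out = np.asarray(out, dtype=float)
    bad = np.isnan(out) | (out == -np.inf) | (out < LOG_FLOOR)
    out = np.where(bad, LOG_FLOOR, out)
    return float(out[0]) if scalar else out


def cdf(params: ParamVector, x) -> np.ndarray | float:
    """CDF on the original data scale (monotone transform, no Jacobian)."""
    params.validate()
    arr, scalar = _as_array(x)
    y = params.transform.forward(arr)
    with np.errstate(all="ignore"):
        out = _handler(params.family).frozen(params.values).cdf(y)
    out = np.clip(np.nan_to_num(np.asarray(out, dtype=float), nan=0.0), 0.0, 1.0)
    return float(out[0]) if scalar else out


def sample(params: ParamVector, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. values on the original data scale, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fr = _handler(params.family).frozen(params.values)
    y = np.asarray(fr.rvs(size=n, random_state=rng), dtype=float)
    return params.transform.inverse(y)


def fit_parameters(
    family: Family, values: Sequence[float], options: FitOptions | None = None
) -> FitOutcome:
    """Maximum-likelihood (or EM) fit of one family to a data vector.

    Support-conforming preprocessing is applied and recorded; the returned
    log-likelihood is evaluated on the original data scale via
    :func:`log_pdf` (floored), so fits of different families are
    comparable.
    """
    opt = options or FitOptions()
    family = Family(family)
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < opt.min_obs:
        raise TooFewSamplesError(
            f"need >= {opt.min_obs} observations, got {len(x)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite observations")
    if np.ptp(x) <= 0:
        raise DegenerateDataError("constant data vector")
    h = _handler(family)
    tr = h.transform_for(x)
    y = tr.forward(x)
    fitted = h.fit(y, opt)
    params = ParamVector(family=family, values=tuple(fitted), transform=tr)
    params.validate()
    ll = float(np.sum(log_pdf(params, x)))
    out = FitOutcome(
        params=params,
        loglik=ll,
        k=n_params(family, opt.mixture_k),
        n=len(x),
    )
    if family is Family.GAUSSIAN_MIXTURE:
        out.converged = getattr(h, "_last_converged", True)
        trace = getattr(h, "_last_trace", None)
        if trace is not None:
            out.loglik_trace = tuple(trace)
            out.n_iter = len(trace)
    return out
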