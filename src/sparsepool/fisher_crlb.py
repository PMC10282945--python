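"""Fisher information matrices and Cramér–Rao lower bounds.

This module carries the estimation-theoretic half of the sparsity argument:
treat the Spatial Pooler's output as data drawn from a parametric family
and ask how well its parameters can be recovered.  For the Cauchy family
C(x0, γ) the Fisher information matrix is diag(1/(2γ²), 1/(2γ²)), so the
CRLB for both the location x0 and the scale γ is 2γ².  Two consequences
matter:

* **Maximum sparsity.**  As γ → 0 the distribution collapses toward a point
  mass at x0 (all the signal concentrated in one output element); the
  Fisher information diverges and the CRLB goes to 0 — a maximally sparse
  output can in principle be reconstructed with vanishing error.
* **Shift invariance.**  Adding a constant λ to every output element (a
  decrease in sparsity) only shifts the location parameter, leaving γ and
  hence the CRLB 2γ² untouched: de-sparsifying by a constant shift buys no
  estimation accuracy.

Analytic FIMs are provided for the Cauchy, Gaussian (μ, δ² variance
parameterization), Pareto, Exponential, Poisson and Bernoulli families,
with numerical expectation (adaptive quadrature / series summation /
Monte Carlo) as the independent cross-check.

Caveat: the Pareto scale x_m is a support-boundary parameter, so the CRLB
regularity conditions fail for it; the textbook formula α²/x_m² is exposed
as printed, but numerical verification is performed only for the shape
entry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ParametricFamily",
    "FIMResult",
    "cauchy",
    "gaussian",
    "pareto",
    "exponential",
    "poisson",
    "bernoulli",
    "loglik",
    "score",
    "fim_analytic",
    "fim_numeric",
    "crlb",
    "sparsity_limit_crlb",
    "shift_invariance_check",
    "SparsityLimitResult",
    "ShiftInvarianceResult",
]

_PARAM_NAMES = {
    "cauchy": ("x0", "gamma"),
    "gaussian": ("mu", "var"),
    "pareto": ("xm", "alpha"),
    "exponential": ("lam",),
    "poisson": ("lam",),
    "bernoulli": ("p",),
}

_DISCRETE = frozenset({"poisson", "bernoulli"})
_LOCATION_SHIFTABLE = frozenset({"cauchy", "gaussian"})


@dataclass(frozen=True)
class ParametricFamily:
    """A named distribution family with a concrete parameter vector."""

    name: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name not in _PARAM_NAMES:
            raise ValueError(f"unsupported family {self.name!r}")
        expected = len(_PARAM_NAMES[self.name])
        if len(self.params) != expected:
            raise ValueError(
                f"{self.name} takes {expected} parameter(s), got {len(self.params)}"
            )

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.name]

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def is_discrete(self) -> bool:
        return self.name in _DISCRETE

    def frozen(self):
        """The corresponding frozen scipy.stats distribution."""
        return _frozen(self.name, self.params)


def _frozen(name: str, params: tuple[float, ...]):
    if name == "cauchy":
        x0, g = params
        return stats.cauchy(loc=x0, scale=g)
    if name == "gaussian":
        mu, var = params
        return stats.norm(loc=mu, scale=math.sqrt(var))
    if name == "pareto":
        xm, alpha = params
        return stats.pareto(alpha, scale=xm)
    if name == "exponential":
        (lam,) = params
        return stats.expon(scale=1.0 / lam)
    if name == "poisson":
        (lam,) = params
        return stats.poisson(lam)
    (p,) = params
    return stats.bernoulli(p)


def cauchy(x0: float, gamma: float) -> ParametricFamily:
    if gamma <= 0:
        raise ValueError(f"cauchy scale gamma must be > 0, got {gamma}")
    return ParametricFamily("cauchy", (float(x0), float(gamma)))


def gaussian(mu: float, var: float) -> ParametricFamily:
    if var <= 0:
        raise ValueError(f"gaussian variance must be > 0, got {var}")
    return ParametricFamily("gaussian", (float(mu), float(var)))


def pareto(xm: float, alpha: float) -> ParametricFamily:
    if xm <= 0 or alpha <= 0:
        raise ValueError(f"pareto requires xm > 0 and alpha > 0, got ({xm}, {alpha})")
    return ParametricFamily("pareto", (float(xm), float(alpha)))


def exponential(lam: float) -> ParametricFamily:
    if lam <= 0:
        raise ValueError(f"exponential rate must be > 0, got {lam}")
    return ParametricFamily("exponential", (float(lam),))


def poisson(lam: float) -> ParametricFamily:
    if lam <= 0:
        raise ValueError(f"poisson rate must be > 0, got {lam}")
    return ParametricFamily("poisson", (float(lam),))


def bernoulli(p: float) -> ParametricFamily:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bernoulli p must be in [0, 1], got {p}")
    return ParametricFamily("bernoulli", (float(p),))


def loglik(family: ParametricFamily, x: float) -> float:
    """Natural-log density (or mass) at x; -inf outside the support."""
    dist = family.frozen()
    return float(dist.logpmf(x) if family.is_discrete else dist.logpdf(x))


_FD_STEP = 1e-6


def _loglik_at(name: str, params: np.ndarray, x: float) -> float:
    dist = _frozen(name, tuple(params))
    return float(dist.logpmf(x) if name in _DISCRETE else dist.logpdf(x))


def score(family: ParametricFamily, x: float) -> np.ndarray:
    """Gradient of the log-likelihood in the parameters.

    Closed form for the Cauchy family; central finite differences
    (step 1e-6) from the scipy log-density elsewhere.
    """
    if family.name == "cauchy":
        x0, g = family.params
        d = g * g + (x - x0) ** 2
        return np.array([2.0 * (x - x0) / d, 1.0 / g - 2.0 * g / d])
    base = np.asarray(family.params, dtype=np.float64)
    grad = np.empty(family.n_params)
    for i in range(family.n_params):
        hi = base.copy()
        lo = base.copy()
        hi[i] += _FD_STEP
        lo[i] -= _FD_STEP
        grad[i] = (
            _loglik_at(family.name, hi, x) - _loglik_at(family.name, lo, x)
        ) / (2.0 * _FD_STEP)
    return grad


@dataclass(frozen=True)
class FIMResult:
    """A Fisher information matrix with parameter labels and provenance."""

    matrix: np.ndarray
    parameter_names: tuple[str, ...]
    provenance: str          # "analytic" | "quadrature" | "monte-carlo"
    n: int = 1               # sample-size multiplier used by the CRLB
    stderr: np.ndarray | None = None  # per-entry Monte-Carlo standard error


def fim_analytic(family: ParametricFamily) -> FIMResult:
    """Closed-form Fisher information matrix."""
    name = family.name
    if name == "cauchy":
        _, g = family.params
        m = np.diag([1.0 / (2.0 * g * g)] * 2)
    elif name == "gaussian":
        _, var = family.params
        m = np.diag([1.0 / var, 1.0 / (2.0 * var * var)])
    elif name == "pareto":
        xm, alpha = family.params
        m = np.diag([alpha * alpha / (xm * xm), 1.0 / (alpha * alpha)])
    elif name == "exponential":
        (lam,) = family.params
        m = np.array([[1.0 / (lam * lam)]])
    elif name == "poisson":
        (lam,) = family.params
        m = np.array([[1.0 / lam]])
    else:  # bernoulli
        (p,) = family.params
        if p in (0.0, 1.0):
            raise ValueError("bernoulli Fisher information diverges at p in {0, 1}")
        m = np.array([[1.0 / (p * (1.0 - p))]])
    return FIMResult(matrix=m, parameter_names=family.param_names, provenance="analytic")


def _fim_quadrature(family: ParametricFamily) -> np.ndarray:
    """E[score scoreᵀ] by adaptive quadrature / exhaustive summation."""
    d = family.n_params
    out = np.full((d, d), np.nan)
    entries = [(i, j) for i in range(d) for j in range(i, d)]

    if family.is_discrete:
        dist = family.frozen()
        if family.name == "bernoulli":
            ks = np.array([0, 1])
        else:
            # cover the support until the tail mass drops below 1e-13
            hi = int(dist.ppf(1.0 - 1e-13)) + 20
            ks = np.arange(0, hi + 1)
        w = dist.pmf(ks)
        scores = np.vstack([score(family, float(k)) for k in ks])
        for i, j in entries:
            out[i, j] = out[j, i] = float(np.sum(w * scores[:, i] * scores[:, j]))
        return out

    if family.name == "cauchy":
        # heavy tails: substitute x = x0 + gamma*tan(u), f(x) dx = du / pi
        x0, g = family.params

        def make_integrand(i, j):
            def integrand(u):
                s = score(family, x0 + g * math.tan(u))
                return s[i] * s[j] / math.pi

            return integrand

        lo, hi = -math.pi / 2.0, math.pi / 2.0
    else:
        dist = family.frozen()
        pdf = dist.pdf

        def make_integrand(i, j):
            def integrand(x):
                s = score(family, x)
                return s[i] * s[j] * pdf(x)

            return integrand

        if family.name == "pareto":
            xm, _ = family.params
            # xm is a support-boundary parameter: only the shape entry obeys
            # the CRLB regularity conditions, so only it is integrated.
            val, _err = integrate.quad(
                make_integrand(1, 1), xm, np.inf,
                epsabs=1e-11, epsrel=1e-10, limit=300,
            )
            out[1, 1] = val
            return out
        lo, hi = dist.support()

    for i, j in entries:
        val, err = integrate.quad(
            make_integrand(i, j), lo, hi, epsabs=1e-11, epsrel=1e-10, limit=300
        )
        if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
            raise RuntimeError(
                f"quadrature for {family.name} FIM entry ({i},{j}) did not "
                f"converge: value={val}, abserr={err}"
            )
        out[i, j] = out[j, i] = val
    return out


def _fim_monte_carlo(
    family: ParametricFamily, n_samples: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    xs = family.frozen().rvs(size=n_samples, random_state=rng)
    scores = np.vstack([score(family, float(x)) for x in np.atleast_1d(xs)])
    prods = scores[:, :, None] * scores[:, None, :]
    return prods.mean(axis=0), prods.std(axis=0, ddof=1) / math.sqrt(n_samples)


def fim_numeric(
    family: ParametricFamily,
    method: str = "quadrature",
    n_samples: int = 100_000,
    seed: int = 0,
) -> FIMResult:
    """Fisher information by numerical expectation of the squared score.

    ``quadrature`` integrates score_i * score_j * f(x) adaptively over the
    support (series summation for discrete families; a tangent transform
    tames the Cauchy tails).  ``monte-carlo`` averages over seeded samples
    and reports per-entry standard errors.
    """
    if method == "quadrature":
        return FIMResult(
            matrix=_fim_quadrature(family),
            parameter_names=family.param_names,
            provenance="quadrature",
        )
    if method == "monte-carlo":
        m, se = _fim_monte_carlo(family, n_samples, seed)
        return FIMResult(
            matrix=m,
            parameter_names=family.param_names,
            provenance="monte-carlo",
            stderr=se,
        )
    raise ValueError(f"unknown method {method!r}")


def crlb(fim: FIMResult, n: int = 1) -> np.ndarray:
    """Per-parameter lower bounds: diagonal of FIM⁻¹ / n."""
    if n < 1:
        raise ValueError(f"sample count n must be >= 1, got {n}")
    m = fim.matrix
    diag = np.diag(m)
    bad = ~np.isfinite(diag) | (diag <= 0)
    if bad.any():
        names = [fim.parameter_names[i] for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(
            f"Fisher information is singular or undefined for parameter(s) {names}"
        )
    try:
        inv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"Fisher information matrix is singular for {fim.parameter_names}"
        ) from exc
    return np.diag(inv) / n


@dataclass(frozen=True)
class SparsityLimitResult:
    """CRLB sequence along γ → 0 for the Cauchy family.

    The γ = 0 endpoint is a degenerate point-mass limit: the Fisher
    information diverges there, so the bound is reported as the limiting
    value 0 and flagged, never evaluated at γ = 0.
    """

    gammas: np.ndarray
    crlb_x0: np.ndarray
    crlb_gamma: np.ndarray
    limit: float
    degenerate_limit: bool


def sparsity_limit_crlb(gamma_sequence) -> SparsityLimitResult:
    """CRLBs 2γ² along a decreasing sequence of Cauchy scales.

    Models the maximum-sparsity limit: as the output concentrates all its
    signal in one element, γ → 0 and the reconstruction-error bound → 0.
    """
    gammas = np.asarray(gamma_sequence, dtype=np.float64)
    if gammas.size == 0:
        raise ValueError("gamma_sequence must be non-empty")
    if (gammas <= 0).any():
        raise ValueError("all gammas must be > 0 (the limit is approached, never evaluated)")
    bounds = np.array([crlb(fim_analytic(cauchy(0.0, g)), n=1) for g in gammas])
    return SparsityLimitResult(
        gammas=gammas,
        crlb_x0=bounds[:, 0],
        crlb_gamma=bounds[:, 1],
        limit=0.0,
        degenerate_limit=True,
    )


@dataclass(frozen=True)
class ShiftInvarianceResult:
    """CRLBs before/after adding a constant λ to every observation."""

    family: str
    lambda_shift: float
    crlb_before_analytic: np.ndarray
    crlb_after_analytic: np.ndarray
    crlb_before_numeric: np.ndarray
    crlb_after_numeric: np.ndarray
    max_abs_difference: float


def _shifted(family: ParametricFamily, lam: float) -> ParametricFamily:
    if family.name == "cauchy":
        x0, g = family.params
        return cauchy(x0 + lam, g)
    mu, var = family.params
    return gaussian(mu + lam, var)


def shift_invariance_check(
    family: ParametricFamily, lambda_shift: float
) -> ShiftInvarianceResult:
    """Compare CRLBs before and after a constant shift of the data.

    Adding λ to every element (a sparsity decrease) moves only the location
    parameter; for the Cauchy the CRLB stays at 2γ² exactly, and the
    Gaussian location bound likewise stays at δ².
    """
    if family.name not in _LOCATION_SHIFTABLE:
        raise ValueError(
            f"{family.name} has no location parameter; shift analysis needs "
            f"one of {sorted(_LOCATION_SHIFTABLE)}"
        )
    shifted = _shifted(family, lambda_shift)
    before_a = crlb(fim_analytic(family), n=1)
    after_a = crlb(fim_analytic(shifted), n=1)
    before_n = crlb(fim_numeric(family, "quadrature"), n=1)
    after_n = crlb(fim_numeric(shifted, "quadrature"), n=1)
    max_diff = max(
        float(np.max(np.abs(after_a - before_a))),
        float(np.max(np.abs(after_n - before_n))),
    )
    return ShiftInvarianceResult(
        family=family.name,
        lambda_shift=lambda_shift,
        crlb_before_analytic=before_a,
        crlb_after_analytic=after_a,
        crlb_before_numeric=before_n,
        crlb_after_numeric=after_n,
        max_abs_difference=max_diff,
    )
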