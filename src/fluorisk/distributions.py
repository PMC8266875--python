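"""Parametric input distributions for the exposure model.

Every stochastic input (fluoride concentration C, daily tea intake DI,
exposure frequency EF, exposure duration ED, body weight BW) is described by
a :class:`DistributionSpec`: a family (point, uniform, triangular, normal,
lognormal), its parameters, and an optional truncation interval. Truncation
is realized by inverse-CDF restriction to the truncated quantile range —
never rejection — so a request for n draws always returns exactly n draws
and the stream depends only on (spec, n, seed).

The triangular fitter mirrors the distribution-fitting step of the source
analysis with a deterministic moment estimator: endpoints at the sample
extremes, mode solved from the sample mean via mean = (a + c + b) / 3.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "point",
    "uniform",
    "triangular",
    "normal",
    "lognormal",
    "sample",
    "sample_with_rng",
    "quantile",
    "cdf",
    "analytic_mean_var",
    "fit_triangular",
    "substream_rng",
]

FAMILIES = ("point", "uniform", "triangular", "normal", "lognormal")

_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "point": ("value",),
    "uniform": ("low", "high"),
    "triangular": ("a", "c", "b"),
    "normal": ("mean", "sd"),
    "lognormal": ("mu", "sigma"),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric distribution with optional truncation.

    ``truncate`` is a (lower, upper) pair; either side may be None for
    unbounded. The truncation interval must intersect the support with
    positive probability.
    """

    family: str
    params: tuple[float, ...]
    truncate: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        names = _PARAM_NAMES[self.family]
        if len(self.params) != len(names):
            raise ValidationError(
                f"{self.family} takes parameters {names}, got {len(self.params)} values"
            )
        p = dict(zip(names, self.params))
        if any(not math.isfinite(v) for v in self.params):
            raise ValidationError(f"parameters must be finite, got {self.params}")
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ValidationError(f"uniform requires low < high, got {self.params}")
        if self.family == "triangular":
            if not (p["a"] <= p["c"] <= p["b"]) or not p["a"] < p["b"]:
                raise ValidationError(
                    f"triangular requires a <= c <= b and a < b, got a={p['a']}, c={p['c']}, b={p['b']}"
                )
        if self.family == "normal" and not p["sd"] > 0:
            raise ValidationError(f"normal requires sd > 0, got {p['sd']}")
        if self.family == "lognormal" and not p["sigma"] > 0:
            raise ValidationError(f"lognormal requires sigma > 0, got {p['sigma']}")
        if self.truncate is not None:
            lo, hi = self.truncate
            if lo is not None and hi is not None and not lo < hi:
                raise ValidationError(f"truncation bounds must be ordered, got {self.truncate}")
            if self.family == "point":
                v = p["value"]
                if (lo is not None and v < lo) or (hi is not None and v > hi):
                    raise ValidationError("point mass lies outside its truncation interval")
            else:
                qlo, qhi = self._trunc_quantiles()
                if not qhi > qlo:
                    raise ValidationError(
                        "truncation interval has zero probability under the base distribution"
                    )

    # -- internals ---------------------------------------------------------

    @property
    def named_params(self) -> dict[str, float]:
        return dict(zip(_PARAM_NAMES[self.family], self.params))

    def _frozen(self):
        """Frozen scipy distribution for the untruncated base (None for point)."""
        p = self.named_params
        if self.family == "point":
            return None
        if self.family == "uniform":
            return sps.uniform(loc=p["low"], scale=p["high"] - p["low"])
        if self.family == "triangular":
            a, c, b = p["a"], p["c"], p["b"]
            return sps.triang(c=(c - a) / (b - a), loc=a, scale=b - a)
        if self.family == "normal":
            return sps.norm(loc=p["mean"], scale=p["sd"])
        return sps.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))

    def _trunc_quantiles(self) -> tuple[float, float]:
        """Base-CDF values of the truncation bounds (0 and 1 when unbounded)."""
        if self.truncate is None:
            return 0.0, 1.0
        dist = self._frozen()
        lo, hi = self.truncate
        qlo = float(dist.cdf(lo)) if lo is not None else 0.0
        qhi = float(dist.cdf(hi)) if hi is not None else 1.0
        return qlo, qhi

    def is_degenerate(self) -> bool:
        """True when the spec has zero variance (a point mass)."""
        return self.family == "point"

    def support(self) -> tuple[float, float]:
        """Effective (lower, upper) support after truncation."""
        p = self.named_params
        if self.family == "point":
            base = (p["value"], p["value"])
        elif self.family == "uniform":
            base = (p["low"], p["high"])
        elif self.family == "triangular":
            base = (p["a"], p["b"])
        elif self.family == "normal":
            base = (-math.inf, math.inf)
        else:
            base = (0.0, math.inf)
        if self.truncate is None:
            return base
        lo, hi = self.truncate
        return (
            base[0] if lo is None else max(base[0], lo),
            base[1] if hi is None else min(base[1], hi),
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """JSON/YAML-friendly form, e.g. ``{family: triangular, a: .., c: .., b: .., truncate: [0, null]}``."""
        out: dict[str, Any] = {"family": self.family}
        out.update(self.named_params)
        if self.truncate is not None:
            out["truncate"] = list(self.truncate)
        return out

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "DistributionSpec":
        data = dict(payload)
        family = data.pop("family", None)
        if family not in FAMILIES:
            raise ValidationError(f"spec fragment needs a family among {FAMILIES}, got {family!r}")
        trunc = data.pop("truncate", None)
        names = _PARAM_NAMES[family]
        missing = [n for n in names if n not in data]
        extra = [k for k in data if k not in names]
        if missing or extra:
            raise ValidationError(
                f"{family} fragment: missing parameters {missing}, unexpected keys {extra}"
            )
        truncate = None if trunc is None else (
            None if trunc[0] is None else float(trunc[0]),
            None if trunc[1] is None else float(trunc[1]),
        )
        return cls(family, tuple(float(data[n]) for n in names), truncate)


# -- constructors ----------------------------------------------------------


def point(value: float) -> DistributionSpec:
    """Degenerate distribution: every draw equals ``value``."""
    return DistributionSpec("point", (float(value),))


def uniform(low: float, high: float, truncate=None) -> DistributionSpec:
    return DistributionSpec("uniform", (float(low), float(high)), truncate)


def triangular(a: float, c: float, b: float, truncate=None) -> DistributionSpec:
    """Triangular with minimum ``a``, mode ``c``, maximum ``b``."""
    return DistributionSpec("triangular", (float(a), float(c), float(b)), truncate)


def normal(mean: float, sd: float, truncate=None) -> DistributionSpec:
    return DistributionSpec("normal", (float(mean), float(sd)), truncate)


def lognormal(mu: float, sigma: float, truncate=None) -> DistributionSpec:
    """Lognormal parameterized on the log scale: log X ~ Normal(mu, sigma)."""
    return DistributionSpec("lognormal", (float(mu), float(sigma)), truncate)


# -- sampling and evaluation ------------------------------------------------


def substream_rng(root_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible substream for a named parameter.

    Derived from (root seed, CRC-32 of the name), so adding or removing one
    parameter never perturbs another parameter's draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(key,)))


def sample_with_rng(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values from ``spec`` using an existing Generator."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if spec.family == "point":
        return np.full(n, spec.params[0], dtype=float)
    qlo, qhi = spec._trunc_quantiles()
    u = rng.uniform(qlo, qhi, size=n)
    return np.asarray(spec._frozen().ppf(u), dtype=float)


def sample(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw n independent values; identical (spec, n, seed) give bit-identical
    output. Truncation uses inverse-CDF restriction, so exactly n values are
    always returned."""
    return sample_with_rng(spec, n, np.random.default_rng(seed))


def quantile(spec: DistributionSpec, q: float) -> float:
    """Inverse CDF at q in [0, 1], honouring truncation."""
    if not 0 <= q <= 1:
        raise ValidationError(f"q must lie in [0, 1], got {q}")
    if spec.family == "point":
        return spec.params[0]
    qlo, qhi = spec._trunc_quantiles()
    return float(spec._frozen().ppf(qlo + q * (qhi - qlo)))


def cdf(spec: DistributionSpec, x: float) -> float:
    """CDF at x, honouring truncation."""
    if spec.family == "point":
        return float(x >= spec.params[0])
    qlo, qhi = spec._trunc_quantiles()
    base = float(spec._frozen().cdf(x))
    return min(1.0, max(0.0, (base - qlo) / (qhi - qlo)))


def _truncation_is_trivial(spec: DistributionSpec) -> bool:
    if spec.truncate is None:
        return True
    qlo, qhi = spec._trunc_quantiles()
    return qlo == 0.0 and qhi == 1.0


def analytic_mean_var(spec: DistributionSpec) -> tuple[float, float]:
    """Closed-form (mean, variance).

    Available for every untruncated family and for truncated uniform, normal
    and lognormal. A truncation that does not actually cut the support (e.g.
    a lognormal truncated at [0, inf)) is treated as absent.

    Raises
    ------
    NotImplementedError
        For a truncated family without a closed form here (triangular).
    """
    p = spec.named_params
    if spec.family == "point":
        return p["value"], 0.0
    if _truncation_is_trivial(spec):
        if spec.family == "uniform":
            lo, hi = p["low"], p["high"]
            return (lo + hi) / 2, (hi - lo) ** 2 / 12
        if spec.family == "triangular":
            a, c, b = p["a"], p["c"], p["b"]
            mean = (a + b + c) / 3
            var = (a * a + b * b + c * c - a * b - a * c - b * c) / 18
            return mean, var
        m, v = spec._frozen().stats(moments="mv")
        return float(m), float(v)
    lo, hi = spec.truncate
    if spec.family == "uniform":
        # truncated uniform is uniform on the clipped interval
        lo2 = p["low"] if lo is None else max(p["low"], lo)
        hi2 = p["high"] if hi is None else min(p["high"], hi)
        return (lo2 + hi2) / 2, (hi2 - lo2) ** 2 / 12
    if spec.family == "normal":
        mu, sd = p["mean"], p["sd"]
        a = -np.inf if lo is None else (lo - mu) / sd
        b = np.inf if hi is None else (hi - mu) / sd
        m, v = sps.truncnorm(a, b, loc=mu, scale=sd).stats(moments="mv")
        return float(m), float(v)
    if spec.family == "lognormal":
        return _truncated_lognormal_mean_var(p["mu"], p["sigma"], lo, hi)
    raise NotImplementedError(
        f"no closed-form moments for a truncated {spec.family} distribution"
    )


def _truncated_lognormal_mean_var(
    mu: float, sigma: float, lo: float | None, hi: float | None
) -> tuple[float, float]:
    """Moments of lognormal(mu, sigma) restricted to (lo, hi).

    E[X^k | lo < X < hi] = exp(k mu + k^2 sigma^2 / 2)
        * [Phi(beta - k sigma) - Phi(alpha - k sigma)] / [Phi(beta) - Phi(alpha)]
    with alpha = (ln lo - mu)/sigma, beta = (ln hi - mu)/sigma.
    """
    alpha = -np.inf if lo is None or lo <= 0 else (math.log(lo) - mu) / sigma
    beta = np.inf if hi is None else (math.log(hi) - mu) / sigma
    z = sps.norm.cdf(beta) - sps.norm.cdf(alpha)

    def raw_moment(k: int) -> float:
        shift = sps.norm.cdf(beta - k * sigma) - sps.norm.cdf(alpha - k * sigma)
        return math.exp(k * mu + 0.5 * k * k * sigma * sigma) * shift / z

    m1 = raw_moment(1)
    m2 = raw_moment(2)
    return m1, m2 - m1 * m1


# -- fitting ----------------------------------------------------------------


def fit_triangular(samples: Sequence[float]) -> DistributionSpec:
    """Fit a triangular distribution by the moment method used throughout the
    package: endpoints fixed at the sample minimum and maximum, the mode
    solved from the sample mean,

        c = clamp(3 * mean - a - b, a, b).

    Deterministic and optimizer-free; appropriate for the sparse concentration
    samples the exposure model consumes.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"triangular fit needs n >= 3, got {x.size}")
    a = float(x.min())
    b = float(x.max())
    if a == b:
        raise DegenerateInputError(
            "all samples identical: a triangular fit is degenerate, use point() instead"
        )
    c = float(np.clip(3.0 * x.mean() - a - b, a, b))
    return triangular(a, c, b)
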