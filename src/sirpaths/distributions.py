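"""Inter-event waiting-time laws for transmission and recovery.

A generalized SIR process on a network is specified by two waiting-time
laws: ``psi``, the time from a node's infection to a transmission attempt
along one of its links, and ``phi``, the time from infection to recovery.
The Poissonian (Markovian) special case uses exponential laws with rates
``beta`` (transmission) and ``gamma`` (recovery); non-exponential choices
make the process non-Markovian.

Sampling follows the survival-inverse convention of inverse-transform
("Inverse Smirnov") sampling: a uniform variate ``u`` in ``(0, 1]`` maps to
the time at which the survival function equals ``u``.  For the exponential
law with rate ``beta`` this is ``-ln(u)/beta``.  Because ``u`` and ``1-u``
are equal in distribution, this produces the same law as the textbook
CDF-inverse, but the survival form is adopted uniformly for every family.

Discrete-time processes use geometric waiting times with support
``{1, 2, ...}``: a transmission or recovery can never take zero steps, and
the parameters are interpreted as per-step success probabilities.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

CONTINUOUS = "continuous"
DISCRETE = "discrete"

__all__ = [
    "InterEventDistribution",
    "Exponential",
    "LogNormal",
    "Deterministic",
    "Geometric",
    "from_spec",
    "si_recovery",
]


def _check_u(u):
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u > 1.0):
        raise ValueError("uniform variate must lie in (0, 1]")
    return u


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be non-negative")
    return t


def _maybe_scalar(x, arr):
    return float(arr) if np.isscalar(x) or np.ndim(x) == 0 else arr


class InterEventDistribution:
    """Base class for a waiting-time law.

    Subclasses provide the survival-inverse ``inverse_cdf``, the CDF, the
    survival function ``sf`` and (where defined) a density ``pdf`` or mass
    function ``pmf``.  All methods are vectorized over numpy arrays.
    """

    family: str = "base"
    time_mode: str = CONTINUOUS

    #: True when the event never occurs (rate or success probability zero);
    #: used for the SI limit where recovery never preempts transmission.
    never: bool = False

    def inverse_cdf(self, u):
        """Waiting time whose survival probability is ``u`` (u in (0,1])."""
        raise NotImplementedError

    def cdf(self, t):
        raise NotImplementedError

    def sf(self, t):
        """Survival function P(T > t)."""
        return 1.0 - self.cdf(t)

    def mean(self) -> float:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size=None):
        """Draw waiting times via the survival-inverse on uniforms in (0,1]."""
        u = 1.0 - rng.random(size)  # rng.random is [0,1); 1-u lies in (0,1]
        return self.inverse_cdf(u)

    def spec(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.spec()!r})"


class Exponential(InterEventDistribution):
    """Exponential waiting time with rate ``rate`` (the Poissonian case).

    ``rate=0`` is the degenerate "never" law (infinite waiting time), used
    to express the SI limit where recovery never happens.
    """

    family = "exponential"
    time_mode = CONTINUOUS

    def __init__(self, rate: float):
        rate = float(rate)
        if rate < 0 or not math.isfinite(rate):
            raise ValueError(f"rate must be a finite non-negative real, got {rate}")
        self.rate = rate
        self.never = rate == 0.0

    def inverse_cdf(self, u):
        uu = _check_u(u)
        if self.never:
            out = np.full_like(uu, np.inf)
        else:
            out = -np.log(uu) / self.rate
        return _maybe_scalar(u, out)

    def cdf(self, t):
        tt = _check_t(t)
        out = np.zeros_like(tt) if self.never else -np.expm1(-self.rate * tt)
        return _maybe_scalar(t, out)

    def sf(self, t):
        tt = _check_t(t)
        out = np.ones_like(tt) if self.never else np.exp(-self.rate * tt)
        return _maybe_scalar(t, out)

    def pdf(self, t):
        tt = np.asarray(t, dtype=float)
        if self.never:
            return _maybe_scalar(t, np.zeros_like(tt))
        return _maybe_scalar(t, self.rate * np.exp(-self.rate * tt))

    def mean(self) -> float:
        return np.inf if self.never else 1.0 / self.rate

    def spec(self) -> str:
        return f"exponential:rate={self.rate:g}"


class LogNormal(InterEventDistribution):
    """Lognormal waiting time, ``ln T ~ Normal(mu, sigma^2)``.

    The canonical heavy-tailed (non-Markovian) law: with a broad sigma it
    drives the spreading process into the strong-disorder regime where
    propagation times grow polynomially with system size.
    """

    family = "lognormal"
    time_mode = CONTINUOUS

    def __init__(self, mu: float, sigma: float):
        sigma = float(sigma)
        if sigma <= 0 or not math.isfinite(sigma):
            raise ValueError(f"sigma must be positive, got {sigma}")
        self.mu = float(mu)
        self.sigma = sigma
        self._frozen = stats.lognorm(s=sigma, scale=math.exp(self.mu))

    def inverse_cdf(self, u):
        uu = _check_u(u)
        return _maybe_scalar(u, self._frozen.isf(uu))

    def cdf(self, t):
        tt = _check_t(t)
        return _maybe_scalar(t, self._frozen.cdf(tt))

    def sf(self, t):
        tt = _check_t(t)
        return _maybe_scalar(t, self._frozen.sf(tt))

    def pdf(self, t):
        return _maybe_scalar(t, self._frozen.pdf(np.asarray(t, dtype=float)))

    def mean(self) -> float:
        return float(self._frozen.mean())

    def spec(self) -> str:
        return f"lognormal:mu={self.mu:g},sigma={self.sigma:g}"


class Deterministic(InterEventDistribution):
    """Fixed waiting time ``delay`` (a point mass).

    Covers the fixed-recovery-time SIR special case, for which edge
    transmission outcomes become fully independent.  May be used in either
    the transmission or the recovery role, in continuous or discrete time
    (discrete requires a positive integer delay).
    """

    family = "deterministic"

    def __init__(self, delay: float, time_mode: str = CONTINUOUS):
        delay = float(delay)
        if delay < 0 or not math.isfinite(delay):
            raise ValueError(f"delay must be a finite non-negative real, got {delay}")
        if time_mode not in (CONTINUOUS, DISCRETE):
            raise ValueError(f"unknown time_mode {time_mode!r}")
        if time_mode == DISCRETE and (delay != int(delay) or delay < 1):
            raise ValueError("discrete deterministic delay must be a positive integer")
        self.delay = delay
        self.time_mode = time_mode

    def inverse_cdf(self, u):
        uu = _check_u(u)
        return _maybe_scalar(u, np.full_like(uu, self.delay))

    def cdf(self, t):
        tt = _check_t(t)
        return _maybe_scalar(t, (tt >= self.delay).astype(float))

    def mean(self) -> float:
        return self.delay

    def spec(self) -> str:
        return f"deterministic:delay={self.delay:g}"


class Geometric(InterEventDistribution):
    """Geometric waiting time on ``{1, 2, ...}`` with per-step success ``p``.

    The discrete-time SIR chain has geometric inter-event laws: an infected
    node attempts transmission along each link with probability ``p`` per
    step, so the step of first success is geometric.  ``p=0`` is the
    degenerate "never" law (discrete SI recovery); ``p=1`` succeeds on the
    first step with certainty.
    """

    family = "geometric"
    time_mode = DISCRETE

    def __init__(self, p: float):
        p = float(p)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"per-step probability must be in [0, 1], got {p}")
        self.p = p
        self.never = p == 0.0

    def inverse_cdf(self, u):
        uu = _check_u(u)
        if self.never:
            out = np.full_like(uu, np.inf)
        elif self.p == 1.0:
            out = np.ones_like(uu)
        else:
            # smallest integer k >= 1 with survival (1-p)^k <= u
            out = np.ceil(np.log(uu) / np.log1p(-self.p))
            out = np.maximum(out, 1.0)
        return _maybe_scalar(u, out)

    def cdf(self, t):
        tt = _check_t(t)
        if self.never:
            out = np.zeros_like(tt)
        else:
            k = np.floor(tt)
            out = -np.expm1(k * np.log1p(-self.p)) if self.p < 1 else (k >= 1).astype(float)
        return _maybe_scalar(t, out)

    def pmf(self, k):
        kk = np.asarray(k, dtype=float)
        if self.never:
            return _maybe_scalar(k, np.zeros_like(kk))
        out = np.where(
            (kk >= 1) & (kk == np.floor(kk)),
            self.p * np.exp((kk - 1) * np.log1p(-self.p)) if self.p < 1 else (kk == 1).astype(float),
            0.0,
        )
        return _maybe_scalar(k, out)

    def mean(self) -> float:
        return np.inf if self.never else 1.0 / self.p

    def spec(self) -> str:
        return f"geometric:p={self.p:g}"


def si_recovery(time_mode: str = CONTINUOUS) -> InterEventDistribution:
    """Recovery law of the SI limit: recovery never occurs (gamma = 0)."""
    if time_mode == CONTINUOUS:
        return Exponential(0.0)
    if time_mode == DISCRETE:
        return Geometric(0.0)
    raise ValueError(f"unknown time_mode {time_mode!r}")


_PARAM_ALIASES = {
    "exponential": {"rate": "rate", "beta": "rate", "gamma": "rate"},
    "lognormal": {"mu": "mu", "sigma": "sigma"},
    "deterministic": {"delay": "delay", "t": "delay"},
    "geometric": {"p": "p", "prob": "p"},
}


def from_spec(text: str) -> InterEventDistribution:
    """Parse a ``family:key=value,...`` distribution spec string.

    Examples: ``exponential:rate=0.01``, ``lognormal:mu=0,sigma=1``,
    ``geometric:p=0.03``, ``deterministic:delay=2``.  A trailing
    ``,discrete=1`` on a deterministic spec selects discrete time.
    """
    text = text.strip()
    family, _, rest = text.partition(":")
    family = family.strip().lower()
    if family not in _PARAM_ALIASES:
        raise ValueError(f"unknown distribution family {family!r}")
    kwargs: dict[str, float] = {}
    discrete = False
    for piece in filter(None, (p.strip() for p in rest.split(","))):
        key, _, value = piece.partition("=")
        key = key.strip().lower()
        if key == "discrete":
            discrete = bool(float(value))
            continue
        try:
            canonical = _PARAM_ALIASES[family][key]
        except KeyError:
            raise ValueError(f"unknown parameter {key!r} for family {family!r}") from None
        kwargs[canonical] = float(value)
    if family == "exponential":
        return Exponential(**kwargs)
    if family == "lognormal":
        return LogNormal(**kwargs)
    if family == "deterministic":
        return Deterministic(time_mode=DISCRETE if discrete else CONTINUOUS, **kwargs)
    return Geometric(**kwargs)
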