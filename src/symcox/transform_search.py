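"""Single-covariate symbolic transformation search with a logistic wrapper.

The search space is the family of expressions

    f(x) = a + b * g(s*x + d)

with the unary base ``g`` drawn from {identity, 1/x, exp, log, sqrt}.
Every expression is wrapped in a logistic function, ``P = 1/(1+e^{-f(x)})``,
and fitted to a binary outcome by maximum Bernoulli likelihood; candidates
are ranked by mean log-loss.  This restricted space spans the affine-wrapped
unary forms that single-covariate symbolic regression engines report, while
removing redundant parameters:

* for ``inverse``, ``log`` and ``sqrt`` the inner scale is absorbed into the
  outer coefficients (``a + b/(c·x + d) ≡ a + (b/c)/(x + d/c)`` and so on),
  leaving ``(a, b, d)`` free plus an explicit sign ``s`` for decreasing
  arguments;
* for ``exp`` the inner rate cannot be absorbed, so the form is
  ``a + b·e^{r·x}`` with ``(a, b, r)`` free (an inner offset would fold into
  ``b``);
* ``identity`` is plain logistic regression on ``x`` and is always included
  as the baseline.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

BASES: tuple[str, ...] = ("identity", "inverse", "exp", "log", "sqrt")

#: Bases whose inner argument must stay strictly positive during fitting.
_SHIFTED_BASES = ("inverse", "log", "sqrt")


class DomainError(ValueError):
    """A transformation was evaluated outside its domain."""


@dataclass(frozen=True)
class TransformSpec:
    """A canonical unary transformation ``f(x) = a + b·g(s·x + d)``.

    For ``base == "exp"`` the form is ``f(x) = a + b·e^{rate·x}`` and
    ``s``/``d`` are ignored.  For ``identity`` it is ``a + b·x``.
    """

    base: str
    a: float = 0.0
    b: float = 1.0
    d: float = 0.0
    s: int = 1
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"unknown base {self.base!r}; choose from {BASES}")
        if self.s not in (1, -1):
            raise ValueError("sign s must be +1 or -1")

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, x) -> np.ndarray:
        """Elementwise f(x); raises :class:`DomainError` out of domain."""
        x = np.asarray(x, dtype=float)
        if self.base == "identity":
            return self.a + self.b * x
        if self.base == "exp":
            return self.a + self.b * np.exp(self.rate * x)
        u = self.s * x + self.d
        if self.base == "inverse":
            bad = u == 0
            if np.any(bad):
                raise DomainError(
                    f"inverse transform undefined at x={_first(x, bad)!r} "
                    "(argument is zero)"
                )
            return self.a + self.b / u
        if self.base == "log":
            bad = u <= 0
            if np.any(bad):
                raise DomainError(
                    f"log transform undefined at x={_first(x, bad)!r} "
                    "(argument not positive)"
                )
            return self.a + self.b * np.log(u)
        # sqrt
        bad = u < 0
        if np.any(bad):
            raise DomainError(
                f"sqrt transform undefined at x={_first(x, bad)!r} "
                "(argument negative)"
            )
        return self.a + self.b * np.sqrt(u)

    __call__ = evaluate

    # -- serialization ------------------------------------------------------
    def to_string(self, var: str = "x") -> str:
        """Plain mathematical string; exact round-trip via ``from_string``."""
        inner = _inner_str(self.s, self.d, var)
        if self.base == "identity":
            tail = f"{_c(self.b)}*{var}"
        elif self.base == "exp":
            tail = f"{_c(self.b)}*exp({_c(self.rate)}*{var})"
        elif self.base == "inverse":
            tail = f"{_c(self.b)}/({inner})"
        else:
            tail = f"{_c(self.b)}*{self.base}({inner})"
        return f"{_c(self.a)} + {tail}"

    @classmethod
    def from_string(cls, text: str, var: str = "x") -> "TransformSpec":
        """Parse ``a + b*g(c*x + d)``-shaped strings, canonicalizing any
        inner scale ``c`` (so a scaled form like ``-2.1 + 1.6/(0.066*x - 0.89)``
        parses to the equivalent canonical spec)."""
        return _parse_spec(cls, text, var)

    def to_record(self) -> dict:
        return {
            "base": self.base,
            "a": self.a,
            "b": self.b,
            "d": self.d,
            "s": self.s,
            "rate": self.rate,
        }

    @classmethod
    def from_record(cls, record: dict) -> "TransformSpec":
        return cls(**record)

    # -- convenience constructors ------------------------------------------
    @classmethod
    def pure(cls, base: str, rate: float = 1.0) -> "TransformSpec":
        """The bare transform g(x) itself: 1/x, log(x), sqrt(x), x, e^{r·x}."""
        return cls(base=base, a=0.0, b=1.0, d=0.0, s=1, rate=rate)


def _first(x, mask) -> float:
    return float(np.asarray(x, dtype=float)[np.asarray(mask)].flat[0])


def _c(v: float) -> str:
    return repr(float(v))


def _inner_str(s: int, d: float, var: str) -> str:
    head = var if s == 1 else f"-{var}"
    if d == 0:
        return head
    return f"{head} - {_c(-d)}" if d < 0 else f"{head} + {_c(d)}"


_FP = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"


def _parse_inner(text: str, var: str) -> tuple[float, float]:
    """Parse 'c*x + d' (c, d optional, any sign) → (c, d)."""
    m = re.fullmatch(rf"\s*(?P<c>{_FP}\s*\*|[+-])?\s*{re.escape(var)}"
                     rf"\s*(?:(?P<op>[+-])\s*(?P<d>{_FP}))?\s*", text)
    if m is None:
        raise ValueError(f"cannot parse inner expression {text!r}")
    c_txt = m.group("c")
    if c_txt is None:
        c = 1.0
    elif c_txt.strip() in ("+", "-"):
        c = 1.0 if c_txt.strip() == "+" else -1.0
    else:
        c = float(c_txt.rstrip("*").strip())
    d = 0.0
    if m.group("d") is not None:
        d = float(m.group("d"))
        if m.group("op") == "-":
            d = -d
    return c, d


def _parse_spec(cls, text: str, var: str) -> TransformSpec:
    t = text.strip()
    head = rf"\s*(?P<a>{_FP})\s*(?P<op>[+-])\s*(?P<b>{_FP})\s*"
    m = re.fullmatch(head + rf"\*\s*{re.escape(var)}\s*", t)
    if m:
        a, b = _outer(m)
        return cls("identity", a=a, b=b)
    m = re.fullmatch(head + rf"\*\s*exp\s*\((?P<inner>[^()]*)\)\s*", t)
    if m:
        a, b = _outer(m)
        c, d = _parse_inner(m.group("inner"), var)
        return cls("exp", a=a, b=b * math.exp(d), rate=c)
    m = re.fullmatch(head + r"/\s*\((?P<inner>[^()]*)\)\s*", t)
    if m:
        a, b = _outer(m)
        c, d = _parse_inner(m.group("inner"), var)
        if c == 0:
            raise ValueError("inverse argument has zero coefficient on x")
        s = 1 if c > 0 else -1
        return cls("inverse", a=a, b=b / abs(c), d=d / abs(c), s=s)
    m = re.fullmatch(head + rf"\*\s*(?P<g>log|sqrt)\s*\((?P<inner>[^()]*)\)\s*", t)
    if m:
        a, b = _outer(m)
        g = m.group("g")
        c, d = _parse_inner(m.group("inner"), var)
        if c == 0:
            raise ValueError(f"{g} argument has zero coefficient on x")
        s = 1 if c > 0 else -1
        if g == "log":
            return cls("log", a=a + b * math.log(abs(c)), b=b, d=d / abs(c), s=s)
        return cls("sqrt", a=a, b=b * math.sqrt(abs(c)), d=d / abs(c), s=s)
    raise ValueError(f"cannot parse transform string {text!r}")


def _outer(m) -> tuple[float, float]:
    a = float(m.group("a"))
    b = float(m.group("b"))
    if m.group("op") == "-":
        b = -b
    return a, b


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformFit:
    """A fitted transformation and its logistic-wrapper fit quality."""

    spec: TransformSpec
    mean_log_loss: float  # nats per observation, on the fitting sample
    n_obs: int
    converged: bool
    n_restarts_used: int


def evaluate(spec: TransformSpec, x) -> np.ndarray:
    """Elementwise f(x) for a transformation spec (see TransformSpec)."""
    return spec.evaluate(x)


def predict_probability(spec: TransformSpec, x) -> np.ndarray:
    """Logistic-wrapped prediction 1/(1+e^{-f(x)}), strictly inside (0,1)."""
    p = expit(spec.evaluate(x))
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


def _bernoulli_entropy(y: np.ndarray) -> float:
    r = float(np.mean(y))
    if r in (0.0, 1.0):
        return 0.0
    return -(r * math.log(r) + (1 - r) * math.log(1 - r))


def _nll_and_grad(theta, base, x, y, s):
    """Mean negative Bernoulli log-likelihood of expit(f(x)) and gradient.

    theta = (a, b, d) for shifted bases, (a, b, rate) for exp,
    (a, b) for identity.
    """
    n = x.size
    a, b = theta[0], theta[1]
    if base == "identity":
        g = x
        dg = None
    elif base == "exp":
        r = theta[2]
        g = np.exp(np.clip(r * x, -700.0, 700.0))
        dg = x * g  # ∂g/∂r
    else:
        d = theta[2]
        u = s * x + d
        if np.any(u <= 0):
            return np.inf, np.zeros_like(theta)
        if base == "inverse":
            g = 1.0 / u
            dg = -1.0 / (u * u)
        elif base == "log":
            g = np.log(u)
            dg = 1.0 / u
        else:  # sqrt
            g = np.sqrt(u)
            dg = 0.5 / g
    f = a + b * g
    # stable: log(1+e^{-f}) and log(1+e^{f})
    nll = float(np.mean(np.logaddexp(0.0, f) - y * f))
    resid = (expit(f) - y) / n
    grad = np.empty_like(np.asarray(theta, dtype=float))
    grad[0] = resid.sum()
    grad[1] = float(resid @ g)
    if dg is not None:
        grad[2] = b * float(resid @ dg)
    if not np.isfinite(nll):
        return np.inf, np.zeros_like(grad)
    return nll, grad


def _feasible_d_low(x: np.ndarray, s: int) -> float:
    """Smallest admissible inner offset for shifted bases.

    Keeps the base's argument at least 0.1% of the observed span away from
    its singularity, so no fit can pin a pole or log singularity onto a
    single extreme observation.
    """
    lo = -float(np.min(s * x))
    span = float(np.ptp(x)) or max(abs(float(np.mean(x))), 1.0)
    return lo + 1e-3 * span


def _restart_points(base, x, y, s, n_restarts, rng):
    """Deterministic-seeded initial points scaled to the data.

    The first restart always starts at the intercept-only model so the fit
    can never end worse than the constant-probability baseline.
    """
    ybar = float(np.mean(y))
    a0 = math.log(ybar / (1 - ybar))
    span = float(np.ptp(x)) or max(abs(float(np.mean(x))), 1.0)
    sx = float(np.std(x)) or span
    points = []
    for k in range(n_restarts):
        if base == "identity":
            b0 = 0.0 if k == 0 else rng.normal(0.0, 2.0) / sx
            points.append(np.array([a0, b0]))
            continue
        if base == "exp":
            if k == 0:
                points.append(np.array([a0, 0.0, 1.0 / span]))
                continue
            mag = 10.0 ** rng.uniform(-1.3, 0.6) / sx  # |r|·sd(x) in ~[0.05, 4]
            r0 = mag * rng.choice([-1.0, 1.0])
            z = np.exp(np.clip(r0 * x, -700, 700))
            sz = float(np.std(z)) or 1.0
            b0 = rng.normal(0.0, 1.5) / sz
            points.append(np.array([a0, b0, r0]))
            continue
        d_lo = _feasible_d_low(x, s)
        if k == 0:
            points.append(np.array([a0, 0.0, d_lo + span]))
            continue
        d0 = d_lo + span * 10.0 ** rng.uniform(-3.0, 1.0)
        u = s * x + d0
        z = {"inverse": 1.0 / u, "log": np.log(u), "sqrt": np.sqrt(u)}[base]
        sz = float(np.std(z)) or 1.0
        b0 = rng.normal(0.0, 1.5) / sz
        points.append(np.array([a0, b0, d0]))
    return points


def _fit_one(base, x, y, s, n_restarts, rng, gtol):
    d_lo = _feasible_d_low(x, s) if base in _SHIFTED_BASES else None
    if base == "exp":
        rmax = 30.0 / max(float(np.max(np.abs(x))), 1e-12)
        bounds = [(None, None), (None, None), (-rmax, rmax)]
    elif base == "identity":
        bounds = [(None, None), (None, None)]
    else:
        bounds = [(None, None), (None, None), (d_lo, None)]
    best = None
    converged = False
    for theta0 in _restart_points(base, x, y, s, n_restarts, rng):
        res = minimize(
            _nll_and_grad,
            theta0,
            args=(base, x, y, s),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    return best, converged


def fit_transform(
    x,
    y,
    base: str,
    n_restarts: int = 16,
    seed: int = 0,
    gtol: float = 1e-8,
) -> TransformFit:
    """Fit the logistic-wrapped transformation of one base to a binary outcome.

    Parameters ``(a, b, d)`` (or ``(a, b, rate)`` for exp) maximize the
    Bernoulli log-likelihood of ``expit(f(x))`` by multi-start L-BFGS-B with
    analytic gradients; for shifted bases both argument signs are tried and
    the better kept.  The inner offset is bounded so the base's argument
    stays strictly positive over the observed sample (hard bound in the
    optimizer, re-checked on the returned spec).

    Raises
    ------
    ValueError
        If ``y`` has a single class, the sample is shorter than 10, or the
        base is unknown.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 observations to fit a transform")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if classes.size < 2:
        raise ValueError("y has a single class; cannot fit a classifier")
    if base not in BASES:
        raise ValueError(f"unknown base {base!r}; choose from {BASES}")

    entropy = _bernoulli_entropy(y)
    ybar = float(np.mean(y))
    if float(np.ptp(x)) == 0.0:
        # degenerate constant covariate: slope-zero solution at the
        # outcome-rate entropy
        spec = TransformSpec("identity", a=math.log(ybar / (1 - ybar)), b=0.0)
        return TransformFit(spec, entropy, x.size, True, 0)

    rng = np.random.default_rng(seed)
    signs = (1, -1) if base in _SHIFTED_BASES else (1,)
    best = None
    best_s = 1
    converged = False
    for s in signs:
        res, conv = _fit_one(base, x, y, s, n_restarts, rng, gtol)
        if best is None or res.fun < best.fun:
            best, best_s = res, s
        converged = converged or conv

    theta = best.x
    if base == "identity":
        spec = TransformSpec("identity", a=float(theta[0]), b=float(theta[1]))
    elif base == "exp":
        spec = TransformSpec(
            "exp", a=float(theta[0]), b=float(theta[1]), rate=float(theta[2])
        )
    else:
        spec = TransformSpec(
            base, a=float(theta[0]), b=float(theta[1]),
            d=float(theta[2]), s=best_s,
        )
    spec.evaluate(x)  # hard domain check
    loss = float(min(best.fun, entropy + 1e-12))
    return TransformFit(spec, loss, x.size, converged, n_restarts * len(signs))


def search_transforms(
    x,
    y,
    bases: Iterable[str] = ("inverse", "exp", "log", "sqrt"),
    n_restarts: int = 16,
    seed: int = 0,
) -> list[TransformFit]:
    """Fit every requested base plus the identity baseline; rank by loss.

    Returns fits sorted ascending by mean log-loss (ties broken by base
    name), deterministic for a fixed seed regardless of the order in which
    bases are supplied.
    """
    base_list = sorted(set(bases) | {"identity"})
    unknown = [b for b in base_list if b not in BASES]
    if unknown:
        raise ValueError(f"unknown bases: {unknown}")
    fits = []
    errors = {}
    for i, base in enumerate(base_list):
        try:
            fits.append(
                fit_transform(x, y, base, n_restarts=n_restarts, seed=seed + i)
            )
        except DomainError as exc:  # pragma: no cover - defensive
            errors[base] = str(exc)
    if not fits:
        raise DomainError(f"all bases infeasible on this sample: {errors}")
    return sorted(fits, key=lambda f: (f.mean_log_loss, f.spec.base))
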