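"""Cox proportional-hazards estimation and survival metrics.

Implements the partial likelihood from scratch: Efron (default) or Breslow
handling of tied event times, a Newton–Raphson solver with step-halving,
Wald and likelihood-ratio inference, the partial AIC, relative-hazard
calculations for (possibly transformed) covariates, Harrell's concordance
index, the cumulative/dynamic AUC at a time horizon, and Kaplan–Meier
curves with Greenwood variance and log(−log) confidence bands.

The baseline hazard h0(t) is deliberately left unestimated: model use here
is restricted to relative hazards and rank-based discrimination metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import Cohort
from .transform_search import TransformSpec

logger = logging.getLogger(__name__)

_TIES_METHODS = ("efron", "breslow")


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged model and has none."""


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxModel:
    """A fitted Cox proportional-hazards model (no baseline hazard).

    ``coef`` are per-unit-of-covariate log-hazard coefficients; ``cov`` is
    the inverse observed information.  ``ll_model``/``ll_null`` are the log
    partial likelihoods at the optimum and at zero, ``lr_statistic`` is
    2·(ll_model − ll_null) and ``partial_aic`` is −2·ll_model + 2·k.
    """

    names: tuple[str, ...]
    coef: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    ll_model: float
    ll_null: float
    lr_statistic: float
    partial_aic: float
    n: int
    n_events: int
    ties: str
    converged: bool
    diagnostics: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def linear_predictor(self, covariates) -> np.ndarray:
        """Risk score x·b for new data (DataFrame with the model's columns,
        or an array in the model's column order)."""
        if isinstance(covariates, pd.DataFrame):
            X = covariates[list(self.names)].to_numpy(dtype=float)
        else:
            X = np.asarray(covariates, dtype=float)
        return X @ self.coef


def _prepare_design(covariates, time, event):
    if isinstance(covariates, pd.DataFrame):
        names = tuple(str(c) for c in covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(time).size != 1:
            X = X.T
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event, dtype=float).ravel()
    if not (len(t) == len(e) == X.shape[0]):
        raise ValueError("covariates, time and event lengths differ")
    if np.any(t <= 0):
        raise ValueError("all follow-up times must be positive")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("event must be binary 0/1")
    ptp = np.ptp(X, axis=0)
    if np.any(ptp == 0):
        bad = [names[i] for i in np.flatnonzero(ptp == 0)]
        raise ValueError(f"constant column(s) {bad}: not identifiable in a Cox model")
    return names, X, t, e.astype(int)


def _partial_loglik(beta, X, t, e, ties):
    """Log partial likelihood, gradient and information (negative Hessian).

    Rows must be sorted by descending time so risk-set sums are prefix sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # everyone with this time enters the risk set
        S0 += float(w[i:j].sum())
        S1 += wX[i:j].sum(axis=0)
        S2 += wXX[i:j].sum(axis=0)
        ev = np.flatnonzero(e[i:j] == 1) + i
        d = ev.size
        if d > 0:
            ll += float(eta[ev].sum())
            grad += X[ev].sum(axis=0)
            s0d = float(w[ev].sum())
            s1d = wX[ev].sum(axis=0)
            s2d = wXX[ev].sum(axis=0)
            if ties == "breslow":
                fracs = np.zeros(d)
            else:  # efron
                fracs = np.arange(d) / d
            for frac in fracs:
                phi = S0 - frac * s0d
                v = S1 - frac * s1d
                m = S2 - frac * s2d
                ll -= math.log(phi)
                grad -= v / phi
                info += m / phi - np.outer(v, v) / (phi * phi)
        i = j
    return ll, grad, info


def cox_fit(
    covariates,
    time,
    event,
    ties: str = "efron",
    max_iter: int = 100,
    gtol: float = 1e-8,
) -> CoxModel:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Parameters
    ----------
    covariates
        Named real matrix (DataFrame preferred; columns become coefficient
        names).  No constant columns allowed.
    time, event
        Positive follow-up times and 0/1 death indicators.
    ties
        ``"efron"`` (default) or ``"breslow"`` handling of tied event times.

    The solver starts at zero, takes Newton steps on the log partial
    likelihood with up to 20 step-halvings per iteration, and declares
    convergence when the gradient norm drops below ``gtol``.  Monotone
    likelihood (complete separation in the risk sets) is detected by
    coefficient-norm divergence and reported through ``converged=False``
    plus ``diagnostics`` — never by silent divergence.
    """
    if ties not in _TIES_METHODS:
        raise ValueError(f"ties must be one of {_TIES_METHODS}")
    names, X, t, e = _prepare_design(covariates, time, event)
    n, p = X.shape
    n_events = int(e.sum())
    if n_events < p:
        raise ValueError(
            f"{n_events} events cannot identify {p} coefficients"
        )

    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]

    # centre and scale for numerical conditioning; exact back-transform at
    # the end (partial likelihood is invariant to centring)
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xs - mu) / sd

    beta = np.zeros(p)
    ll_null, _, _ = _partial_loglik(beta, Z, ts, es, ties)
    ll = ll_null
    converged = False
    diagnostics = ""
    for it in range(max_iter):
        ll, grad, info = _partial_loglik(beta, Z, ts, es, ties)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            diagnostics = "singular information matrix"
            break
        # step-halving: accept the first step that does not decrease ll
        # (tolerance relative to |ll| to absorb floating-point plateau noise)
        accepted = False
        for half in range(21):
            cand = beta + step / (2.0**half)
            ll_new, _, _ = _partial_loglik(cand, Z, ts, es, ties)
            if ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                beta = cand
                accepted = True
                break
        if not accepted:
            diagnostics = "step-halving failed to improve the likelihood"
            break
        if float(np.linalg.norm(beta)) > 1e4:
            diagnostics = (
                "coefficient norm diverging: likely monotone partial "
                "likelihood (complete separation in risk sets)"
            )
            break
    else:
        diagnostics = f"gradient norm {gnorm:.2e} after {max_iter} iterations"

    ll, grad, info = _partial_loglik(beta, Z, ts, es, ties)
    if converged and float(np.max(np.abs(beta))) > 10.0:
        # a per-SD log-hazard coefficient beyond e^10 is not a finite MLE:
        # the partial likelihood is monotone (risk sets perfectly separated)
        # and the gradient only vanished on the plateau
        converged = False
        diagnostics = (
            "monotone partial likelihood: standardized coefficient "
            f"{float(np.max(np.abs(beta))):.1f} (complete separation in "
            "risk sets); estimates are not finite maximum-likelihood values"
        )
    if converged:
        cov_z = np.linalg.inv(info)
    else:
        cov_z = np.linalg.pinv(info)
        logger.warning("cox_fit did not converge: %s", diagnostics)

    # back-transform from standardized scale
    coef = beta / sd
    cov = cov_z / np.outer(sd, sd)
    cov = (cov + cov.T) / 2.0

    return CoxModel(
        names=names,
        coef=coef,
        cov=cov,
        ll_model=float(ll),
        ll_null=float(ll_null),
        lr_statistic=float(2.0 * (ll - ll_null)),
        partial_aic=float(-2.0 * ll + 2.0 * p),
        n=n,
        n_events=n_events,
        ties=ties,
        converged=converged,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Wald inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldRow:
    """One covariate's Wald summary: coefficient, hazard ratio with CI, z, p."""

    name: str
    coef: float
    se: float
    hr: float
    hr_lower: float
    hr_upper: float
    z: float
    p: float


def wald_summary(model: CoxModel, confidence: float = 0.95) -> list[WaldRow]:
    """Per-coefficient Wald table: HR = e^b, CI = e^{b ± z·se}, normal p."""
    if not model.converged:
        raise ConvergenceError(
            f"model did not converge ({model.diagnostics}); "
            "Wald inference is not valid"
        )
    zcrit = float(norm.ppf(0.5 + confidence / 2.0))
    rows = []
    for name, b, se in zip(model.names, model.coef, model.se):
        z = b / se
        rows.append(
            WaldRow(
                name=name,
                coef=float(b),
                se=float(se),
                hr=math.exp(b),
                hr_lower=math.exp(b - zcrit * se),
                hr_upper=math.exp(b + zcrit * se),
                z=float(z),
                p=float(2.0 * norm.sf(abs(z))),
            )
        )
    return rows


def wald_table(model: CoxModel, confidence: float = 0.95) -> pd.DataFrame:
    """Wald summary as a DataFrame in conventional reporting column order."""
    rows = wald_summary(model, confidence)
    pct = int(round(confidence * 100))
    return pd.DataFrame(
        {
            "coef": [r.coef for r in rows],
            "HR": [r.hr for r in rows],
            f"HR lower {pct}%": [r.hr_lower for r in rows],
            f"HR upper {pct}%": [r.hr_upper for r in rows],
            "z": [r.z for r in rows],
            "p": [r.p for r in rows],
        },
        index=[r.name for r in rows],
    )


def relative_hazard(
    model: CoxModel,
    covariate: str,
    x_from: float,
    delta: float,
    transform: TransformSpec | None = None,
) -> float:
    """Hazard ratio for moving one covariate from ``x_from`` by ``delta``.

    Without a transform this is e^{b·delta}, independent of the origin
    ``x_from``; with a transform f it is e^{b·(f(x_from+delta) − f(x_from))},
    which depends on the origin — the point of transforming covariates.
    """
    if covariate not in model.names:
        raise KeyError(f"covariate {covariate!r} not in model {model.names}")
    b = float(model.coef[model.names.index(covariate)])
    if transform is None:
        return math.exp(b * delta)
    f0 = float(transform.evaluate(np.array([x_from]))[0])
    f1 = float(transform.evaluate(np.array([x_from + delta]))[0])
    return math.exp(b * (f1 - f0))


# ---------------------------------------------------------------------------
# Discrimination metrics
# ---------------------------------------------------------------------------

def concordance_index(risk_scores, time, event) -> float:
    """Harrell's C over admissible pairs.

    A pair (i, j) is admissible when subject i has an observed event and
    either fails strictly earlier than j's follow-up, or fails at exactly
    j's censoring time (j is then known to survive at least as long).
    Pairs of events tied in time carry no ordering and are excluded.
    Concordant pairs have the earlier failure carrying the higher risk
    score; tied scores contribute 1/2.
    """
    s = np.asarray(risk_scores, dtype=float).ravel()
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event, dtype=int).ravel()
    if not (len(s) == len(t) == len(e)):
        raise ValueError("risk_scores, time, event lengths differ")
    num = 0.0
    n_pairs = 0
    # chunked O(n^2) comparison; exact, fine up to a few thousand subjects
    ev_idx = np.flatnonzero(e == 1)
    chunk = 512
    for start in range(0, ev_idx.size, chunk):
        idx = ev_idx[start : start + chunk]
        ti = t[idx][:, None]
        si = s[idx][:, None]
        admissible = (ti < t[None, :]) | (
            (ti == t[None, :]) & (e[None, :] == 0)
        )
        n_pairs += int(admissible.sum())
        num += float(((si > s[None, :]) & admissible).sum())
        num += 0.5 * float(((si == s[None, :]) & admissible).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs: cannot compute a C-index")
    return num / n_pairs


def _rank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Two-sample rank AUC (Mann–Whitney statistic / n1·n2), ties at 1/2."""
    gt = (cases[:, None] > controls[None, :]).sum()
    eq = (cases[:, None] == controls[None, :]).sum()
    return (float(gt) + 0.5 * float(eq)) / (cases.size * controls.size)


def auc_at_horizon(
    risk_scores,
    time,
    event,
    horizon: float,
    censored_controls: str = "exclude",
) -> float:
    """Cumulative/dynamic AUC for discriminating death by ``horizon`` days.

    Cases are subjects with an observed event at or before the horizon.
    Controls depend on ``censored_controls``:

    * ``"exclude"`` (default): only subjects still under observation at the
      horizon are controls; subjects censored strictly earlier are excluded.
    * ``"include"``: every non-case is a control (censored subjects treated
      as event-free), i.e. the plain rank AUC of the death-by-horizon label.
    * ``"ipcw"``: inverse-probability-of-censoring weighting — cases
      weighted by 1/G(t_i), controls (time > horizon) by 1/G(horizon),
      where G is the Kaplan–Meier estimate of the censoring distribution.

    The unweighted variants equal the Mann–Whitney statistic of the scores
    between the two groups.
    """
    s = np.asarray(risk_scores, dtype=float).ravel()
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event, dtype=int).ravel()
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    case = (e == 1) & (t <= horizon)
    if censored_controls == "exclude":
        control = (t > horizon) | ((t == horizon) & (e == 0))
    elif censored_controls == "include":
        control = ~case
    elif censored_controls == "ipcw":
        return _auc_ipcw(s, t, e, horizon)
    else:
        raise ValueError("censored_controls must be exclude, include or ipcw")
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError(
            f"need at least one case and one control at horizon {horizon}; "
            f"got {int(case.sum())} cases, {int(control.sum())} controls"
        )
    return _rank_auc(s[case], s[control])


def _auc_ipcw(s, t, e, horizon) -> float:
    cens_curve = kaplan_meier(t, 1 - e)
    G = cens_curve.survival_at

    case = (e == 1) & (t <= horizon)
    control = t > horizon
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("need at least one case and one control for IPCW AUC")
    # G evaluated just before each case's event time
    wg_case = np.array([G(ti, before=True) for ti in t[case]])
    wg_case[wg_case <= 0] = np.nan
    w_case = 1.0 / wg_case
    w_case = np.where(np.isfinite(w_case), w_case, 0.0)
    g_h = G(horizon)
    w_control = np.full(int(control.sum()), 1.0 / g_h if g_h > 0 else 0.0)

    sc, so = s[case], s[control]
    wmat = np.outer(w_case, w_control)
    gt = (sc[:, None] > so[None, :]) * wmat
    eq = (sc[:, None] == so[None, :]) * wmat
    denom = wmat.sum()
    if denom <= 0:
        raise ValueError("IPCW weights degenerate at this horizon")
    return float((gt.sum() + 0.5 * eq.sum()) / denom)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate with Greenwood confidence bands.

    ``times`` are the distinct event times; the curve is the right-
    continuous step function with S(0) = 1.  ``variance`` is Greenwood's
    estimate and the bands use the log(−log S) transformation (so they stay
    inside [0, 1]).  Subjects censored at an event time are counted at risk
    through that time.
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    confidence: float

    def survival_at(self, t: float, before: bool = False) -> float:
        """S(t) (or S(t−) with ``before=True``) from the step function."""
        if before:
            k = int(np.searchsorted(self.times, t, side="left"))
        else:
            k = int(np.searchsorted(self.times, t, side="right"))
        return 1.0 if k == 0 else float(self.survival[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


def kaplan_meier(time, event, confidence: float = 0.95) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate with Greenwood variance.

    Confidence bands use the log(−log) transformation; at S = 1 or S = 0
    the band collapses onto the point estimate.
    """
    t = np.asarray(time, dtype=float).ravel()
    e = np.asarray(event, dtype=int).ravel()
    if t.size == 0:
        raise ValueError("need at least one subject")
    if np.any(t <= 0):
        raise ValueError("all times must be positive")

    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    event_times = np.unique(ts[es == 1])

    n = t.size
    surv = np.empty(event_times.size)
    var_sum = 0.0
    variance = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    d_events = np.empty(event_times.size, dtype=int)

    s = 1.0
    for k, et in enumerate(event_times):
        nk = int((ts >= et).sum())  # censored at et remain at risk through et
        dk = int(((ts == et) & (es == 1)).sum())
        s *= 1.0 - dk / nk
        at_risk[k] = nk
        d_events[k] = dk
        if nk > dk:
            var_sum += dk / (nk * (nk - dk))
            variance[k] = s * s * var_sum
        else:
            variance[k] = np.inf if s == 0 else s * s * var_sum
        surv[k] = s

    zcrit = float(norm.ppf(0.5 + confidence / 2.0))
    lower = np.empty_like(surv)
    upper = np.empty_like(surv)
    for k, (sk, vk) in enumerate(zip(surv, variance)):
        if sk <= 0.0 or sk >= 1.0 or not np.isfinite(vk):
            lower[k] = upper[k] = sk
            continue
        se_ll = math.sqrt(vk) / (sk * abs(math.log(sk)))
        lower[k] = sk ** math.exp(zcrit * se_ll)
        upper[k] = sk ** math.exp(-zcrit * se_ll)
    return SurvivalCurve(
        times=event_times,
        survival=surv,
        variance=variance,
        ci_lower=lower,
        ci_upper=upper,
        n_at_risk=at_risk,
        n_events=d_events,
        confidence=confidence,
    )


def km_by_stratum(
    cohort: Cohort,
    covariate: str,
    bin_edges: Sequence[float],
    confidence: float = 0.95,
) -> dict[str, SurvivalCurve]:
    """Kaplan–Meier curves per half-open covariate bin (lower, upper].

    Bins must cover the observed range of the covariate.  Empty strata are
    omitted with a logged warning.  Keys are interval labels like
    ``"(25, 40]"``.
    """
    x = cohort.column(covariate)
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    if x.min() <= edges[0] or x.max() > edges[-1]:
        raise ValueError(
            f"bins ({edges[0]}, {edges[-1]}] do not cover the observed "
            f"{covariate} range [{x.min()}, {x.max()}]"
        )
    t, e = cohort.time, cohort.event
    curves: dict[str, SurvivalCurve] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (x > lo) & (x <= hi)
        label = f"({lo:g}, {hi:g}]"
        if not mask.any():
            logger.warning("stratum %s of %s is empty; omitted", label, covariate)
            continue
        curves[label] = kaplan_meier(t[mask], e[mask], confidence)
    return curves


def plot_survival(curves: Mapping[str, SurvivalCurve] | SurvivalCurve, path) -> None:
    """Step-plot survival curve(s) with confidence bands to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(curves, SurvivalCurve):
        curves = {"all": curves}
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, curve in curves.items():
        xs = np.concatenate([[0.0], curve.times])
        ys = np.concatenate([[1.0], curve.survival])
        lo = np.concatenate([[1.0], curve.ci_lower])
        hi = np.concatenate([[1.0], curve.ci_upper])
        (line,) = ax.step(xs, ys, where="post", label=label)
        ax.fill_between(
            xs, lo, hi, step="post", alpha=0.2, color=line.get_color()
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
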