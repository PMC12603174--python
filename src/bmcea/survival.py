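"""Parametric time-to-event families and maximum-likelihood fitting.

Six standard extrapolation families (exponential, Weibull, Gompertz,
log-logistic, log-normal, generalized gamma) are fitted to right-censored
single-transition data — one dataset per transition pathway per treatment
arm, with time measured from entry into the origin state (clock-reset
semantics) — and ranked by AIC/BIC.

Parameters live on an unconstrained scale (log for positive quantities,
identity otherwise) so that optimisation is box-free and the fitted
covariance can be used directly for multivariate-normal probabilistic
sensitivity draws.  Natural-scale values are exposed for reporting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "FAMILY_ORDER",
    "SurvivalFamily",
    "ParametricSurvivalModel",
    "TransitionDataset",
    "ModelSelection",
    "get_family",
    "fit_mle",
    "select_model",
    "read_transition_datasets",
    "models_to_json",
    "models_from_json",
]

TRANSITIONS = ("TP1", "TP2", "TP3", "TP4", "TP5", "TP6")
ARMS = ("intervention", "comparator")

_TINY = 1e-300


class SurvivalError(ValueError):
    """Base class for survival-fitting problems."""


class DegenerateFitError(SurvivalError):
    """Too few events (or none) to identify the family's parameters."""


class ConvergenceError(SurvivalError):
    """Optimiser failed to converge after the multi-start policy."""


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------


class SurvivalFamily:
    """A parametric family on the unconstrained parameter scale.

    Subclasses implement ``log_sf`` and ``log_pdf``; hazard and cumulative
    hazard derive from them.  ``t`` may be scalar or array, ``t >= 0``.
    """

    name: str = ""
    n_params: int = 0
    param_names: tuple[str, ...] = ()

    # -- core ---------------------------------------------------------------
    def log_sf(self, t, params):  # pragma: no cover - abstract
        raise NotImplementedError

    def log_pdf(self, t, params):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- derived ------------------------------------------------------------
    def sf(self, t, params):
        return np.exp(self.log_sf(t, params))

    def pdf(self, t, params):
        return np.exp(self.log_pdf(t, params))

    def cumhaz(self, t, params):
        return -self.log_sf(t, params)

    def hazard(self, t, params):
        t = np.asarray(t, dtype=float)
        return np.exp(self.log_pdf(t, params) - self.log_sf(t, params))

    def natural_params(self, params) -> dict[str, float]:
        """Map the unconstrained vector to named natural-scale values."""
        raise NotImplementedError

    def initial_values(self, times, events) -> list[np.ndarray]:
        """Deterministic multi-start points from moment estimates."""
        raise NotImplementedError

    # helpers shared by subclasses
    @staticmethod
    def _moment_anchor(times, events):
        """Crude exponential-rate anchor: events / total time at risk."""
        total = float(np.sum(times))
        rate = max(float(np.sum(events)), 0.5) / max(total, 1e-12)
        return rate


class Exponential(SurvivalFamily):
    name = "exponential"
    n_params = 1
    param_names = ("log_rate",)

    def log_sf(self, t, params):
        rate = math.exp(params[0])
        return -rate * np.asarray(t, dtype=float)

    def log_pdf(self, t, params):
        rate = math.exp(params[0])
        return params[0] - rate * np.asarray(t, dtype=float)

    def natural_params(self, params):
        return {"rate": math.exp(params[0])}

    def initial_values(self, times, events):
        r = self._moment_anchor(times, events)
        base = np.array([math.log(r)])
        return [base, base + 0.5, base - 0.5, base + 1.0, base - 1.0]


class Weibull(SurvivalFamily):
    """S(t) = exp(-(t/scale)^shape)."""

    name = "weibull"
    n_params = 2
    param_names = ("log_shape", "log_scale")

    def log_sf(self, t, params):
        shape, scale = math.exp(params[0]), math.exp(params[1])
        t = np.asarray(t, dtype=float)
        return -np.power(t / scale, shape)

    def log_pdf(self, t, params):
        shape, scale = math.exp(params[0]), math.exp(params[1])
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, _TINY)
        return (
            math.log(shape)
            - math.log(scale)
            + (shape - 1.0) * (np.log(tt) - math.log(scale))
            - np.power(tt / scale, shape)
        )

    def natural_params(self, params):
        return {"shape": math.exp(params[0]), "scale": math.exp(params[1])}

    def initial_values(self, times, events):
        r = self._moment_anchor(times, events)
        scale = 1.0 / r
        base = np.array([0.0, math.log(scale)])
        return [
            base,
            base + np.array([0.4, 0.0]),
            base + np.array([-0.4, 0.0]),
            base + np.array([0.0, 0.5]),
            base + np.array([0.2, -0.5]),
        ]


class Gompertz(SurvivalFamily):
    """H(t) = (rate/shape)(exp(shape t) - 1); shape may be negative.

    Negative shape gives a decreasing hazard with a plateau: S(inf) > 0.
    """

    name = "gompertz"
    n_params = 2
    param_names = ("shape", "log_rate")

    @staticmethod
    def _cumhaz(t, shape, rate):
        t = np.asarray(t, dtype=float)
        if abs(shape) < 1e-8:
            # Taylor limit: rate * t * (1 + shape t / 2)
            return rate * t * (1.0 + 0.5 * shape * t)
        return (rate / shape) * np.expm1(shape * t)

    def log_sf(self, t, params):
        shape, rate = params[0], math.exp(params[1])
        return -self._cumhaz(t, shape, rate)

    def log_pdf(self, t, params):
        shape, rate = params[0], math.exp(params[1])
        t = np.asarray(t, dtype=float)
        return math.log(rate) + shape * t - self._cumhaz(t, shape, rate)

    def natural_params(self, params):
        return {"shape": params[0], "rate": math.exp(params[1])}

    def initial_values(self, times, events):
        r = self._moment_anchor(times, events)
        lr = math.log(r)
        return [
            np.array([0.0, lr]),
            np.array([0.5, lr]),
            np.array([-0.5, lr]),
            np.array([1.0, lr - 0.5]),
            np.array([-1.0, lr + 0.5]),
        ]


class LogLogistic(SurvivalFamily):
    """S(t) = 1 / (1 + (t/scale)^shape)."""

    name = "loglogistic"
    n_params = 2
    param_names = ("log_shape", "log_scale")

    def log_sf(self, t, params):
        shape, scale = math.exp(params[0]), math.exp(params[1])
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, _TINY)
        z = shape * (np.log(tt) - math.log(scale))
        out = -np.logaddexp(0.0, z)
        return np.where(t > 0, out, 0.0)

    def log_pdf(self, t, params):
        shape, scale = math.exp(params[0]), math.exp(params[1])
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, _TINY)
        z = shape * (np.log(tt) - math.log(scale))
        return (
            math.log(shape)
            - np.log(tt)
            + z
            - 2.0 * np.logaddexp(0.0, z)
        )

    def natural_params(self, params):
        return {"shape": math.exp(params[0]), "scale": math.exp(params[1])}

    def initial_values(self, times, events):
        r = self._moment_anchor(times, events)
        base = np.array([0.3, math.log(1.0 / r)])
        return [
            base,
            base + np.array([0.4, 0.0]),
            base + np.array([-0.3, 0.3]),
            base + np.array([0.0, -0.5]),
            base + np.array([0.6, 0.5]),
        ]


class LogNormal(SurvivalFamily):
    """log T ~ Normal(mu, sigma^2)."""

    name = "lognormal"
    n_params = 2
    param_names = ("mu", "log_sigma")

    def log_sf(self, t, params):
        mu, sigma = params[0], math.exp(params[1])
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, _TINY)
        w = (np.log(tt) - mu) / sigma
        out = special.log_ndtr(-w)
        return np.where(t > 0, out, 0.0)

    def log_pdf(self, t, params):
        mu, sigma = params[0], math.exp(params[1])
        t = np.asarray(t, dtype=float)
        tt = np.maximum(t, _TINY)
        w = (np.log(tt) - mu) / sigma
        return -0.5 * w * w - 0.5 * math.log(2.0 * math.pi) - math.log(sigma) - np.log(tt)

    def natural_params(self, params):
        return {"mu": params[0], "sigma": math.exp(params[1])}

    def initial_values(self, times, events):
        lt = np.log(np.maximum(np.asarray(times, dtype=float), _TINY))
        mu = float(np.mean(lt))
        sd = max(float(np.std(lt)), 0.2)
        base = np.array([mu, math.log(sd)])
        return [
            base,
            base + np.array([0.3, 0.0]),
            base + np.array([-0.3, 0.0]),
            base + np.array([0.0, 0.4]),
            base + np.array([0.0, -0.4]),
        ]


class GenGamma(SurvivalFamily):
    """Generalized gamma, (mu, sigma, q) parameterisation.

    q -> 0 recovers the log-normal; q = 1 recovers the Weibull with
    shape 1/sigma and scale exp(mu).  With w = (log t - mu)/sigma and
    a = q^-2, the density is

        f(t) = |q| a^a / (sigma t Gamma(a)) * exp(a (q w - exp(q w)))

    and F(t) = P(a, a e^{q w}) for q > 0 (1 - P for q < 0), with P the
    regularised lower incomplete gamma function.
    """

    name = "gengamma"
    n_params = 3
    param_names = ("mu", "log_sigma", "q")

    _Q_EPS = 1e-5

    def _w(self, t, mu, sigma):
        tt = np.maximum(np.asarray(t, dtype=float), _TINY)
        return (np.log(tt) - mu) / sigma

    def log_sf(self, t, params):
        mu, sigma, q = params[0], math.exp(params[1]), params[2]
        t = np.asarray(t, dtype=float)
        if abs(q) < self._Q_EPS:
            return LogNormal().log_sf(t, np.array([mu, math.log(sigma)]))
        w = self._w(t, mu, sigma)
        a = q ** -2.0
        y = a * np.exp(np.minimum(q * w, 700.0))
        if q > 0:
            sf = special.gammaincc(a, y)
        else:
            sf = special.gammainc(a, y)
        out = np.log(np.maximum(sf, _TINY))
        return np.where(t > 0, out, 0.0)

    def log_pdf(self, t, params):
        mu, sigma, q = params[0], math.exp(params[1]), params[2]
        t = np.asarray(t, dtype=float)
        if abs(q) < self._Q_EPS:
            return LogNormal().log_pdf(t, np.array([mu, math.log(sigma)]))
        tt = np.maximum(t, _TINY)
        w = self._w(t, mu, sigma)
        a = q ** -2.0
        qw = np.minimum(q * w, 700.0)
        return (
            math.log(abs(q))
            + a * math.log(a)
            - special.gammaln(a)
            - math.log(sigma)
            - np.log(tt)
            + a * (qw - np.exp(qw))
        )

    def natural_params(self, params):
        return {"mu": params[0], "sigma": math.exp(params[1]), "q": params[2]}

    def initial_values(self, times, events):
        lt = np.log(np.maximum(np.asarray(times, dtype=float), _TINY))
        mu = float(np.mean(lt))
        sd = max(float(np.std(lt)), 0.2)
        ls = math.log(sd)
        return [
            np.array([mu, ls, 1.0]),  # Weibull corner
            np.array([mu, ls, 0.1]),  # near log-normal
            np.array([mu, ls, -0.5]),
            np.array([mu, ls + 0.4, 0.5]),
            np.array([mu, ls - 0.4, 1.5]),
        ]


FAMILY_ORDER = (
    "exponential",
    "weibull",
    "gompertz",
    "loglogistic",
    "lognormal",
    "gengamma",
)

FAMILIES: dict[str, SurvivalFamily] = {
    "exponential": Exponential(),
    "weibull": Weibull(),
    "gompertz": Gompertz(),
    "loglogistic": LogLogistic(),
    "lognormal": LogNormal(),
    "gengamma": GenGamma(),
}


def get_family(name: str) -> SurvivalFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise SurvivalError(
            f"unknown survival family {name!r}; choose from {FAMILY_ORDER}"
        ) from None


# ---------------------------------------------------------------------------
# Data and fitted-model containers
# ---------------------------------------------------------------------------


@dataclass
class TransitionDataset:
    """Right-censored times from entry into one state to one exit cause.

    Times are measured in years since state entry (clock reset); exits via
    competing causes appear as censored records at the competing exit time.
    """

    times: np.ndarray
    events: np.ndarray
    transition_id: str = "TP1"
    arm: str = "intervention"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise SurvivalError("times and events must have equal length")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise SurvivalError("times must be finite and strictly positive")
        if not np.all(np.isin(self.events, (0, 1))):
            raise SurvivalError("event indicators must be 0 or 1")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class ParametricSurvivalModel:
    """One fitted family for one transition pathway in one arm."""

    family: SurvivalFamily
    params: np.ndarray
    vcov: np.ndarray | None = None
    loglik: float = float("nan")
    n_events: int = 0
    n_obs: int = 0
    transition_id: str = ""
    arm: str = ""

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.size != self.family.n_params:
            raise SurvivalError(
                f"{self.family.name} expects {self.family.n_params} params, "
                f"got {self.params.size}"
            )
        if not np.all(np.isfinite(self.params)):
            raise SurvivalError("model parameters must be finite")
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, dtype=float)

    # -- evaluation ---------------------------------------------------------
    def _check_t(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise SurvivalError("negative time: survival quantities need t >= 0")
        return t

    def sf(self, t):
        return self.family.sf(self._check_t(t), self.params)

    def hazard(self, t):
        return self.family.hazard(self._check_t(t), self.params)

    def cumhaz(self, t):
        return self.family.cumhaz(self._check_t(t), self.params)

    def pdf(self, t):
        return self.family.pdf(self._check_t(t), self.params)

    def evaluate(self, t, quantity: str):
        """Evaluate S, h, H or f at time-since-state-entry ``t`` (years)."""
        fn = {"S": self.sf, "h": self.hazard, "H": self.cumhaz, "f": self.pdf}
        if quantity not in fn:
            raise SurvivalError(f"quantity must be one of S/h/H/f, got {quantity!r}")
        return fn[quantity](t)

    @property
    def aic(self) -> float:
        return 2.0 * self.family.n_params - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.family.n_params * math.log(max(self.n_obs, 1)) - 2.0 * self.loglik

    def natural_params(self) -> dict[str, float]:
        return self.family.natural_params(self.params)

    def with_params(self, params) -> "ParametricSurvivalModel":
        """Copy with a new coefficient vector (PSA/DSA perturbations)."""
        return ParametricSurvivalModel(
            family=self.family,
            params=np.asarray(params, dtype=float),
            vcov=self.vcov,
            loglik=self.loglik,
            n_events=self.n_events,
            n_obs=self.n_obs,
            transition_id=self.transition_id,
            arm=self.arm,
        )


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


def _negloglik(params, family, times, events):
    with np.errstate(over="ignore", invalid="ignore"):
        ls = family.log_sf(times, params)
        lp = family.log_pdf(times, params)
    ll = np.where(events == 1, lp, ls)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.sum(ll))


def _numeric_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = fun(x + ei)
                fmm = fun(x - ei)
                hess[i, i] = (fpp - 2.0 * f0 + fmm) / (h[i] * h[i])
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def fit_mle(data: TransitionDataset, family: SurvivalFamily | str) -> ParametricSurvivalModel:
    """Fit one family to right-censored times by maximum likelihood.

    Uses quasi-Newton (BFGS) on the unconstrained parameter scale with a
    deterministic set of moment-based starting points; the covariance is
    the inverse observed information at the optimum.
    """
    if isinstance(family, str):
        family = get_family(family)
    if data.n_events == 0:
        raise DegenerateFitError(
            f"{data.transition_id}/{data.arm}: no events; cannot fit {family.name}"
        )
    if data.n_events < family.n_params:
        raise DegenerateFitError(
            f"{data.transition_id}/{data.arm}: {data.n_events} events < "
            f"{family.n_params} parameters of {family.name}"
        )

    times, events = data.times, data.events
    obj = lambda p: _negloglik(p, family, times, events)

    best = None
    for x0 in family.initial_values(times, events):
        res = optimize.minimize(obj, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise ConvergenceError(
            f"MLE failed for {family.name} on {data.transition_id}/{data.arm} "
            f"after multi-start (n={data.n_obs}, events={data.n_events})"
        )

    hess = _numeric_hessian(obj, best.x)
    try:
        vcov = np.linalg.inv(hess)
        # Symmetrise and guard tiny negative eigenvalues from differencing.
        vcov = 0.5 * (vcov + vcov.T)
        evals, evecs = np.linalg.eigh(vcov)
        vcov = (evecs * np.maximum(evals, 0.0)) @ evecs.T
    except np.linalg.LinAlgError:
        vcov = np.full((family.n_params, family.n_params), np.nan)

    return ParametricSurvivalModel(
        family=family,
        params=best.x,
        vcov=vcov,
        loglik=-float(best.fun),
        n_events=data.n_events,
        n_obs=data.n_obs,
        transition_id=data.transition_id,
        arm=data.arm,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


@dataclass
class ModelSelection:
    """AIC/BIC ranking of candidate fits for one transition pathway."""

    ranked: list[ParametricSurvivalModel] = field(default_factory=list)

    @property
    def best(self) -> ParametricSurvivalModel:
        return self.ranked[0]

    @property
    def second_best(self) -> ParametricSurvivalModel:
        if len(self.ranked) < 2:
            raise SurvivalError("second-best model requested but only one fit supplied")
        return self.ranked[1]

    @property
    def top3(self) -> list[ParametricSurvivalModel]:
        if len(self.ranked) < 3:
            raise SurvivalError("top-3 candidate set requested but fewer than 3 fits supplied")
        return self.ranked[:3]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [m.family.name for m in self.ranked],
                "n_params": [m.family.n_params for m in self.ranked],
                "loglik": [m.loglik for m in self.ranked],
                "AIC": [m.aic for m in self.ranked],
                "BIC": [m.bic for m in self.ranked],
            }
        )


def select_model(fits: Sequence[ParametricSurvivalModel]) -> ModelSelection:
    """Rank fits by AIC (BIC, then fewer parameters, then fixed family order
    as tie-breaks).  All fits must come from the same dataset."""
    fits = list(fits)
    if not fits:
        raise SurvivalError("select_model needs at least one fitted model")
    n_obs = {m.n_obs for m in fits}
    if len(n_obs) != 1:
        raise SurvivalError("fits being compared must share one dataset (n_obs differ)")

    def key(m: ParametricSurvivalModel):
        return (m.aic, m.bic, m.family.n_params, FAMILY_ORDER.index(m.family.name))

    return ModelSelection(ranked=sorted(fits, key=key))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_transition_datasets(path) -> dict[tuple[str, str], TransitionDataset]:
    """Read the (id, arm, transition_id, time_years, event) CSV layout into
    one TransitionDataset per (transition, arm)."""
    df = pd.read_csv(path)
    required = {"id", "arm", "transition_id", "time_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SurvivalError(f"transition CSV missing column(s): {sorted(missing)}")
    out = {}
    for (tp, arm), grp in df.groupby(["transition_id", "arm"], sort=True):
        out[(str(tp), str(arm))] = TransitionDataset(
            times=grp["time_years"].to_numpy(),
            events=grp["event"].to_numpy(),
            transition_id=str(tp),
            arm=str(arm),
        )
    return out


def _model_to_dict(m: ParametricSurvivalModel) -> dict:
    return {
        "family": m.family.name,
        "param_names": list(m.family.param_names),
        "params": m.params.tolist(),
        "natural_params": m.natural_params(),
        "vcov": None if m.vcov is None else m.vcov.tolist(),
        "loglik": m.loglik,
        "AIC": m.aic,
        "BIC": m.bic,
        "n_events": m.n_events,
        "n_obs": m.n_obs,
        "transition_id": m.transition_id,
        "arm": m.arm,
    }


def _model_from_dict(d: dict) -> ParametricSurvivalModel:
    return ParametricSurvivalModel(
        family=get_family(d["family"]),
        params=np.asarray(d["params"], dtype=float),
        vcov=None if d.get("vcov") is None else np.asarray(d["vcov"], dtype=float),
        loglik=float(d.get("loglik", float("nan"))),
        n_events=int(d.get("n_events", 0)),
        n_obs=int(d.get("n_obs", 0)),
        transition_id=d.get("transition_id", ""),
        arm=d.get("arm", ""),
    )


def models_to_json(models: Sequence[ParametricSurvivalModel], path=None) -> str:
    payload = json.dumps([_model_to_dict(m) for m in models], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def models_from_json(source) -> list[ParametricSurvivalModel]:
    """Load fitted models from a JSON string or file path."""
    if isinstance(source, str) and source.lstrip().startswith("["):
        data = json.loads(source)
    else:
        with open(source) as fh:
            data = json.load(fh)
    return [_model_from_dict(d) for d in data]
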