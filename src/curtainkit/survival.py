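"""Dwell-time analysis: Kaplan-Meier survival and double-exponential fits.

Binding lifetimes of single complexes on DNA are right-censored by the
finite observation window (bleaching-limited or recording-limited), so
the survival curve is estimated with the Kaplan-Meier product-limit
estimator and summarized by a two-population mixture

    S(t) = (1 - f) exp(-t / tau_short) + f exp(-t / tau_long),

where f is the long-lived fraction.  The mixture is fitted either by
censored-data maximum likelihood (default) or by least squares to the
Kaplan-Meier curve (compatibility mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.optimize import minimize

__all__ = [
    "SurvivalData",
    "SurvivalModel",
    "KaplanMeierCurve",
    "DoubleExpFit",
    "kaplan_meier",
    "bootstrap_band",
    "fit_double_exponential",
]


@dataclass
class SurvivalData:
    """Observed dwell times with right-censoring flags."""

    durations: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored flags must match in length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")

    def __len__(self) -> int:
        return len(self.durations)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"duration": self.durations, "censored": self.censored.astype(int)}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalData":
        df = pd.read_csv(path)
        return cls(df["duration"].to_numpy(), df["censored"].to_numpy().astype(bool))


@dataclass(frozen=True)
class SurvivalModel:
    """Double-exponential survival S(t) = (1-f) e^{-t/ts} + f e^{-t/tl}.

    Label switching is resolved at construction: components are relabeled
    so that tau_short <= tau_long.
    """

    f_long: float
    tau_short: float
    tau_long: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_long <= 1:
            raise ValueError("f_long must be in [0, 1]")
        if self.tau_short <= 0 or self.tau_long <= 0:
            raise ValueError("time constants must be > 0")
        if self.tau_short > self.tau_long:
            object.__setattr__(self, "f_long", 1.0 - self.f_long)
            ts, tl = self.tau_long, self.tau_short
            object.__setattr__(self, "tau_short", ts)
            object.__setattr__(self, "tau_long", tl)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        s = (1 - self.f_long) * np.exp(-t / self.tau_short) + self.f_long * np.exp(
            -t / self.tau_long
        )
        return s if s.ndim else float(s)

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        d = (1 - self.f_long) / self.tau_short * np.exp(
            -t / self.tau_short
        ) + self.f_long / self.tau_long * np.exp(-t / self.tau_long)
        return d if d.ndim else float(d)


@dataclass
class KaplanMeierCurve:
    """Right-continuous non-increasing step estimate of S(t), S(0) = 1."""

    times: np.ndarray  # event times where S steps down
    survival: np.ndarray  # S just after each event time

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return s if s.ndim else float(s)


def kaplan_meier(data: SurvivalData) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimate.

    Censored molecules leave the risk set without stepping the curve; tied
    event times produce one combined step.  Raises if every observation is
    censored (no estimable events).
    """
    if np.all(data.censored):
        raise ValueError("all observations censored: no events to estimate from")
    kmf = KaplanMeierFitter()
    kmf.fit(data.durations, event_observed=~data.censored)
    sf = kmf.survival_function_["KM_estimate"]
    # keep only times where the curve actually steps (event times)
    times = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)
    steps = np.flatnonzero(np.diff(np.concatenate([[1.0], vals])) < 0)
    return KaplanMeierCurve(times[steps], vals[steps])


def bootstrap_band(
    data: SurvivalData,
    B: int = 1000,
    level: float = 0.68,
    seed: int | None = 0,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pointwise percentile confidence band for S(t) from case bootstrap.

    Molecules (duration, censored) pairs are resampled with replacement B
    times; at each grid time the (1-level)/2 and (1+level)/2 percentiles
    of the resampled Kaplan-Meier curves form the band.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile band")
    km = kaplan_meier(data)
    if times is None:
        times = km.times
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(data)
    curves = np.empty((B, len(times)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = SurvivalData(data.durations[idx], data.censored[idx])
        if np.all(boot.censored):  # rare degenerate resample
            curves[b] = 1.0
            continue
        curves[b] = kaplan_meier(boot)(times)
    qlo, qhi = (1 - level) / 2, (1 + level) / 2
    lo = np.quantile(curves, qlo, axis=0)
    hi = np.quantile(curves, qhi, axis=0)
    s = km(times)
    return pd.DataFrame({"t": times, "S": s, "lo": np.minimum(lo, s),
                         "hi": np.maximum(hi, s)})


@dataclass
class DoubleExpFit:
    """Fitted double-exponential model with diagnostics."""

    model: SurvivalModel
    se: dict = field(default_factory=dict)
    loglik: float = np.nan
    mode: str = "mle"
    converged: bool = True
    message: str = ""


def _neg_loglik(theta: np.ndarray, t: np.ndarray, cens: np.ndarray) -> float:
    # theta = (logit f, log ts, log tl)
    f = 1.0 / (1.0 + np.exp(-theta[0]))
    ts, tl = np.exp(theta[1]), np.exp(theta[2])
    dens = (1 - f) / ts * np.exp(-t / ts) + f / tl * np.exp(-t / tl)
    surv = (1 - f) * np.exp(-t / ts) + f * np.exp(-t / tl)
    with np.errstate(divide="ignore"):
        ll = np.where(cens, np.log(np.maximum(surv, 1e-300)),
                      np.log(np.maximum(dens, 1e-300)))
    return -float(np.sum(ll))


def fit_double_exponential(
    data: SurvivalData,
    mode: str = "mle",
    n_restarts: int = 10,
    seed: int = 0,
) -> DoubleExpFit:
    """Fit the two-population mixture to dwell-time data.

    mode="mle" (default) maximizes the censored-data likelihood: censored
    observations contribute S(t), events contribute the density.
    mode="curve" least-squares fits the model survival to the Kaplan-Meier
    step values at the event times.  Initialization splits the data at the
    median lifetime (method of moments) plus random restarts; the best of
    all starts is kept and non-convergence is flagged, never silent.
    """
    n_events = int(np.sum(~data.censored))
    if n_events < 30:
        warnings.warn(
            f"only {n_events} uncensored events: three-parameter fit may be "
            "poorly identified", stacklevel=2,
        )
    t, cens = data.durations, data.censored
    rng = np.random.default_rng(seed)

    # method-of-moments start: split at the median lifetime
    med = np.median(t)
    lo_mean = max(np.mean(t[t <= med]), 1e-6)
    hi_mean = max(np.mean(t[t > med]), lo_mean * 1.5) if np.any(t > med) else lo_mean * 2
    starts = [np.array([0.0, np.log(lo_mean), np.log(hi_mean)])]
    for _ in range(n_restarts):
        starts.append(
            np.array([
                rng.normal(0, 1.5),
                np.log(lo_mean) + rng.normal(0, 1.0),
                np.log(hi_mean) + rng.normal(0, 1.0),
            ])
        )

    if mode == "mle":
        objective = lambda th: _neg_loglik(th, t, cens)  # noqa: E731
    elif mode == "curve":
        km = kaplan_meier(data)

        def objective(th: np.ndarray) -> float:
            f = 1.0 / (1.0 + np.exp(-th[0]))
            ts, tl = np.exp(th[1]), np.exp(th[2])
            pred = (1 - f) * np.exp(-km.times / ts) + f * np.exp(-km.times / tl)
            return float(np.sum((pred - km.survival) ** 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    f = 1.0 / (1.0 + np.exp(-best.x[0]))
    ts, tl = np.exp(best.x[1]), np.exp(best.x[2])
    model = SurvivalModel(f, ts, tl)

    # crude curvature-based standard errors on the natural scale
    se = {}
    if mode == "mle":
        try:
            h = _numeric_hessian(lambda th: _neg_loglik(th, t, cens), best.x)
            cov = np.linalg.inv(h)
            dse = np.sqrt(np.maximum(np.diag(cov), 0))
            se = {
                "f_long": float(dse[0] * f * (1 - f)),
                "tau_short": float(dse[1] * ts),
                "tau_long": float(dse[2] * tl),
            }
        except np.linalg.LinAlgError:
            se = {}
    return DoubleExpFit(
        model,
        se=se,
        loglik=-best.fun if mode == "mle" else np.nan,
        mode=mode,
        converged=bool(best.success),
        message=str(best.message),
    )


def _numeric_hessian(fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
            ) / (4 * eps * eps)
    return h
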