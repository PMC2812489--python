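"""Logistic recovery fitting: equilibrium size K and return time phi.

Log abundance after a perturbation is modelled with the three-parameter
logistic

    ln N(t) = ln K / (1 + exp((m - t) / phi))

where K is the equilibrium population size, m the inflection time (the
time at which ln N reaches ln(K)/2, i.e. abundance sqrt(K)) and phi the
shape parameter: the log-scale deviation from equilibrium decays by a
factor e per phi years, so phi is the return time (reciprocal of the
return rate).  A four-parameter form with a lower asymptote A,

    ln N(t) = A + (ln K - A) / (1 + exp((m - t) / phi)),

accommodates species whose growth rate initially increases after the
disturbance (skylark).  Weather years enter as a random grouping factor:
the asymptote of year-label y is ln K + b_y with b_y ~ Normal(0, sigma_b^2).

Estimation is two-stage: (1) pooled nonlinear least squares for the fixed
curve; (2) per-label asymptote deviations from label means of late-window
residuals with empirical-Bayes shrinkage, variance components by method
of moments.  Confidence intervals come from a parametric bootstrap of the
fitted mixed model.  The exposed contract is the estimates, intervals and
convergence flag, not the estimation algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._rng import child_rng

__all__ = [
    "logistic3",
    "logistic4",
    "LogisticFit",
    "fit_recovery",
    "fit_unperturbed",
    "UnperturbedFit",
    "segmentwise_K",
    "simulate_logistic_trajectory",
]

_PHI_MIN = 0.05


def logistic3(t, lnK, m, phi):
    """Three-parameter logistic on the log scale: lnK / (1 + exp((m - t)/phi)).

    Strictly increasing in t with upper asymptote lnK (for lnK > 0);
    at t = m the value is lnK/2, so abundance equals sqrt(K).
    """
    if np.any(np.asarray(phi) <= 0):
        raise ValueError("phi must be positive")
    t = np.asarray(t, dtype=float)
    return lnK / (1.0 + np.exp((m - t) / phi))


def logistic4(t, A, lnK, m, phi):
    """Four-parameter logistic: A + (lnK - A) / (1 + exp((m - t)/phi)).

    Lower asymptote A (as t -> -inf), upper asymptote lnK; reduces to
    :func:`logistic3` when A = 0.
    """
    if np.any(np.asarray(phi) <= 0):
        raise ValueError("phi must be positive")
    t = np.asarray(t, dtype=float)
    return A + (lnK - A) / (1.0 + np.exp((m - t) / phi))


@dataclass
class LogisticFit:
    """Result of a mixed logistic recovery fit."""

    K: float = float("nan")
    m: float = float("nan")
    phi: float = float("nan")
    A: float | None = None
    sigma_b: float = float("nan")
    sigma_e: float = float("nan")
    b_y: dict = field(default_factory=dict)
    K_ci: tuple | None = None
    phi_ci: tuple | None = None
    converged: bool = False
    n_obs: int = 0
    n_zero_dropped: int = 0
    form: int = 3
    diagnostic: str = ""

    @property
    def lnK(self) -> float:
        return math.log(self.K) if self.K > 0 else float("nan")


def _stack_segments(segments) -> pd.DataFrame:
    frames = []
    for seg in segments:
        df = seg if isinstance(seg, pd.DataFrame) else pd.DataFrame(seg, columns=["t", "lnN", "weather_label"])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _nls(t, lnN, form, L):
    """Pooled nonlinear least squares; returns (params, success, at_bound)."""
    lnK0 = float(np.max(lnN))
    if lnK0 <= 0:
        lnK0 = 0.1
    above = t[lnN >= lnK0 / 2.0]
    m0 = float(above.min()) if above.size else float(np.median(t))
    phi0 = max(_PHI_MIN * 2, L / 8.0)
    phi_hi = 10.0 * L
    if form == 3:
        p0 = [lnK0, m0, phi0]
        lo = [1e-8, -L, _PHI_MIN]
        hi = [np.inf, 2.0 * L, phi_hi]

        def resid(p):
            return logistic3(t, *p) - lnN

    else:
        A0 = float(np.min(lnN))
        p0 = [min(A0, lnK0 - 1e-3), lnK0, m0, phi0]
        lo = [-20.0, 1e-8, -L, _PHI_MIN]
        hi = [lnK0 + 5.0, np.inf, 2.0 * L, phi_hi]

        def resid(p):
            return logistic4(t, *p) - lnN

    p0 = np.clip(p0, lo, hi)
    try:
        res = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:
        return None, False, True
    p = res.x
    phi = p[-1]
    at_bound = phi <= _PHI_MIN * (1 + 1e-6) or phi >= phi_hi * (1 - 1e-6)
    return p, bool(res.success), at_bound


def _predict(p, t, form):
    return logistic3(t, *p) if form == 3 else logistic4(t, *p)


def _label_components(t, lnN, y, p, form):
    """Late-window label offsets with EB shrinkage + MoM variance components."""
    lnK, m, phi = (p[0], p[1], p[2]) if form == 3 else (p[1], p[2], p[3])
    late = t >= m + phi
    if late.sum() < 2 * len(set(y[late])) or len(set(y[late])) < 2:
        late = t >= np.median(t)
    r = lnN[late] - _predict(p, t[late], form)
    yl = y[late]
    labels = pd.unique(yl)
    d = np.array([r[yl == lab].mean() for lab in labels])
    n_y = np.array([(yl == lab).sum() for lab in labels])
    within = np.concatenate([r[yl == lab] - d[i] for i, lab in enumerate(labels)])
    dof = max(1, within.size - len(labels))
    sigma_e2 = float((within**2).sum() / dof)
    var_d = float(np.var(d, ddof=1)) if len(d) > 1 else 0.0
    sigma_b2 = max(0.0, var_d - sigma_e2 * float(np.mean(1.0 / n_y)))
    lam = sigma_b2 / (sigma_b2 + sigma_e2 / n_y) if sigma_b2 > 0 else np.zeros(len(d))
    b = {lab: float(lam[i] * d[i]) for i, lab in enumerate(labels)}
    return b, math.sqrt(sigma_b2), math.sqrt(sigma_e2)


def fit_recovery(
    segments,
    form: int = 3,
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> LogisticFit:
    """Fit the mixed logistic recovery model to pooled recovery segments.

    ``segments`` is a list of DataFrames (or record lists) with columns
    t, lnN, weather_label; rows with undefined lnN (zero counts) are
    excluded and counted.  Requires >= 8 usable points spanning >= 2
    weather labels.  Returns a :class:`LogisticFit` with parametric-
    bootstrap confidence intervals for K and phi; on optimizer failure or
    a shape parameter pinned at its bounds, ``converged`` is False and no
    intervals are reported (no exception is raised).
    """
    if form not in (3, 4):
        raise ValueError("form must be 3 or 4")
    data = _stack_segments(segments)
    n_zero = int(data["lnN"].isna().sum())
    data = data.dropna(subset=["lnN"])
    t = data["t"].to_numpy(float)
    lnN = data["lnN"].to_numpy(float)
    y = data["weather_label"].to_numpy()
    labels = pd.unique(y)
    if len(labels) < 2:
        raise ValueError("fewer than 2 weather labels: fit a pooled (unlabelled) model instead")
    if t.size < 8:
        raise ValueError(f"need >= 8 usable points, got {t.size}")
    fit = LogisticFit(n_obs=int(t.size), n_zero_dropped=n_zero, form=form)
    if np.ptp(lnN) < 1e-12:
        fit.diagnostic = "no growth signal"
        return fit

    L = float(np.max(t))
    p, ok, at_bound = _nls(t, lnN, form, L)
    if p is None or not ok or at_bound:
        fit.diagnostic = "optimizer failed" if p is None or not ok else "phi at bounds"
        return fit

    if form == 3:
        lnK, m, phi, A = p[0], p[1], p[2], None
    else:
        A, lnK, m, phi = p
    b, sigma_b, sigma_e = _label_components(t, lnN, y, p, form)

    fit.K = math.exp(lnK)
    fit.m = float(m)
    fit.phi = float(phi)
    fit.A = None if A is None else float(A)
    fit.sigma_b, fit.sigma_e = sigma_b, sigma_e
    fit.b_y = b
    fit.converged = True

    if n_boot and n_boot > 0:
        rng = child_rng(seed, "bootstrap")
        lnK_bs, phi_bs = [], []
        q = len(labels)
        for _ in range(n_boot):
            # scale sigma_b by an inverse-chi-square draw so the intervals
            # carry the sampling uncertainty of the variance component
            sb = sigma_b * math.sqrt((q - 1) / float(rng.chisquare(q - 1))) if q > 1 else sigma_b
            b_star = {lab: rng.normal(0.0, sb) for lab in labels}
            shift = np.array([b_star[lab] for lab in y])
            if form == 3:
                mu = logistic3(t, lnK + shift, m, phi)
            else:
                mu = logistic4(t, A, lnK + shift, m, phi)
            lnN_star = mu + rng.normal(0.0, sigma_e, size=t.size)
            p_s, ok_s, bad_s = _nls(t, lnN_star, form, L)
            if p_s is None or not ok_s or bad_s:
                continue
            lnK_bs.append(p_s[0] if form == 3 else p_s[1])
            phi_bs.append(p_s[-1])
        if len(lnK_bs) >= max(20, n_boot // 4):
            a = (1.0 - ci_level) / 2.0
            fit.K_ci = tuple(np.exp(np.quantile(lnK_bs, [a, 1.0 - a])))
            fit.phi_ci = tuple(np.quantile(phi_bs, [a, 1.0 - a]))
        else:
            fit.converged = False
            fit.diagnostic = "bootstrap refits failed"
    return fit


@dataclass
class UnperturbedFit:
    """Per-weather-label equilibrium fit for an unperturbed trajectory."""

    K: float
    intercepts: dict
    sigma_e: float
    n_obs: int


def fit_unperturbed(trajectory) -> UnperturbedFit:
    """Intercept-only equilibrium model with weather-year intercepts.

    ln N is modelled as a per-label intercept plus homogeneous Gaussian
    noise; the grand equilibrium K is the exponential of the mean of the
    label intercepts.
    """
    rec = trajectory.analyzed
    rec = rec[rec["N"] > 0]
    if len(rec) == 0:
        raise ValueError("empty (or fully extinct) analyzed trajectory")
    lnN = np.log(rec["N"].to_numpy(float))
    y = rec["weather_label"].to_numpy()
    labels = pd.unique(y)
    intercepts = {lab: float(lnN[y == lab].mean()) for lab in labels}
    resid = lnN - np.array([intercepts[lab] for lab in y])
    dof = max(1, lnN.size - len(labels))
    sigma_e = math.sqrt(float((resid**2).sum() / dof))
    K = math.exp(float(np.mean(list(intercepts.values()))))
    return UnperturbedFit(K=K, intercepts=intercepts, sigma_e=sigma_e, n_obs=int(lnN.size))


def segmentwise_K(segments, seed: int = 0) -> pd.DataFrame:
    """Per-segment asymptotes with shared inflection and shape.

    Fits ln N(t) = lnK_j / (1 + exp((m - t)/phi)) with one free asymptote
    per recovery segment j and (m, phi) shared, enabling inspection of
    equilibrium decline across successive perturbations.  Returns a
    DataFrame (segment, K, se_K, lnK, se_lnK) in segment order; standard
    errors from the Gauss-Newton covariance.
    """
    if len(segments) < 2:
        raise ValueError("need >= 2 segments for segmentwise asymptotes")
    ts, lnNs, seg_idx = [], [], []
    for j, seg in enumerate(segments):
        df = seg.dropna(subset=["lnN"])
        ts.append(df["t"].to_numpy(float))
        lnNs.append(df["lnN"].to_numpy(float))
        seg_idx.append(np.full(len(df), j))
    t = np.concatenate(ts)
    lnN = np.concatenate(lnNs)
    j = np.concatenate(seg_idx)
    nseg = len(segments)
    L = float(np.max(t))

    lnK0 = max(0.1, float(np.max(lnN)))
    m0 = float(t[lnN >= lnK0 / 2].min()) if (lnN >= lnK0 / 2).any() else L / 4.0
    p0 = np.concatenate([[m0, L / 8.0], np.full(nseg, lnK0)])
    lo = np.concatenate([[-L, _PHI_MIN], np.full(nseg, 1e-8)])
    hi = np.concatenate([[2 * L, 10 * L], np.full(nseg, np.inf)])

    def resid(p):
        m, phi = p[0], p[1]
        lnKj = p[2:][j]
        return lnKj / (1.0 + np.exp((m - t) / phi)) - lnN

    res = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi), xtol=1e-13, ftol=1e-13)
    if not res.success:
        raise RuntimeError("segmentwise asymptote fit did not converge")
    dof = max(1, t.size - res.x.size)
    s2 = float((res.fun**2).sum() / dof)
    J = res.jac
    cov = s2 * np.linalg.pinv(J.T @ J)
    se = np.sqrt(np.diag(cov))
    lnKj = res.x[2:]
    se_lnKj = se[2:]
    return pd.DataFrame(
        {
            "segment": np.arange(nseg),
            "K": np.exp(lnKj),
            "se_K": np.exp(lnKj) * se_lnKj,
            "lnK": lnKj,
            "se_lnK": se_lnKj,
            "m": res.x[0],
            "phi": res.x[1],
        }
    )


def simulate_logistic_trajectory(
    K: float,
    m: float,
    phi: float,
    sigma_e: float,
    sigma_b: float,
    n_segments: int = 10,
    segment_length: int = 17,
    n_labels: int = 10,
    seed: int = 0,
) -> list:
    """Synthetic recovery segments from the mixed logistic model.

    ln N(t) = logistic3(t; lnK + b_y, m, phi) + eps with eps ~ N(0,
    sigma_e^2) and label effects b_y ~ N(0, sigma_b^2) fixed per label
    across the whole run.  Calendar years run consecutively across
    segments so labels cycle with period ``n_labels``.  Deterministic
    given ``seed``.
    """
    if min(K, phi) <= 0 or segment_length < 1 or n_segments < 1:
        raise ValueError("parameters must be positive")
    rng = child_rng(seed, "sim-logistic")
    lnK = math.log(K)
    b = rng.normal(0.0, sigma_b, size=n_labels)
    segs = []
    year = 0
    for s in range(n_segments):
        rows = []
        for t in range(1, segment_length + 1):
            year += 1
            lab_i = (year - 1) % n_labels
            mu = logistic3(float(t), lnK + b[lab_i], m, phi)
            lnN = mu + rng.normal(0.0, sigma_e)
            rows.append((float(t), float(lnN), f"w{lab_i}"))
        segs.append(pd.DataFrame(rows, columns=["t", "lnN", "weather_label"]))
    return segs
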