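"""Variability-based feature filtering.

Transcripts are split into low- and high-variability components by fitting a
two-component Gaussian mixture to the per-feature coefficient of variation
(CV) with the EM algorithm; features assigned to the high component (by
posterior probability) are retained for downstream analysis.

The EM is a plain univariate two-component fit: responsibilities in the
E-step, weighted moments in the M-step, with a median-split initialization
plus random restarts and a guard against collapsing components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureMatrix, ValidationError

log = logging.getLogger(__name__)


def compute_cv(fm: FeatureMatrix, scale: str = "linear") -> pd.Series:
    """Per-feature coefficient of variation (sample SD / mean) across samples.

    ``scale="linear"`` (default) un-logs the stored log2 values first: the CV
    of log-scale values is ill-defined near zero. ``scale="log"`` computes it
    on the stored values directly.
    """
    if fm.n_samples < 2:
        raise ValidationError("CV needs at least 2 samples")
    if scale == "linear":
        x = np.exp2(fm.values)
    elif scale == "log":
        x = fm.values
    else:
        raise ValidationError(f"cv scale must be 'linear' or 'log', got {scale!r}")
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    bad = mean <= 0
    if bad.any():
        offenders = [fm.feature_ids[i] for i in np.flatnonzero(bad)[:5]]
        raise ValidationError(f"features with non-positive mean abundance: {offenders}")
    return pd.Series(sd / mean, index=fm.feature_ids, name="cv")


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture; components ordered so that
    ``means[0] < means[1]``; ``posterior_high`` is P(high component | CV)."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    posterior_high: pd.Series
    loglik_trace: list[float] = field(default_factory=list)


def _em_once(
    x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, np.ndarray, list[float]]:
    n = x.size
    sd_floor = 1e-6 * x.std()
    trace: list[float] = []
    prev = -np.inf
    converged = False
    resp = np.empty((n, 2))
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        logdens = np.stack(
            [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)], axis=1
        )
        m = logdens.max(axis=1, keepdims=True)
        pointwise = m[:, 0] + np.log(np.exp(logdens - m).sum(axis=1))
        loglik = float(pointwise.sum())
        trace.append(loglik)
        resp = np.exp(logdens - pointwise[:, None])
        if np.isfinite(prev) and loglik < prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # violates EM guarantee
        if np.isfinite(prev) and abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
        # M-step
        nk = resp.sum(axis=0)
        if nk.min() < 1e-12:
            raise _DegenerateFit("a component lost all responsibility")
        w = nk / n
        mu = resp.T @ x / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if sd.min() < sd_floor:
            raise _DegenerateFit(f"component SD collapsed below {sd_floor:.3g}")
    return w, mu, sd, trace[-1], len(trace), converged, resp, trace


class _DegenerateFit(RuntimeError):
    pass


def fit_gaussian_mixture_em(
    cv: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    n_restarts: int = 5,
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to the CV distribution.

    Initialization: median split, then ``n_restarts - 1`` random splits; the
    fit with the best log-likelihood wins. A component whose SD collapses
    below 1e-6 x data SD triggers a restart; if every start degenerates the
    fit errors out.
    """
    x = np.asarray(cv, dtype=float)
    if x.size < 10:
        raise ValidationError(f"need >=10 features to fit a mixture, got {x.size}")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    if x.std() == 0:
        raise ValidationError("degenerate fit: all CV values identical")

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            split = np.median(x)
        else:
            split = rng.uniform(np.quantile(x, 0.2), np.quantile(x, 0.8))
        lo, hi = x[x <= split], x[x > split]
        if lo.size < 2 or hi.size < 2:
            continue
        w0 = np.array([lo.size, hi.size], dtype=float) / x.size
        mu0 = np.array([lo.mean(), hi.mean()])
        sd0 = np.maximum(np.array([lo.std(), hi.std()]), 1e-3 * x.std())
        try:
            result = _em_once(x, w0, mu0, sd0, tol, max_iter)
        except _DegenerateFit as err:
            log.warning("EM restart %d degenerated: %s", restart, err)
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise ValidationError("degenerate fit: every EM restart collapsed")

    w, mu, sd, loglik, n_iter, converged, resp, trace = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    posterior_high = pd.Series(resp[:, order[1]], index=cv.index, name="posterior_high")
    return MixtureFit(w, mu, sd, loglik, n_iter, converged, posterior_high, trace)


def select_high_variance(
    fm: FeatureMatrix, fit: MixtureFit, cutoff: float = 0.5
) -> FeatureMatrix:
    """Retain features whose posterior probability of the high-variability
    component is at least ``cutoff`` (0.5 = maximum a posteriori)."""
    if not fit.converged:
        log.warning("mixture fit did not converge; selection may be unstable")
    keep = fit.posterior_high.index[fit.posterior_high >= cutoff]
    keep = [f for f in fm.feature_ids if f in set(keep)]  # preserve matrix order
    if not keep:
        raise ValidationError(
            "no features retained at this posterior cutoff; review the cutoff"
        )
    log.info("variance filter retained %d / %d features", len(keep), fm.n_features)
    return fm.subset(keep)
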