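"""Comparing the one- and two-environment hypotheses.

Marginal likelihoods are estimated from posterior samples with a generalized
harmonic mean (GHM) estimator: a multivariate normal importance density q is
fitted to the retained samples (sample mean; sample variances inflated by a
variance-scaling factor, treated as diagonal for numerical robustness in the
~10³-dimensional parameter space), and

    log M = −log( (1/S) Σ_s exp[ log q(θ_s) − log(prior × likelihood)(θ_s) ] )

evaluated with max-subtraction. The stored unnormalized log posterior of the
trace is reused; the likelihood is never re-evaluated. Larger variance
scalings can only increase the estimate, so small scalings (default 1.1)
give conservative Bayes factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .mutsel import PosteriorTrace


def ghm_log_marginal(
    trace: PosteriorTrace | tuple[np.ndarray, np.ndarray],
    variance_scaling: float = 1.1,
    min_samples: int = 100,
) -> float:
    """Generalized-harmonic-mean estimate of the log marginal likelihood.

    ``trace`` is either a :class:`PosteriorTrace` (its retained window is
    used, widened to at least ``min_samples``) or a ``(theta, log_post)``
    pair of posterior draws and their unnormalized log posterior densities.
    """
    if isinstance(trace, PosteriorTrace):
        s = len(trace.samples)
        keep = max(len(trace.retained_index()), min(min_samples, s))
        theta = trace.samples[s - keep :]
        log_post = trace.log_post[s - keep :]
    else:
        theta, log_post = trace
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if theta.shape[0] == 1 and len(log_post) > 1:
            theta = theta.T
        log_post = np.asarray(log_post, dtype=float)
    if len(theta) < min_samples:
        raise ValueError(
            f"need at least {min_samples} retained samples, got {len(theta)}"
        )
    if not np.isfinite(theta).all() or not np.isfinite(log_post).all():
        raise ValueError("non-finite samples or log-posterior values")

    mean = theta.mean(axis=0)
    var = theta.var(axis=0, ddof=1) * variance_scaling
    if np.any(var <= 0):
        raise ValueError(
            "degenerate (zero-variance) parameter dimension; "
            "more samples are needed for the importance density"
        )
    z = (theta - mean) / np.sqrt(var)
    log_q = -0.5 * np.sum(z**2, axis=1) - 0.5 * np.sum(np.log(2 * np.pi * var))
    return float(-(logsumexp(log_q - log_post) - np.log(len(theta))))


def log_bayes_factor(log_marginal_a: float, log_marginal_b: float) -> float:
    """log K = log M_a − log M_b (positive favors model a)."""
    if not (np.isfinite(log_marginal_a) and np.isfinite(log_marginal_b)):
        raise ValueError("log marginal likelihoods must be finite")
    return float(log_marginal_a - log_marginal_b)


def likelihood_ratio_test(
    loglik_full: float,
    n_full: int,
    loglik_reduced: float,
    n_reduced: int,
) -> tuple[float, int, float]:
    """Chi-square LRT of nested models: returns (statistic, df, p)."""
    df = n_full - n_reduced
    if df <= 0:
        raise ValueError(f"full model must have more parameters (df={df})")
    if loglik_full < loglik_reduced:
        import warnings

        warnings.warn(
            "full-model log-likelihood below the reduced model's; "
            "the LRT statistic is negative",
            stacklevel=2,
        )
    stat = 2.0 * (loglik_full - loglik_reduced)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def compare_models(
    trace_separated: PosteriorTrace,
    trace_combined: PosteriorTrace,
    loglik_separated: float,
    n_separated: int,
    loglik_combined: float,
    n_combined: int,
    variance_scaling: float = 1.1,
) -> pd.DataFrame:
    """Model-comparison report: log L, n, log marginal, log K, LRT p-value."""
    log_m_sep = ghm_log_marginal(trace_separated, variance_scaling)
    log_m_comb = ghm_log_marginal(trace_combined, variance_scaling)
    log_k = log_bayes_factor(log_m_sep, log_m_comb)
    stat, df, p = likelihood_ratio_test(
        loglik_separated, n_separated, loglik_combined, n_combined
    )
    return pd.DataFrame(
        [
            {
                "hypothesis": "combined",
                "log_lik": loglik_combined,
                "n_parameters": n_combined,
                "log_marginal": log_m_comb,
                "log_bayes_factor": np.nan,
                "lrt_p": np.nan,
            },
            {
                "hypothesis": "separated",
                "log_lik": loglik_separated,
                "n_parameters": n_separated,
                "log_marginal": log_m_sep,
                "log_bayes_factor": log_k,
                "lrt_p": p,
            },
        ]
    )
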