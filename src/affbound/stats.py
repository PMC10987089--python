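"""Statistical kernels: Fisher transform, dependent-correlation tests,
normal-prior Bayes factors, and percentile bootstrap intervals.

These are the reusable pieces behind the boundary statistics.  The
Bayes factor follows the normal-normal construction: the observed
Fisher-z value is modeled as ``N(theta, se^2)`` and the two hypotheses
put normal priors on ``theta`` (H0 standard normal at 0; H1 normal at 2
by default), so both marginal likelihoods are available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_io import InsufficientDataError


def fisher_z(r):
    """arctanh of a correlation; strictly increasing, odd, requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    """Inverse Fisher transform (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def fisher_se(n: int) -> float:
    """Asymptotic SE of a Fisher-z value from n paired samples."""
    if n <= 3:
        raise InsufficientDataError("Fisher-z SE requires n > 3")
    return 1.0 / np.sqrt(n - 3)


def correlation_se(r, n: int):
    """SE of a correlation coefficient, sqrt((1 - r^2) / (n - 2))."""
    if n <= 2:
        raise InsufficientDataError("correlation SE requires n > 2")
    r = np.asarray(r, dtype=float)
    out = np.sqrt((1.0 - r ** 2) / (n - 2))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BayesFactorSpec:
    """Normal priors on the Fisher-z scale for BF10.

    H0 defaults to a standard normal centered at zero and H1 to a
    normal centered at 2; the H1 spread is an assumption of this
    package (the value matters, see docs/methods.md) and is
    configurable.
    """

    h0_mean: float = 0.0
    h0_sd: float = 1.0
    h1_mean: float = 2.0
    h1_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.h0_sd <= 0 or self.h1_sd <= 0:
            raise ValueError("prior sds must be positive")

    def swapped(self) -> "BayesFactorSpec":
        return BayesFactorSpec(self.h1_mean, self.h1_sd, self.h0_mean, self.h0_sd)


def bayes_factor_normal(z_obs: float, se: float,
                        spec: BayesFactorSpec = BayesFactorSpec()) -> float:
    """BF10 for a normally observed z under two normal priors.

    Marginalizing ``z_obs ~ N(theta, se^2)`` over ``theta ~ N(m, sd^2)``
    gives ``z_obs ~ N(m, se^2 + sd^2)``; BF10 is the ratio of the two
    marginal densities.  ``se = 0`` is allowed (point observation).
    """
    if not (np.isfinite(z_obs) and np.isfinite(se)):
        raise ValueError("z_obs and se must be finite")
    if se < 0:
        raise ValueError("se must be non-negative")
    sd1 = np.sqrt(se ** 2 + spec.h1_sd ** 2)
    sd0 = np.sqrt(se ** 2 + spec.h0_sd ** 2)
    log_bf = (sps.norm.logpdf(z_obs, spec.h1_mean, sd1)
              - sps.norm.logpdf(z_obs, spec.h0_mean, sd0))
    return float(np.exp(log_bf))


def _check_psd_triple(r12: float, r13: float, r23: float) -> None:
    det = 1 + 2 * r12 * r13 * r23 - r12 ** 2 - r13 ** 2 - r23 ** 2
    if det < -1e-12:
        raise ValueError(
            f"correlation triple ({r12}, {r13}, {r23}) is not positive "
            "semidefinite")


def steiger_z(r12, r13, r23, n: int):
    """Steiger's Z for two overlapping dependent correlations.

    Tests ``H0: rho12 = rho13`` where both correlations share variable 1
    and are estimated from the same n samples; ``r23`` is the
    correlation between the two non-shared variables.  The Fisher-z
    difference is scaled by its asymptotic SE, which uses the pooled
    correlation.  Returns ``(Z, p)`` with a one-tailed p for the
    alternative ``rho12 > rho13``.
    """
    if n < 4:
        raise InsufficientDataError("steiger_z requires n >= 4")
    r12a, r13a, r23a = (np.asarray(v, dtype=float) for v in (r12, r13, r23))
    if np.any(np.abs(r12a) >= 1) or np.any(np.abs(r13a) >= 1):
        raise ValueError("|r12| and |r13| must be < 1 (Fisher-z diverges)")
    if np.ndim(r12) == 0:
        _check_psd_triple(float(r12a), float(r13a), float(r23a))
    rm = (r12a + r13a) / 2
    rm2 = rm ** 2
    cov = (r23a * (1 - 2 * rm2) - 0.5 * rm2 * (1 - 2 * rm2 - r23a ** 2)) \
        / (1 - rm2) ** 2
    diff = np.arctanh(r12a) - np.arctanh(r13a)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff * np.sqrt((n - 3) / (2 - 2 * cov))
    # equal correlations are a Z of exactly 0 even when the covariance
    # term degenerates (e.g. r23 -> 1 makes the SE collapse)
    z = np.where(diff == 0, 0.0, z)
    if np.ndim(r12) == 0 and not np.isfinite(z):
        raise ValueError(
            "degenerate correlation structure: the difference SE vanishes")
    p = sps.norm.sf(z)
    if np.ndim(r12) == 0:
        return float(z), float(p)
    return z, p


def zou_ci(r12, r13, r23, n: int, level: float = 0.95) -> tuple[float, float]:
    """Zou's confidence interval for the difference rho12 - rho13
    of two overlapping dependent correlations."""
    if n < 4:
        raise InsufficientDataError("zou_ci requires n >= 4")
    _check_psd_triple(r12, r13, r23)
    zcrit = sps.norm.ppf(1 - (1 - level) / 2)
    se = fisher_se(n)
    l1, u1 = np.tanh(np.arctanh(r12) + np.array([-1, 1]) * zcrit * se)
    l2, u2 = np.tanh(np.arctanh(r13) + np.array([-1, 1]) * zcrit * se)
    c = (((r23 - 0.5 * r12 * r13) * (1 - r12 ** 2 - r13 ** 2 - r23 ** 2)
          + r23 ** 3)
         / ((1 - r12 ** 2) * (1 - r13 ** 2)))
    diff = r12 - r13
    lo = diff - np.sqrt((r12 - l1) ** 2 + (u2 - r13) ** 2
                        - 2 * c * (r12 - l1) * (u2 - r13))
    hi = diff + np.sqrt((u1 - r12) ** 2 + (r13 - l2) ** 2
                        - 2 * c * (u1 - r12) * (r13 - l2))
    return float(lo), float(hi)


def percentile_bootstrap_ci(values, level: float = 0.95, n_boot: int = 1000,
                            seed: int | np.random.Generator = 0,
                            ) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise InsufficientDataError(
            "percentile bootstrap needs at least 2 values")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
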