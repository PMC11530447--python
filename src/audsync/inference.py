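"""Significance assessment for inter-subject correlation.

Two complementary routes:

* a parametric one-sample t-test comparing the distribution of
  per-participant ISCs against zero (one-tailed), with Cohen's d and a
  noncentral-t confidence interval for d;
* a nonparametric circular-shuffle permutation test per participant, in
  which the participant's series is rotated by a random offset and the
  participant ISC recomputed against unshifted partners.  Rotation
  preserves the series' autocorrelation while destroying stimulus
  alignment, so the null respects the autoregressive structure of
  physiological signals.  Decisions across participants are corrected by
  Benjamini-Hochberg FDR.

Also provides Welch's two-sample test and noncentral-t power arithmetic
(solve any one of effect size, sample size, power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from ._sliding import (
    circularly_shifted_matrix,
    pair_mean_over_windows,
    shifted_pair_scalars,
    sliding_pearson,
)
from .isc import WINDOW_S
from .signal import SignalSeries


# --------------------------------------------------------------------------
# circular shuffle


def circular_shift(values: np.ndarray, offset: int) -> np.ndarray:
    """Rotate a series by ``offset`` samples (value multiset preserved)."""
    values = np.asarray(values)
    if len(values) == 0:
        return values.copy()
    return np.roll(values, int(offset) % len(values))


@dataclass
class PermutationResult:
    participant_id: str
    observed_isc: float
    null_iscs: np.ndarray
    p_value: float
    fdr_q: float = 0.05
    significant: bool | None = None

    @property
    def n_iter(self) -> int:
        return len(self.null_iscs)


def _participant_isc_against(
    target: np.ndarray, partners: np.ndarray, window_s: int
) -> float:
    """Median over partners of (mean over windows of Pearson r)."""
    r = sliding_pearson(target, partners, window_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmedian(pair_mean_over_windows(r)))


def participant_permutation_test(
    target: SignalSeries | np.ndarray,
    partners: Sequence[SignalSeries] | np.ndarray,
    n_iter: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    window_s: int = WINDOW_S,
    fdr_q: float = 0.05,
) -> PermutationResult:
    """Circular-shuffle significance of one participant's ISC.

    The target series is rotated ``n_iter`` times by offsets drawn
    uniformly from [window, T - window] (a guard band of one window at each
    end, so shifted and unshifted series never align trivially) and the
    participant ISC recomputed against the unshifted partners each time.
    p = (1 + #{null >= observed}) / (1 + n_iter), never exactly zero.
    """
    if isinstance(target, SignalSeries):
        pid, x = target.participant_id, target.values
    else:
        pid, x = "target", np.asarray(target, dtype=float)
    if isinstance(partners, np.ndarray):
        Y = np.atleast_2d(np.asarray(partners, dtype=float))
    else:
        Y = np.stack([p.values for p in partners])
    T = len(x)
    if Y.shape[1] != T:
        raise ValueError("target and partners must share length")
    if T < 2 * window_s:
        raise ValueError(f"series must be at least twice the window ({2 * window_s} s)")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    rng = np.random.default_rng(rng_seed)

    offsets = rng.integers(window_s, T - window_s + 1, size=n_iter)
    # offset 0 first: observed and null flow through the identical kernel,
    # preserving exchangeability of the test statistic
    XS = circularly_shifted_matrix(x, np.concatenate(([0], offsets)))
    pair_scalars = shifted_pair_scalars(XS, Y, window_s)  # (P, 1 + n_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scalars = np.nanmedian(pair_scalars, axis=0)  # (1 + n_iter,)
    observed, null = float(scalars[0]), scalars[1:]
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_iter)
    return PermutationResult(
        participant_id=pid,
        observed_isc=observed,
        null_iscs=null,
        p_value=float(p),
        fdr_q=fdr_q,
    )


def cohort_permutation_tests(
    series: Sequence[SignalSeries],
    partner_map: dict[str, list[str]] | None = None,
    n_iter: int = 10_000,
    rng_seed: int = 0,
    window_s: int = WINDOW_S,
    fdr_q: float = 0.05,
) -> list[PermutationResult]:
    """Run the permutation test for every participant and apply BH-FDR.

    ``partner_map`` gives each participant id its list of partner ids
    (e.g. the members of the other modality group for the narrative
    design); by default everyone is everyone else's partner.
    """
    by_id = {s.participant_id: s for s in series}
    if partner_map is None:
        partner_map = {
            pid: [q for q in by_id if q != pid] for pid in by_id
        }
    rng = np.random.default_rng(rng_seed)
    results = []
    for pid, partner_ids in partner_map.items():
        res = participant_permutation_test(
            by_id[pid],
            [by_id[q] for q in partner_ids],
            n_iter=n_iter,
            rng_seed=rng.integers(0, 2**31 - 1),
            window_s=window_s,
            fdr_q=fdr_q,
        )
        results.append(res)
    keep = bh_fdr(np.array([r.p_value for r in results]), fdr_q)
    return [replace(r, significant=bool(k)) for r, k in zip(results, keep)]


# --------------------------------------------------------------------------
# multiple testing


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * q
    decisions = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        decisions[order[: k + 1]] = True
    return decisions


# --------------------------------------------------------------------------
# parametric tests


@dataclass
class GroupTestResult:
    mean_r: float
    t: float
    df: float
    p: float
    d: float
    d_ci: tuple[float, float]


def _nct_cdf_safe(t_obs: float, df: float, nc: float) -> float:
    """nct.cdf that degrades gracefully where scipy underflows to NaN."""
    v = stats.nct.cdf(t_obs, df, nc)
    if np.isnan(v):
        return 0.0 if nc > t_obs else 1.0
    return float(v)


def _d_ci_noncentral(t_obs: float, df: float, scale: float, level: float = 0.95):
    """CI for Cohen's d by inverting the noncentral-t cdf in the
    noncentrality parameter; ``scale`` maps noncentrality to d."""
    alpha = 1.0 - level

    def solve(target_cdf: float) -> float:
        # cdf is decreasing in nc; expand the bracket until it straddles
        f = lambda nc: _nct_cdf_safe(t_obs, df, nc) - target_cdf
        lo, hi = t_obs - 2.0, t_obs + 2.0
        while f(lo) < 0:
            lo -= 2.0 * (t_obs - lo)
        while f(hi) > 0:
            hi += 2.0 * (hi - t_obs)
        return brentq(f, lo, hi, xtol=1e-8)

    lo = solve(1.0 - alpha / 2.0)
    hi = solve(alpha / 2.0)
    return (lo * scale, hi * scale)


def group_isc_test(participant_iscs: np.ndarray, tails: int = 1) -> GroupTestResult:
    """One-sample t-test of per-participant ISCs against zero.

    One-tailed by default (synchrony means ISC above zero).  Cohen's
    d = mean/sd with a 95 % noncentral-t confidence interval.
    """
    x = np.asarray(participant_iscs, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 participants")
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return GroupTestResult(0.0, 0.0, n - 1, 0.5 if tails == 1 else 1.0, 0.0, (0.0, 0.0))
        raise ValueError("zero variance with nonzero mean: t undefined")
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    if tails == 1:
        p = float(stats.t.sf(t, df))
    elif tails == 2:
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ValueError("tails must be 1 or 2")
    d = mean / sd
    d_ci = _d_ci_noncentral(t, df, 1.0 / np.sqrt(n))
    return GroupTestResult(mean, float(t), df, p, float(d), d_ci)


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> GroupTestResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    ``mean_r`` carries the mean difference a - b; ``d`` is Cohen's d with
    the pooled standard deviation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    diff = float(np.mean(a) - np.mean(b))
    if se2 == 0.0:
        return GroupTestResult(diff, 0.0, na + nb - 2, 1.0, 0.0, (0.0, 0.0))
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = diff / sp if sp > 0 else 0.0
    scale = np.sqrt(1.0 / na + 1.0 / nb)
    d_ci = _d_ci_noncentral(float(t), df, scale) if sp > 0 else (0.0, 0.0)
    return GroupTestResult(diff, float(t), float(df), p, float(d), d_ci)


# --------------------------------------------------------------------------
# power arithmetic


@dataclass
class PowerSpec:
    """Noncentral-t power problem: exactly one of d, n, power is None.

    ``n`` is the total sample for the one-sample test, the per-group size
    for the two-sample tests.  ``welch_t`` power is evaluated under equal
    variances (where it coincides with the pooled test).
    """

    test: Literal["one_sample_t", "two_sample_t", "welch_t"] = "one_sample_t"
    tails: int = 1
    alpha: float = 0.05
    n: int | None = None
    d: float | None = None
    power: float | None = None


def _nct_sf_safe(t_obs: float, df: float, nc: float) -> float:
    v = stats.nct.sf(t_obs, df, nc)
    if np.isnan(v):
        return 1.0 if nc > t_obs else 0.0
    return float(v)


def _power_from_d(test: str, tails: int, alpha: float, n: int, d: float) -> float:
    if test == "one_sample_t":
        df, nc = n - 1, d * np.sqrt(n)
    else:  # two_sample_t / welch_t, equal n per group
        df, nc = 2 * n - 2, d * np.sqrt(n / 2.0)
    if tails == 1:
        tcrit = stats.t.ppf(1 - alpha, df)
        return _nct_sf_safe(tcrit, df, nc)
    if tails == 2:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return _nct_sf_safe(tcrit, df, nc) + _nct_cdf_safe(-tcrit, df, nc)
    raise ValueError("tails must be 1 or 2")


def power_t(spec: PowerSpec) -> PowerSpec:
    """Complete a power specification by solving for its single unknown.

    Solves the noncentral-t power equation for the missing one of
    {effect size d, sample size n, power}; d and n by bisection.
    """
    unknown = [name for name in ("d", "n", "power") if getattr(spec, name) is None]
    if len(unknown) != 1:
        raise ValueError("exactly one of d, n, power must be None")
    which = unknown[0]
    if which == "power":
        power = _power_from_d(spec.test, spec.tails, spec.alpha, spec.n, spec.d)
        return replace(spec, power=power)
    if spec.power <= spec.alpha:
        raise ValueError("requested power must exceed alpha")
    if which == "d":
        f = lambda d: (
            _power_from_d(spec.test, spec.tails, spec.alpha, spec.n, d) - spec.power
        )
        d = brentq(f, 1e-9, 100.0, xtol=1e-10)
        return replace(spec, d=float(d))
    # minimal integer n reaching the requested power
    n = 3
    while _power_from_d(spec.test, spec.tails, spec.alpha, n, spec.d) < spec.power:
        n += 1
        if n > 10_000_000:
            raise ValueError("no feasible n below 1e7")
    return replace(spec, n=n)
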