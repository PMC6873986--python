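"""Concordance statistics and univariable Cox regression for survival evaluation.

A pair (j, i) is *comparable* when sample i experienced the event and sample
j's observed time is strictly longer — the only orderings knowable under
right-censoring.  Concordance is evaluated over exactly these pairs, scores
interpreted as risk (higher risk should accompany the earlier failure i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .cohort_io import DataError

#: z-scores are capped here; the two-sided normal p underflows well before.
_Z_CAP = 40.0


@dataclass
class ComparablePairList:
    """The pair set E = {(j, i) | event_i = 1, time_j > time_i} of one cohort."""

    j: np.ndarray  # index of the longer survivor
    i: np.ndarray  # index of the earlier event
    n_samples: int

    def __post_init__(self) -> None:
        self.j = np.asarray(self.j, dtype=np.intp)
        self.i = np.asarray(self.i, dtype=np.intp)
        if self.j.shape != self.i.shape:
            raise DataError("pair index arrays must have equal length")

    @property
    def m(self) -> int:
        return int(self.j.shape[0])

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.j.tolist(), self.i.tolist()))


@dataclass
class ConcordanceResult:
    c: float
    n_concordant: int
    n_discordant: int
    n_tied: int
    m: int
    se: float = np.nan
    z: float = np.nan
    p: float = np.nan


@dataclass
class CoxResult:
    beta: float
    se: float
    z: float
    p: float
    converged: bool
    n_iter: int
    loglik: float


def comparable_pairs(times, events) -> ComparablePairList:
    """Enumerate all comparable pairs (strict time inequality; tied times excluded)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape or times.ndim != 1:
        raise DataError("times and events must be equal-length 1-D vectors")
    # mask[j, i] = True when (j, i) is comparable
    mask = (times[:, None] > times[None, :]) & (events[None, :] == 1)
    j, i = np.nonzero(mask)
    return ComparablePairList(j, i, n_samples=times.shape[0])


def _pair_scores(scores: np.ndarray, pairs: ComparablePairList) -> np.ndarray:
    """Per-pair concordance score: 1 concordant, 0 discordant, 0.5 tied risk."""
    si = scores[pairs.i]
    sj = scores[pairs.j]
    return np.where(si > sj, 1.0, np.where(si < sj, 0.0, 0.5))


def concordance_from_pairs(scores, pairs: ComparablePairList) -> ConcordanceResult:
    scores = np.asarray(scores, dtype=float)
    if pairs.m == 0:
        raise DataError("no comparable pairs: concordance index is undefined")
    h = _pair_scores(scores, pairs)
    n_conc = int(np.count_nonzero(h == 1.0))
    n_disc = int(np.count_nonzero(h == 0.0))
    n_tied = pairs.m - n_conc - n_disc
    c = float(h.mean())
    return ConcordanceResult(c, n_conc, n_disc, n_tied, pairs.m)


def concordance_index(scores, times, events) -> ConcordanceResult:
    """Harrell's c-index of ``scores`` (interpreted as risk) against survival."""
    return concordance_from_pairs(scores, comparable_pairs(times, events))


def cindex_ztest_from_pairs(scores, pairs: ComparablePairList) -> ConcordanceResult:
    """c-index with its asymptotic standard error, z = (c - 0.5)/se and
    two-sided p-value.

    The variance estimator is the per-subject influence (Hajek projection)
    form se^2 = sum_i ((v_i - m_i * c) / m)^2, where v_i sums the pair scores
    of all comparable pairs involving subject i and m_i counts them.  In the
    two-sample special case this reduces to the DeLong AUC estimator.
    Degenerate scores (all pairs tied) yield c = 0.5 and z = 0 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    res = concordance_from_pairs(scores, pairs)
    n = pairs.n_samples
    h = _pair_scores(scores, pairs)
    v = np.zeros(n)
    mi = np.zeros(n)
    np.add.at(v, pairs.i, h)
    np.add.at(v, pairs.j, h)
    np.add.at(mi, pairs.i, 1.0)
    np.add.at(mi, pairs.j, 1.0)
    d = (v - mi * res.c) / pairs.m
    # n/(n-1) small-sample factor: makes the projection estimator agree with
    # the delete-one jackknife (exactly so for a sample mean)
    se = float(np.sqrt(np.sum(d * d) * n / (n - 1)))
    res.se = se
    if se == 0.0:
        if res.c == 0.5:  # all pairs tied (e.g. constant scores)
            res.z = 0.0
            res.p = 1.0
        else:
            # estimator degenerates at perfect (anti-)concordance; cap the
            # z-score where the normal tail already underflows
            res.z = _Z_CAP if res.c > 0.5 else -_Z_CAP
            res.p = float(2.0 * norm.sf(_Z_CAP))
    else:
        res.z = float(np.clip((res.c - 0.5) / se, -_Z_CAP, _Z_CAP))
        res.p = float(2.0 * norm.sf(abs(res.z)))
    return res


def cindex_ztest(scores, times, events) -> ConcordanceResult:
    pairs = comparable_pairs(times, events)
    if pairs.m < 2:
        raise DataError("cindex_ztest requires at least 2 comparable pairs")
    return cindex_ztest_from_pairs(scores, pairs)


# ---------------------------------------------------------------------------
# Univariable Cox regression (Breslow ties)
# ---------------------------------------------------------------------------

def _cox_loglik_grad_hess(beta: float, x: np.ndarray, times: np.ndarray,
                          events: np.ndarray) -> tuple[float, float, float]:
    """Breslow partial log-likelihood of a single coefficient with derivatives.

    Samples are assumed sorted by descending time so that the risk set of an
    event at position t is the prefix [0..t] — cumulative sums give the
    risk-set aggregates in O(n).
    """
    eta = beta * x
    eta -= eta.max()  # guard exp overflow; the shift cancels in all terms below
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    # Breslow: tied event times share one risk set including all the ties.
    # With the descending sort, equal times occupy a contiguous block and the
    # shared risk set ends at the block's last index.
    n = times.shape[0]
    block_end = np.empty(n, dtype=np.intp)
    start = 0
    for end in np.concatenate([np.nonzero(np.diff(times) != 0)[0], [n - 1]]):
        block_end[start:end + 1] = end
        start = end + 1
    ev = events == 1
    r = block_end[ev]
    s0r, s1r, s2r = s0[r], s1[r], s2[r]
    ll = float(np.sum(eta[ev] - np.log(s0r)))
    grad = float(np.sum(x[ev] - s1r / s0r))
    hess = float(-np.sum(s2r / s0r - (s1r / s0r) ** 2))
    return ll, grad, hess


def univariable_cox(covariate, times, events, max_iter: int = 50,
                    tol: float = 1e-9) -> CoxResult:
    """Fit a single-covariate Cox model by Newton-Raphson (Breslow ties).

    Returns the Wald z and two-sided p.  A constant covariate carries no
    information: beta = 0, p = 1.  Monotone likelihood (perfect separation)
    is reported as non-convergence.
    """
    x = np.asarray(covariate, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (x.shape == times.shape == events.shape):
        raise DataError("covariate, times and events must be aligned")
    if (events == 1).sum() < 1:
        raise DataError("Cox regression requires at least one event")

    order = np.argsort(-times, kind="stable")
    x_s, t_s, e_s = x[order], times[order], events[order]

    if np.ptp(x) == 0.0:
        ll0 = _cox_loglik_grad_hess(0.0, x_s, t_s, e_s)[0]
        return CoxResult(0.0, np.inf, 0.0, 1.0, True, 0, ll0)

    scale = float(np.std(x))
    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, x_s, t_s, e_s)
        if hess >= 0 or not np.isfinite(hess):
            break
        step = -grad / hess
        # dampen absurd steps (monotone-likelihood escape)
        if abs(step) > 10.0 / scale:
            step = np.sign(step) * 10.0 / scale
        beta += step
        if abs(grad) < tol and abs(step) < 1e-10 / max(scale, 1e-12):
            converged = True
            break
        if abs(grad) < tol:
            converged = True
            break
    ll, grad, hess = _cox_loglik_grad_hess(beta, x_s, t_s, e_s)
    if abs(beta) * scale > 50:  # monotone likelihood: estimate diverging
        converged = False
    if hess < 0:
        se = float(np.sqrt(-1.0 / hess))
        z = beta / se
        p = float(2.0 * norm.sf(abs(z)))
    else:
        se, z, p = np.inf, 0.0, 1.0
        converged = False
    return CoxResult(float(beta), se, float(z), p, converged, it, float(ll))
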