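"""Demographic-expansion statistics on sequence data.

Fu's Fs (via the Ewens sampling formula with log-space Stirling numbers),
the Ramos-Onsins & Rozas R2 statistic, coalescent-resampling p-values
conditioned on the observed number of segregating sites, and mismatch
distributions with a sudden-expansion model fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaincc, gammaln, logsumexp

from invaroute.popstats import as_base_array, _clean_columns

__all__ = [
    "NeutralityResult",
    "MismatchFit",
    "fu_fs",
    "fu_fs_from_counts",
    "ewens_log_pmf",
    "r2_stat",
    "singletons_per_sequence",
    "neutrality_pvalues",
    "neutrality_test",
    "mismatch_observed",
    "expected_mismatch",
    "fit_sudden_expansion",
]


@dataclass(frozen=True)
class NeutralityResult:
    fs: float
    r2: float
    p_fs: float
    p_r2: float
    n: int
    s: int
    theta_pi: float


@dataclass
class MismatchFit:
    observed: np.ndarray
    tau: float
    theta0: float
    theta1: float
    expected: np.ndarray
    ssd: float
    converged: bool = True


# ---------------------------------------------------------------------------
# Fu's Fs

_LOG_STIRLING_ROWS: list[np.ndarray] = [np.array([0.0]), np.array([-np.inf, 0.0])]


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind),
    built by the recurrence |s(n+1,k)| = n |s(n,k)| + |s(n,k-1)| in log
    space to stay finite at large n."""
    while len(_LOG_STIRLING_ROWS) <= n:
        m = len(_LOG_STIRLING_ROWS) - 1  # current max row index
        row = _LOG_STIRLING_ROWS[m]
        new = np.full(m + 2, -np.inf)
        # new[k] = logaddexp(log(m) + |s(m,k)|, |s(m,k-1)|) for k = 1..m+1
        shifted_up = np.concatenate([row[1:], [-np.inf]])
        new[1:] = np.logaddexp(np.log(m) + shifted_up, row)
        _LOG_STIRLING_ROWS.append(new)
    return _LOG_STIRLING_ROWS[n]


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling formula:
    P(K=k) = |s(n,k)| theta^k / prod_{i=0}^{n-1}(theta + i)."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    k = np.arange(n + 1)
    log_norm = np.sum(np.log(theta + np.arange(n)))
    return _log_stirling_row(n) + k * math.log(theta) - log_norm


def fu_fs_from_counts(n: int, theta: float, k_obs: int) -> float:
    """Fu's Fs from sample size, theta-pi and the observed haplotype count.

    S' = P(K >= k_obs | theta, n); Fs = ln(S' / (1 - S')).  Returns +inf
    (degenerate) when k_obs <= 1 and -inf when S' underflows to 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if theta <= 0:
        raise ValueError("theta must be > 0 (monomorphic data are degenerate)")
    logp = ewens_log_pmf(n, theta)
    if k_obs <= 1:
        return math.inf
    log_sp = logsumexp(logp[k_obs:])
    log_one_minus = logsumexp(logp[:k_obs])
    if log_sp == -math.inf:
        return -math.inf
    if log_one_minus == -math.inf:
        return math.inf
    return float(log_sp - log_one_minus)


def _haplotype_count(aln: np.ndarray) -> int:
    return np.unique(aln, axis=0).shape[0]


def _theta_pi(aln: np.ndarray) -> float:
    n = aln.shape[0]
    seg = aln[:, (aln != aln[0]).any(axis=0)]
    if seg.shape[1] == 0:
        return 0.0
    diffs = (seg[:, None, :] != seg[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, 1)
    return float(diffs[iu].mean())


def fu_fs(alignment) -> float:
    """Fu's Fs of an alignment (gap/ambiguity columns excluded)."""
    aln = _clean_columns(as_base_array(alignment))
    n = aln.shape[0]
    theta = _theta_pi(aln)
    if theta == 0:
        raise ValueError("theta_pi is 0: Fs undefined on monomorphic data")
    return fu_fs_from_counts(n, theta, _haplotype_count(aln))


# ---------------------------------------------------------------------------
# R2

def singletons_per_sequence(aln: np.ndarray) -> np.ndarray:
    """U_i: number of singleton variants carried by each sequence.

    A singleton is a base present in exactly one sequence at a polymorphic
    site; that sequence's count is incremented (at n=2 both variants of a
    segregating site are singletons)."""
    n, L = aln.shape
    u = np.zeros(n, dtype=np.int64)
    seg = aln[:, (aln != aln[0]).any(axis=0)]
    for col in seg.T:
        vals, counts = np.unique(col, return_counts=True)
        for v, c in zip(vals, counts):
            if c == 1 and len(vals) > 1:
                u[np.nonzero(col == v)[0][0]] += 1
    return u


def r2_stat(alignment) -> float:
    """Ramos-Onsins & Rozas R2:
    sqrt(mean_i (U_i - pi/2)^2) / S with U_i the per-sequence singleton
    counts and pi the mean pairwise difference."""
    aln = _clean_columns(as_base_array(alignment))
    n = aln.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    seg_count = int(((aln != aln[0]).any(axis=0)).sum())
    if seg_count == 0:
        raise ValueError("no segregating sites: R2 undefined")
    pi = _theta_pi(aln)
    u = singletons_per_sequence(aln)
    return float(np.sqrt(np.mean((u - pi / 2.0) ** 2)) / seg_count)


# ---------------------------------------------------------------------------
# resampling null distribution (constant-size coalescent conditioned on S)


def _kingman_branch_table(n: int, rng: np.random.Generator):
    """Simulate a Kingman genealogy of n tips (unit size); return
    (parent, branch lengths) with parents above children in index order."""
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    ids = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        parent[ids[i]] = nxt
        parent[ids[j]] = nxt
        times[nxt] = t
        ids[i] = nxt
        ids[j] = ids[-1]
        ids.pop()
        nxt += 1
        k -= 1
    lens = np.zeros(2 * n - 1)
    nr = parent >= 0
    lens[nr] = times[parent[nr]] - times[nr]
    return parent, lens


def _null_replicates(
    n: int, s: int, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(Fs, R2) under a constant-size panmictic coalescent with exactly
    ``s`` infinite-sites mutations placed uniformly on the genealogy."""
    fs_vals = np.empty(n_reps)
    r2_vals = np.empty(n_reps)
    for rep in range(n_reps):
        parent, lens = _kingman_branch_table(n, rng)
        branches = rng.choice(len(lens), size=s, p=lens / lens.sum())
        # infinite sites: one column per mutation; tip carries 1 if below branch
        aln = np.zeros((n, s), dtype=np.uint8)
        below = np.zeros((2 * n - 1, s), dtype=bool)
        below[branches, np.arange(s)] = True
        # propagate "carries mutation" down from each branch to tips
        for node in range(2 * n - 2, n - 1, -1):
            child_mask = parent == node
            below[child_mask] |= below[node]
        aln[:, :] = below[:n]
        pi = _theta_pi(aln)
        k_obs = _haplotype_count(aln)
        fs_vals[rep] = (
            fu_fs_from_counts(n, pi, k_obs) if pi > 0 else math.inf
        )
        u = singletons_per_sequence(aln)
        seg = int(((aln != aln[0]).any(axis=0)).sum())
        r2_vals[rep] = (
            np.sqrt(np.mean((u - pi / 2.0) ** 2)) / seg if seg > 0 else np.nan
        )
    return fs_vals, r2_vals


def neutrality_pvalues(
    fs_obs: float,
    r2_obs: float,
    n: int,
    s: int,
    n_reps: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """One-sided resampling p-values: the fraction of constant-size
    coalescent replicates (conditioned on n and S) with Fs (resp. R2) at or
    below the observed value — small values of both signal expansion."""
    if n_reps < 100:
        raise ValueError("need n_reps >= 100")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fs_null, r2_null = _null_replicates(n, s, n_reps, rng)
    p_fs = float(np.mean(fs_null <= fs_obs))
    p_r2 = float(np.mean(r2_null[~np.isnan(r2_null)] <= r2_obs))
    return p_fs, p_r2


def neutrality_test(
    alignment, n_reps: int = 1000, rng_seed: int | np.random.Generator = 0
) -> NeutralityResult:
    """Fu's Fs and R2 with resampling p-values for one alignment."""
    aln = _clean_columns(as_base_array(alignment))
    n = aln.shape[0]
    s = int(((aln != aln[0]).any(axis=0)).sum())
    pi = _theta_pi(aln)
    fs = fu_fs_from_counts(n, pi, _haplotype_count(aln)) if pi > 0 else math.inf
    r2 = r2_stat(aln) if s > 0 else math.nan
    p_fs, p_r2 = neutrality_pvalues(fs, r2, n, s, n_reps, rng_seed)
    return NeutralityResult(fs, r2, p_fs, p_r2, n, s, pi)


# ---------------------------------------------------------------------------
# mismatch distribution


def mismatch_observed(alignment) -> np.ndarray:
    """Normalised frequency spectrum of pairwise difference counts
    (support 0..max observed difference)."""
    aln = _clean_columns(as_base_array(alignment))
    n = aln.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    seg = aln[:, (aln != aln[0]).any(axis=0)]
    diffs = (seg[:, None, :] != seg[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, 1)
    counts = np.bincount(diffs[iu])
    return counts / counts.sum()


def _log_gammaincc(a: np.ndarray, x: float) -> np.ndarray:
    """log of the regularised upper incomplete gamma Q(a, x), with an
    asymptotic fallback where Q underflows (x >> a)."""
    a = np.asarray(a, dtype=float)
    q = gammaincc(a, x)
    out = np.full_like(a, -np.inf)
    ok = q > 1e-290
    out[ok] = np.log(q[ok])
    bad = ~ok
    if np.any(bad) and x > 0:
        # Q(a,x) ~ x^(a-1) e^-x / Gamma(a) * sum_m prod_{i<m}(a-1-i)/x^m
        ab = a[bad]
        series = np.ones_like(ab)
        term = np.ones_like(ab)
        for m in range(1, 12):
            term = term * (ab - m) / x
            series += term
        series = np.maximum(series, 1e-300)
        out[bad] = (ab - 1) * math.log(x) - x - gammaln(ab) + np.log(series)
    return out


def expected_mismatch(
    tau: float, theta0: float, theta1: float, jmax: int, renormalize: bool = True
) -> np.ndarray:
    """Expected pairwise-difference spectrum F_j under the sudden-expansion
    model: current (mutational-time) scaled size theta1 for the last tau
    units, theta0 before.

    F_j = int P(coalesce at s) Pois_j(s) ds with hazard 1/theta1 on [0, tau)
    and 1/theta0 beyond; at tau = 0 it reduces to the equilibrium geometric
    form theta0^j / (1 + theta0)^(j+1).
    """
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise ValueError("need tau >= 0, theta0 >= 0, theta1 > 0")
    j = np.arange(jmax + 1, dtype=float)
    a1 = 1.0 + 1.0 / theta1
    if tau == 0:
        th = max(theta0, 1e-12)
        f = np.exp(j * math.log(th) - (j + 1) * math.log1p(th))
    else:
        # recent epoch: (1/theta1) * a1^-(j+1) * P(j+1, a1 tau)
        term1 = (
            np.exp(-math.log(theta1) - (j + 1) * math.log(a1))
            * gammainc(j + 1, a1 * tau)
        )
        # ancient epoch
        th0 = theta0
        if th0 < 1e-9:
            # coalescence effectively at tau: Poisson(tau) differences
            log_t2 = -tau / theta1 - tau + j * math.log(max(tau, 1e-300)) - gammaln(
                j + 1
            )
            term2 = np.exp(log_t2)
        else:
            a0 = 1.0 + 1.0 / th0
            log_t2 = (
                -tau / theta1
                + tau / th0
                - math.log(th0)
                - (j + 1) * math.log(a0)
                + _log_gammaincc(j + 1, a0 * tau)
            )
            term2 = np.exp(log_t2)
        f = term1 + term2
    if renormalize:
        total = f.sum()
        if total > 0:
            f = f / total
    return f


def fit_sudden_expansion(
    observed: np.ndarray,
    tau_max: float = 50.0,
    theta0_max: float | None = None,
    theta1_max: float | None = None,
) -> MismatchFit:
    """Least-squares fit of the sudden-expansion spectrum to an observed
    mismatch distribution (grid search then bounded local refinement)."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed spectrum must be a 1-d histogram")
    obs = obs / obs.sum()
    jmax = obs.size - 1
    mean_pi = float(np.sum(np.arange(obs.size) * obs))
    if theta0_max is None:
        theta0_max = max(mean_pi, 0.5)
    if theta1_max is None:
        theta1_max = 10.0 * mean_pi + 10.0

    def ssd(params: np.ndarray) -> float:
        tau, th0, dth = params
        if tau < 0 or th0 < 0 or dth < 0:
            return 1e6 + float(np.sum(np.minimum(params, 0) ** 2))
        exp_spec = expected_mismatch(tau, th0, th0 + dth + 1e-9, jmax)
        return float(np.sum((obs - exp_spec) ** 2))

    starts = []
    for tau in np.linspace(0.0, min(tau_max, 3.0 * mean_pi + 5.0), 8):
        for th0 in np.linspace(0.0, theta0_max, 5):
            for dth in np.geomspace(0.1, theta1_max, 6):
                p = np.array([tau, th0, dth])
                starts.append((ssd(p), p))
    starts.sort(key=lambda t: t[0])
    bounds = [(0.0, tau_max), (0.0, theta0_max), (1e-6, theta1_max)]
    best_val, best_p = starts[0]
    converged = False
    for _, p0 in starts[:4]:
        res = minimize(ssd, p0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_val:
            best_val, best_p, converged = float(res.fun), res.x, bool(res.success)
    polish = minimize(
        ssd, best_p, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
    )
    px = np.clip(polish.x, [b[0] for b in bounds], [b[1] for b in bounds])
    if ssd(px) <= best_val:
        best_val, best_p = float(ssd(px)), px
        converged = converged or bool(polish.success)
    tau, th0, dth = best_p
    th1 = th0 + dth + 1e-9
    return MismatchFit(
        observed=obs,
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th1),
        expected=expected_mismatch(tau, th0, th1, jmax),
        ssd=best_val,
        converged=converged,
    )
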