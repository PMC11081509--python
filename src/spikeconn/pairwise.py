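"""Cross-correlogram machinery and the five pairwise inference algorithms.

Each algorithm emits an :class:`~spikeconn.spike_trains.InferenceResult`
with a score graph ``S`` (detection confidence for ``i -> j``) and a weight
graph ``W`` (signed coupling-strength estimate). Default parameters follow
the published defaults of the source methods and are exposed in every
result's ``params`` record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spike_trains import (SpikeTrainSet, InferenceResult, bin_spikes,
                           jitter_surrogate, clip_scores)

__all__ = [
    "Ccg", "SynWindow", "SurrogateNull", "GlmccFit",
    "compute_ccg", "hollow_gaussian_baseline",
    "infer_ci", "infer_sccg", "infer_dsttc", "infer_glmcc", "infer_te",
    "fit_glmcc_ccg",
]

_EPS = 1e-12


@dataclass
class SynWindow:
    """Putative monosynaptic lag interval (lo, hi], in ms."""

    lo_ms: float = 0.5
    hi_ms: float = 5.0

    def __post_init__(self):
        if not 0 <= self.lo_ms < self.hi_ms:
            raise ValueError("need 0 <= lo < hi")


@dataclass
class SurrogateNull:
    """Summary of a jitter-surrogate null distribution for one statistic.

    ``mu_surr``/``sd_surr`` are per-ordered-pair matrices of the surrogate
    mean and SD; ``samples`` optionally keeps the raw per-surrogate values
    (n_surrogates x N x N).
    """

    n_surrogates: int
    mu_surr: np.ndarray
    sd_surr: np.ndarray
    samples: np.ndarray | None = None

    def __post_init__(self):
        if self.n_surrogates < 2:
            raise ValueError("n_surrogates must be >= 2")
        if np.any(np.asarray(self.sd_surr) < 0):
            raise ValueError("sd_surr must be non-negative")


@dataclass
class Ccg:
    """Cross-correlogram of an ordered pair (i pre, j post).

    ``counts[k]`` is the number of spike pairs with lag
    ``t_j - t_i`` in ``[lags_ms[k] - D/2, lags_ms[k] + D/2)``.
    """

    lags_ms: np.ndarray
    counts: np.ndarray
    bin_width_ms: float
    n_pre: int
    n_post: int


def _pair_lags(a: np.ndarray, b: np.ndarray, max_lag_s: float) -> np.ndarray:
    """All lags b - a within +/- max_lag_s, fully vectorized."""
    if a.size == 0 or b.size == 0:
        return np.empty(0)
    lo = np.searchsorted(b, a - max_lag_s, side="left")
    hi = np.searchsorted(b, a + max_lag_s, side="right")
    c = hi - lo
    total = int(c.sum())
    if total == 0:
        return np.empty(0)
    spike_id = np.repeat(np.arange(a.size), c)
    offs = np.concatenate([[0], np.cumsum(c)[:-1]])
    pos = np.arange(total) - np.repeat(offs, c) + np.repeat(lo, c)
    return b[pos] - a[spike_id]


def _count_in_window(a: np.ndarray, b: np.ndarray, lo_s: float,
                     hi_s: float) -> int:
    """Number of (a, b) spike pairs with b - a in (lo_s, hi_s]."""
    if a.size == 0 or b.size == 0:
        return 0
    return int((np.searchsorted(b, a + hi_s, side="right")
                - np.searchsorted(b, a + lo_s, side="right")).sum())


def _has_in_window(a: np.ndarray, b: np.ndarray, lo_s: float,
                   hi_s: float) -> int:
    """Number of a-spikes with at least one b-spike in (lo_s, hi_s]."""
    if a.size == 0 or b.size == 0:
        return 0
    return int((np.searchsorted(b, a + hi_s, side="right")
                > np.searchsorted(b, a + lo_s, side="right")).sum())


def compute_ccg(sts: SpikeTrainSet, i, j, t_max_ms: float = 50.0,
                bin_width_ms: float = 1.0) -> Ccg:
    """Cross-correlogram between units i (presynaptic) and j (postsynaptic).

    For ``i == j`` the zero-lag self pairs are excluded.
    """
    ia, ib = sts.unit_index(i), sts.unit_index(j)
    a, b = sts.spikes[ia], sts.spikes[ib]
    n_half = int(round(t_max_ms / bin_width_ms))
    lags_ms = (np.arange(-n_half, n_half + 1)) * bin_width_ms
    edges = (np.arange(-n_half, n_half + 2) - 0.5) * bin_width_ms / 1000.0
    if a.size == 0 or b.size == 0:
        warnings.warn("empty spike train; all-zero CCG")
        return Ccg(lags_ms, np.zeros(lags_ms.size, dtype=np.int64),
                   bin_width_ms, a.size, b.size)
    d = _pair_lags(a, b, (t_max_ms + bin_width_ms) / 1000.0)
    if ia == ib:
        d = d[d != 0.0]
    counts, _ = np.histogram(d, bins=edges)
    return Ccg(lags_ms, counts.astype(np.int64), bin_width_ms,
               a.size, b.size)


def hollow_gaussian_baseline(ccg: Ccg, sigma_ms: float = 10.0,
                             hollow_fraction: float = 0.6) -> np.ndarray:
    """Slow-background estimate of a CCG via a partially hollow Gaussian.

    The counts are convolved with a unit-mass Gaussian whose central weight
    is scaled by ``1 - hollow_fraction`` (and the kernel renormalized), so
    that a fast synaptic feature at the centre bin does not inflate its own
    baseline. Edges are handled by renormalizing the kernel over its valid
    support.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be > 0")
    if not 0 <= hollow_fraction <= 1:
        raise ValueError("hollow_fraction must be in [0, 1]")
    half = int(np.ceil(5 * sigma_ms / ccg.bin_width_ms))
    x = np.arange(-half, half + 1) * ccg.bin_width_ms
    g = np.exp(-0.5 * (x / sigma_ms) ** 2)
    g /= g.sum()
    g[half] *= (1.0 - hollow_fraction)
    g /= g.sum()
    num = np.convolve(ccg.counts.astype(float), g, mode="same")
    den = np.convolve(np.ones(ccg.counts.size), g, mode="same")
    return num / den


def _window_bins(ccg_lags_ms: np.ndarray, window: SynWindow) -> np.ndarray:
    """Indices of CCG bins whose centre lies in (lo, hi]."""
    return np.flatnonzero((ccg_lags_ms > window.lo_ms)
                          & (ccg_lags_ms <= window.hi_ms))


def _coincidence_matrix(sts: SpikeTrainSet, lo_s: float,
                        hi_s: float) -> np.ndarray:
    """N x N matrix of windowed coincidence counts over ordered pairs."""
    n = sts.n_units
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out[i, j] = _count_in_window(sts.spikes[i], sts.spikes[j],
                                         lo_s, hi_s)
    return out


def infer_ci(sts: SpikeTrainSet, window: SynWindow | None = None,
             jitter_ms: float = 10.0, n_surrogates: int = 50,
             seed: int = 0) -> InferenceResult:
    """Coincidence index: windowed CCG integral vs jittered surrogates.

    Per ordered pair the observed number of coincidences ``N_c`` in the
    synaptic window is z-scored against the distribution obtained from
    ``n_surrogates`` jittered copies of the full recording; the score is
    ``|z|`` and the weight is the signed excess coincidence count per
    presynaptic spike.
    """
    if sts.n_units < 2:
        raise ValueError("need at least 2 units")
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    window = window or SynWindow()
    lo_s, hi_s = window.lo_ms / 1000.0, window.hi_ms / 1000.0
    obs = _coincidence_matrix(sts, lo_s, hi_s)
    surr = np.empty((n_surrogates,) + obs.shape)
    for k in range(n_surrogates):
        js = jitter_surrogate(sts, jitter_ms, seed=seed * 100003 + k)
        surr[k] = _coincidence_matrix(js, lo_s, hi_s)
    mu = surr.mean(axis=0)
    sd = surr.std(axis=0)
    z = (obs - mu) / np.maximum(sd, _EPS)
    n_pre = np.maximum(sts.spike_counts(), 1)[:, None]
    W = (obs - mu) / n_pre
    params = dict(window=(window.lo_ms, window.hi_ms), jitter_ms=jitter_ms,
                  n_surrogates=n_surrogates, seed=seed)
    res = InferenceResult("CI", clip_scores(np.abs(z)), W,
                          list(sts.unit_ids), params)
    res.surrogate_null = SurrogateNull(n_surrogates, mu, sd)
    return res


def infer_sccg(sts: SpikeTrainSet, window: SynWindow | None = None,
               sigma_ms: float = 10.0, hollow_fraction: float = 0.6,
               t_max_ms: float = 50.0,
               bin_width_ms: float = 1.0) -> InferenceResult:
    """Smoothed cross-correlogram with a partially hollow Gaussian baseline.

    The windowed CCG sum ``C_w`` is compared to the baseline expectation
    ``Lambda_w`` under a Poisson model; the score is
    ``-log10 min(p_excess, p_deficit)`` and the weight the signed excess per
    presynaptic spike (a spike-transmission estimate).
    """
    window = window or SynWindow()
    if window.hi_ms > t_max_ms:
        raise ValueError("window outside CCG span")
    n = sts.n_units
    S = np.full((n, n), np.nan)
    W = np.full((n, n), np.nan)
    counts = sts.spike_counts()
    for i in range(n):
        for j in range(i + 1, n):
            ccg = compute_ccg(sts, sts.unit_ids[i], sts.unit_ids[j],
                              t_max_ms, bin_width_ms)
            lam = hollow_gaussian_baseline(ccg, sigma_ms, hollow_fraction)
            for (a, b, sign) in ((i, j, 1), (j, i, -1)):
                wb = _window_bins(sign * ccg.lags_ms, window)
                C_w = float(ccg.counts[wb].sum())
                L_w = float(lam[wb].sum())
                p_plus = stats.poisson.sf(C_w - 1, L_w)  # P(X >= C_w)
                p_minus = stats.poisson.cdf(C_w, L_w)
                S[a, b] = -np.log10(max(min(p_plus, p_minus), 1e-300))
                W[a, b] = (C_w - L_w) / max(1, counts[a])
    params = dict(window=(window.lo_ms, window.hi_ms), sigma_ms=sigma_ms,
                  hollow_fraction=hollow_fraction, t_max_ms=t_max_ms,
                  bin_width_ms=bin_width_ms)
    return InferenceResult("sCCG", clip_scores(S), W, list(sts.unit_ids),
                           params)


# ---------------------------------------------------------------------------
# directed spike-time tiling coefficient
# ---------------------------------------------------------------------------

def _coverage(t: np.ndarray, dt_s: float, duration_s: float,
              direction: int) -> float:
    """Fraction of the recording covered by (0, dt] windows after each
    spike (direction=+1) or [-dt, 0) windows before each spike (-1)."""
    if t.size == 0:
        return 0.0
    if direction > 0:
        starts, ends = t, np.minimum(t + dt_s, duration_s)
    else:
        starts, ends = np.maximum(t - dt_s, 0.0), t
    total = ends[0] - starts[0]
    for k in range(1, t.size):
        s = max(starts[k], ends[k - 1])
        total += max(0.0, ends[k] - s)
    return total / duration_s


def infer_dsttc(sts: SpikeTrainSet, dt_ms: float = 5.0,
                jitter_ms: float = 10.0, n_surrogates: int = 50,
                seed: int = 0) -> InferenceResult:
    """Directed spike-time tiling coefficient with a jitter-surrogate score.

    Rate-robust coincidence measure: excess of j-spikes in the (0, dt]
    window after i-spikes and of i-spikes in the [-dt, 0) window before
    j-spikes, each corrected by the fraction of time tiled by such windows.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    dt_s = dt_ms / 1000.0
    n = sts.n_units

    def matrix(s: SpikeTrainSet) -> np.ndarray:
        cov_p = [_coverage(t, dt_s, s.duration_s, +1) for t in s.spikes]
        cov_m = [_coverage(t, dt_s, s.duration_s, -1) for t in s.spikes]
        out = np.zeros((n, n))
        for i in range(n):
            a = s.spikes[i]
            for j in range(n):
                if i == j:
                    continue
                b = s.spikes[j]
                if a.size == 0 or b.size == 0:
                    continue
                p_plus = _has_in_window(a, b, 0.0, dt_s) / a.size
                p_minus = _has_in_window(b, a, -dt_s, 0.0) / b.size
                val = 0.0
                for p, t in ((p_plus, cov_p[j]), (p_minus, cov_m[i])):
                    den = 1.0 - p * t
                    val += 1.0 if den == 0.0 else (p - t) / den
                out[i, j] = 0.5 * val
        return out

    obs = matrix(sts)
    surr = np.empty((n_surrogates, n, n))
    for k in range(n_surrogates):
        surr[k] = matrix(jitter_surrogate(sts, jitter_ms,
                                          seed=seed * 100019 + k))
    mu, sd = surr.mean(axis=0), surr.std(axis=0)
    z = (obs - mu) / np.maximum(sd, _EPS)
    params = dict(dt_ms=dt_ms, jitter_ms=jitter_ms,
                  n_surrogates=n_surrogates, seed=seed)
    res = InferenceResult("dSTTC", clip_scores(np.abs(z)), obs,
                          list(sts.unit_ids), params)
    res.surrogate_null = SurrogateNull(n_surrogates, mu, sd)
    return res


# ---------------------------------------------------------------------------
# GLM on the cross-correlogram (GLMCC)
# ---------------------------------------------------------------------------

@dataclass
class GlmccFit:
    """Fitted CCG decomposition: smooth background a(tau) plus synaptic
    kernels J_fwd * f(tau) and J_bwd * f(-tau)."""

    J_fwd: float
    J_bwd: float
    a: np.ndarray
    delay_ms: float
    tau_syn_ms: float
    se_fwd: float
    se_bwd: float
    converged: bool


def fit_glmcc_ccg(counts: np.ndarray, lags_ms: np.ndarray,
                  bin_width_ms: float, delay_ms: float = 1.0,
                  tau_syn_ms: float = 4.0, smooth_penalty: float = 20.0,
                  ridge: float = 1e-4, max_iter: int = 100,
                  tol: float = 1e-6) -> GlmccFit:
    """Penalized Poisson ML fit of the GLMCC model to one CCG.

    Model: ``counts_k ~ Poisson(exp(a_k + J_fwd f(tau_k) + J_bwd f(-tau_k)))``
    with ``f(tau) = exp(-(tau - d)/tau_syn)`` for ``tau >= d`` and a
    quadratic first-difference penalty on the background ``a``.
    """
    y = counts.astype(float)
    m = y.size
    f_fwd = np.where(lags_ms >= delay_ms,
                     np.exp(-(lags_ms - delay_ms) / tau_syn_ms), 0.0)
    f_bwd = f_fwd[::-1].copy()
    # difference operator penalty
    D = np.diff(np.eye(m), axis=0)
    P = smooth_penalty * (D.T @ D)
    a = np.log(np.maximum(y, 0.5))
    # light smoothing of the init stabilises early Newton steps
    kern = np.ones(5) / 5.0
    a = np.convolve(a, kern, mode="same")
    theta = np.concatenate([a, [0.0, 0.0]])

    def unpack(th):
        return th[:m], th[m], th[m + 1]

    def nll(th):
        a_, jf, jb = unpack(th)
        eta = a_ + jf * f_fwd + jb * f_bwd
        lam = np.exp(np.minimum(eta, 30.0))
        return (lam - y * eta).sum() + 0.5 * a_ @ P @ a_ \
            + 0.5 * ridge * (jf ** 2 + jb ** 2)

    converged = False
    cur = nll(theta)
    for _ in range(max_iter):
        a_, jf, jb = unpack(theta)
        eta = a_ + jf * f_fwd + jb * f_bwd
        lam = np.exp(np.minimum(eta, 30.0))
        resid = lam - y
        grad = np.concatenate([
            resid + P @ a_,
            [resid @ f_fwd + ridge * jf, resid @ f_bwd + ridge * jb]])
        H = np.zeros((m + 2, m + 2))
        H[:m, :m] = np.diag(lam) + P
        H[:m, m] = H[m, :m] = lam * f_fwd
        H[:m, m + 1] = H[m + 1, :m] = lam * f_bwd
        H[m, m] = lam @ f_fwd ** 2 + ridge
        H[m + 1, m + 1] = lam @ f_bwd ** 2 + ridge
        H[m, m + 1] = H[m + 1, m] = lam @ (f_fwd * f_bwd)
        if np.linalg.norm(grad) < tol * max(1.0, abs(cur)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # backtracking line search
        t_step = 1.0
        for _ in range(20):
            new = theta - t_step * step
            v = nll(new)
            if v <= cur + 1e-12:
                theta, cur = new, v
                break
            t_step *= 0.5
        else:
            break
    a_, jf, jb = unpack(theta)
    eta = a_ + jf * f_fwd + jb * f_bwd
    lam = np.exp(np.minimum(eta, 30.0))
    H = np.zeros((m + 2, m + 2))
    H[:m, :m] = np.diag(lam) + P
    H[:m, m] = H[m, :m] = lam * f_fwd
    H[:m, m + 1] = H[m + 1, :m] = lam * f_bwd
    H[m, m] = lam @ f_fwd ** 2 + ridge
    H[m + 1, m + 1] = lam @ f_bwd ** 2 + ridge
    H[m, m + 1] = H[m + 1, m] = lam @ (f_fwd * f_bwd)
    try:
        cov = np.linalg.inv(H)
        se_f = float(np.sqrt(max(cov[m, m], _EPS)))
        se_b = float(np.sqrt(max(cov[m + 1, m + 1], _EPS)))
    except np.linalg.LinAlgError:
        se_f = se_b = float("nan")
        converged = False
    return GlmccFit(float(jf), float(jb), a_, delay_ms, tau_syn_ms,
                    se_f, se_b, converged)


def infer_glmcc(sts: SpikeTrainSet, t_max_ms: float = 50.0,
                bin_width_ms: float = 1.0, delay_ms: float = 1.0,
                tau_syn_ms: float = 4.0, smooth_penalty: float = 20.0,
                ridge: float = 1e-4,
                min_pairs: int = 50) -> InferenceResult:
    """GLM fit to the CCG of every unordered pair.

    One optimization per unordered pair populates both directed entries:
    score ``|J|/se`` (Wald) and weight ``J``. Pairs whose pooled CCG holds
    fewer than ``min_pairs`` spike pairs are skipped with s = w = 0.
    """
    n = sts.n_units
    S = np.full((n, n), np.nan)
    W = np.full((n, n), np.nan)
    skipped = []
    for i in range(n):
        for j in range(i + 1, n):
            ccg = compute_ccg(sts, sts.unit_ids[i], sts.unit_ids[j],
                              t_max_ms, bin_width_ms)
            if ccg.counts.sum() < min_pairs:
                S[i, j] = S[j, i] = 0.0
                W[i, j] = W[j, i] = 0.0
                skipped.append((sts.unit_ids[i], sts.unit_ids[j]))
                continue
            fit = fit_glmcc_ccg(ccg.counts, ccg.lags_ms, bin_width_ms,
                                delay_ms, tau_syn_ms, smooth_penalty, ridge)
            if not fit.converged or not np.isfinite(fit.se_fwd):
                S[i, j] = S[j, i] = 0.0
                W[i, j] = W[j, i] = 0.0
                skipped.append((sts.unit_ids[i], sts.unit_ids[j]))
                continue
            S[i, j] = abs(fit.J_fwd) / max(fit.se_fwd, _EPS)
            W[i, j] = fit.J_fwd
            S[j, i] = abs(fit.J_bwd) / max(fit.se_bwd, _EPS)
            W[j, i] = fit.J_bwd
    params = dict(t_max_ms=t_max_ms, bin_width_ms=bin_width_ms,
                  delay_ms=delay_ms, tau_syn_ms=tau_syn_ms,
                  smooth_penalty=smooth_penalty, n_skipped=len(skipped))
    return InferenceResult("GLMCC", clip_scores(S), W, list(sts.unit_ids),
                           params)


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def _te_bits(c111, c110, c101, c100, c011, c010, c001, c000) -> float:
    """Plug-in TE from the 2x2x2 (y, h, s) contingency counts."""
    cells = np.maximum(np.array([c000, c001, c010, c011,
                                 c100, c101, c110, c111], dtype=float), 0.0)
    total = cells.sum()
    if total <= 0:
        return 0.0
    p = cells / total
    # indices: bit2 = y, bit1 = h, bit0 = s
    te = 0.0
    for y in (0, 1):
        for h in (0, 1):
            for s in (0, 1):
                pj = p[4 * y + 2 * h + s]
                if pj <= 0:
                    continue
                p_hs = p[2 * h + s] + p[4 + 2 * h + s]
                p_h = p[2 * h] + p[2 * h + 1] + p[4 + 2 * h] + p[4 + 2 * h + 1]
                p_yh = p[4 * y + 2 * h] + p[4 * y + 2 * h + 1]
                te += pj * np.log2((pj / p_hs) / (p_yh / p_h))
    return max(te, 0.0)


def _te_pair_all_delays(bins_i: np.ndarray, bins_j: np.ndarray,
                        n_bins: int, delays: np.ndarray) -> np.ndarray:
    """Delayed TE(i -> j) in bits for every delay, history of one bin.

    Works on the sparse sets of occupied (binary) bins: all contingency
    counts reduce to difference histograms between the two index sets.
    """
    d_max = int(delays.max())
    # valid prediction times: t in [d_max, n_bins)
    t0 = d_max
    n_t = n_bins - t0
    if n_t <= 0:
        return np.zeros(delays.size)
    Y = bins_j[bins_j >= t0]
    H = bins_j + 1
    H = H[(H >= t0) & (H < n_bins)]
    A = bins_j[np.flatnonzero(np.diff(bins_j) == 1) + 1]  # y=1 & h=1 times
    A = A[A >= t0]
    n_y = Y.size
    n_h = H.size
    n_a = A.size

    def lag_counts(tgt: np.ndarray) -> np.ndarray:
        """counts[d] = #{(t in tgt, t - d in bins_i)} for d in delays."""
        if tgt.size == 0 or bins_i.size == 0:
            return np.zeros(delays.size)
        diffs = _pair_lags(bins_i.astype(float), tgt.astype(float),
                           d_max + 1.5)
        diffs = diffs[(diffs >= delays.min() - 0.5)]
        hist, _ = np.histogram(diffs, bins=np.arange(delays.min() - 0.5,
                                                     d_max + 1.5))
        return hist.astype(float)

    # source-active count among valid times, per delay: s(t)=x_i(t-d)=1
    lo = np.searchsorted(bins_i, t0 - delays)
    hi = np.searchsorted(bins_i, n_bins - delays)
    n_s = (hi - lo).astype(float)

    cYS = lag_counts(Y)
    cHS = lag_counts(H)
    cAS = lag_counts(A)
    out = np.zeros(delays.size)
    for k, d in enumerate(delays):
        c_ys = cYS[k]
        c_hs = cHS[k]
        c_as = cAS[k]
        c111 = c_as
        c110 = n_a - c_as
        c101 = c_ys - c_as
        c100 = n_y - n_a - c101
        c011 = c_hs - c_as
        c010 = n_h - n_a - c011
        c001 = n_s[k] - c_ys - c011
        c000 = n_t - n_y - n_h + n_a - c001
        out[k] = _te_bits(c111, c110, c101, c100, c011, c010, c001, c000)
    return out


def infer_te(sts: SpikeTrainSet, bin_width_ms: float = 1.0,
             delay_range_ms=(1, 20), history_bins: int = 1,
             jitter_ms: float = 10.0, n_surrogates: int = 50,
             seed: int = 0, window: SynWindow | None = None,
             sigma_ms: float = 10.0,
             hollow_fraction: float = 0.6) -> InferenceResult:
    """Delayed transfer entropy on binarized spike trains.

    ``TE(i -> j)`` is the plug-in transfer entropy (bits) maximized over the
    source delay; the score is the TE z-scored against jittered surrogates
    and the weight is TE signed by the CCG windowed excess/deficit (so that
    inhibition carries a negative weight).
    """
    if history_bins != 1:
        raise NotImplementedError("only history_bins=1 is supported")
    bm = bin_spikes(sts, bin_width_ms)
    if bm.n_bins < 1000:
        raise ValueError("fewer than 1000 bins: insufficient data for TE")
    d_lo = max(1, int(round(delay_range_ms[0] / bin_width_ms)))
    d_hi = max(d_lo, int(round(delay_range_ms[1] / bin_width_ms)))
    delays = np.arange(d_lo, d_hi + 1)
    n = sts.n_units

    def te_matrix(s: SpikeTrainSet) -> np.ndarray:
        b = bin_spikes(s, bin_width_ms)
        occupied = [np.flatnonzero(b.counts[k] > 0) for k in range(n)]
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                te = _te_pair_all_delays(occupied[i], occupied[j],
                                         b.n_bins, delays)
                out[i, j] = te.max()
        return out

    obs = te_matrix(sts)
    surr = np.empty((n_surrogates, n, n))
    for k in range(n_surrogates):
        surr[k] = te_matrix(jitter_surrogate(sts, jitter_ms,
                                             seed=seed * 100043 + k))
    mu_surr, sd_surr = surr.mean(axis=0), surr.std(axis=0)
    z = (obs - mu_surr) / np.maximum(sd_surr, _EPS)

    # sign from the sCCG window statistic (excess vs hollow-Gaussian baseline)
    window = window or SynWindow()
    sign = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ccg = compute_ccg(sts, sts.unit_ids[i], sts.unit_ids[j],
                              50.0, 1.0)
            lam = hollow_gaussian_baseline(ccg, sigma_ms, hollow_fraction)
            for (a, b, sgn) in ((i, j, 1), (j, i, -1)):
                wb = _window_bins(sgn * ccg.lags_ms, window)
                sign[a, b] = 1.0 if (ccg.counts[wb].sum()
                                     >= lam[wb].sum()) else -1.0
    W = obs * sign
    params = dict(bin_width_ms=bin_width_ms, delay_range_ms=tuple(delay_range_ms),
                  history_bins=history_bins, jitter_ms=jitter_ms,
                  n_surrogates=n_surrogates, seed=seed)
    res = InferenceResult("TE", clip_scores(z), W, list(sts.unit_ids),
                          params)
    res.surrogate_null = SurrogateNull(n_surrogates, mu_surr, sd_surr)
    return res
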