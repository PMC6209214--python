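"""Burst-suppression probability (BSP) estimation.

The global binary signal is reduced to per-epoch counts ``n_t`` of suppressed
samples out of ``N_t`` valid samples, and a state-space model is fit:

    x_t = x_{t-1} + v_t,        v_t ~ N(0, sigma_v^2)       (logit-scale random walk)
    n_t ~ Binomial(N_t, p_t),   p_t = logistic(x_t)

BSP_t = p_t is the instantaneous probability that the EEG is suppressed. The
forward pass is a Gaussian-approximation filter (posterior mode by Newton's
method, variance from the curvature at the mode); a fixed-interval
Rauch–Tung–Striebel pass gives the smoothed trajectory, whose variance never
exceeds the filtered variance. Missing epochs (N_t = 0) propagate the
prediction unchanged, so gaps widen — never shrink — the credible band.

At steady state BSP agrees with the classical windowed burst-suppression ratio
(BSR); BSP is preferred for dynamic data and yields a well-defined probability
with credible bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .segmentation import BinarySuppressionSignal

#: Lower bound for the process-noise variance (keeps EM and filtering well-posed).
SIGMA_V2_FLOOR = 1e-8

#: Default process-noise variance on the logit scale per 1-s epoch. Chosen so the
#: smoother averages the fast renewal alternation of bursts and suppressions
#: (seconds) while still settling within ~2–3 min of a true level change; see
#: docs/methods.md for the bias–variance argument.
DEFAULT_SIGMA_V2 = 2e-6


@dataclass
class EpochCounts:
    """Suppressed-sample counts per epoch; N_t = 0 marks a missing observation."""

    n: np.ndarray
    N: np.ndarray
    epoch_len: float = 1.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.N = np.asarray(self.N, dtype=np.int64)
        if self.n.shape != self.N.shape:
            raise ValueError("n and N must have equal length")
        if np.any(self.n < 0) or np.any(self.n > self.N):
            raise ValueError("need 0 <= n_t <= N_t")

    def __len__(self) -> int:
        return len(self.n)

    @property
    def valid(self) -> np.ndarray:
        return self.N > 0


@dataclass
class BSPTrajectory:
    """Posterior summary of the latent suppression probability per epoch.

    ``x`` and ``var`` are the posterior mode and variance on the logit scale;
    ``bsp`` = logistic(x); the 95% credible bounds are logistic(x ± 1.96·sd),
    hence always within [0, 1] and ordered.
    """

    x: np.ndarray
    var: np.ndarray
    sigma_v2: float
    epoch_len: float = 1.0
    counts: EpochCounts | None = None
    kind: str = "filtered"

    @property
    def bsp(self) -> np.ndarray:
        return expit(self.x)

    @property
    def ci_lo(self) -> np.ndarray:
        return expit(self.x - 1.96 * np.sqrt(self.var))

    @property
    def ci_hi(self) -> np.ndarray:
        return expit(self.x + 1.96 * np.sqrt(self.var))

    @property
    def times(self) -> np.ndarray:
        """Epoch start times in seconds."""
        return np.arange(len(self.x)) * self.epoch_len

    def __len__(self) -> int:
        return len(self.x)


def epoch_counts(signal: BinarySuppressionSignal, epoch_len: float = 1.0) -> EpochCounts:
    """Aggregate the global binary signal into per-epoch suppressed/valid counts.

    Samples in epochs masked invalid contribute to neither n_t nor N_t, so a
    fully masked epoch has N_t = 0.
    """
    if epoch_len <= 0:
        raise ValueError("epoch length must be positive")
    nsamp = signal.n_samples
    spe = int(round(signal.fs * epoch_len))
    ne = int(np.ceil(nsamp / spe)) if nsamp else 0
    ok = signal.mask.sample_mask(nsamp, signal.fs)
    vals = np.zeros(ne * spe, dtype=np.int64)
    valid = np.zeros(ne * spe, dtype=np.int64)
    vals[:nsamp] = signal.values * ok
    valid[:nsamp] = ok
    return EpochCounts(
        vals.reshape(ne, spe).sum(axis=1), valid.reshape(ne, spe).sum(axis=1), epoch_len
    )


def _newton_update(x0: float, v_pred: float, n: int, N: int, epoch: int) -> tuple[float, float]:
    """Posterior mode and variance for one binomial observation.

    Newton's method on the strictly concave one-step log-posterior, safeguarded
    by a bracket on its (strictly decreasing) gradient: on the flat logistic
    tails a raw Newton step can enter a two-cycle, so steps leaving the bracket
    fall back to bisection.
    """

    def grad(x: float) -> float:
        return -(x - x0) / v_pred + n - N * expit(x)

    # the mode lies between the prior mean and the observation's logit
    x_obs = float(logit((n + 0.5) / (N + 1)))
    lo, hi = min(x0, x_obs) - 1.0, max(x0, x_obs) + 1.0
    while grad(lo) < 0:
        lo -= 2.0
    while grad(hi) > 0:
        hi += 2.0
    x = x0
    for _ in range(50):
        p = expit(x)
        g = -(x - x0) / v_pred + n - N * p
        h = -1.0 / v_pred - N * p * (1.0 - p)
        step = g / h
        x_new = x - step
        # on the flat logistic tails Newton can leap back and forth across the
        # mode without settling; force a bisection whenever the step leaves the
        # bracket or fails to shrink it, which guarantees geometric convergence
        if not (lo < x_new < hi) or abs(step) > 0.5 * (hi - lo):
            x_new = 0.5 * (lo + hi)
            step = x_new - x
        if grad(x_new) > 0:
            lo = x_new
        else:
            hi = x_new
        x = x_new
        if abs(step) < 1e-8:
            p = expit(x)
            return x, v_pred / (1.0 + v_pred * N * p * (1.0 - p))
    raise RuntimeError(f"Newton iteration failed to converge at epoch {epoch}")


def default_x0(counts: EpochCounts) -> float:
    """Logit of the first valid epoch's suppressed fraction, clipped to [0.01, 0.99]."""
    valid = np.flatnonzero(counts.valid)
    if valid.size == 0:
        return 0.0
    k = valid[0]
    rate = counts.n[k] / counts.N[k]
    return float(logit(np.clip(rate, 0.01, 0.99)))


def bsp_filter(
    counts: EpochCounts,
    sigma_v2: float = DEFAULT_SIGMA_V2,
    x0: float | None = None,
    var0: float = 1.0,
) -> BSPTrajectory:
    """Forward (filtered) pass of the binomial state-space model.

    Each epoch first predicts (x, var + sigma_v2) from the previous posterior,
    then — if the epoch is observed — moves to the mode of the one-step
    log-posterior by Newton's method, with variance from the negative inverse
    Hessian. Missing epochs keep the prediction, so the variance grows by
    sigma_v2 per missing epoch.
    """
    if sigma_v2 < SIGMA_V2_FLOOR:
        raise ValueError(f"sigma_v2 must be >= {SIGMA_V2_FLOOR}")
    if x0 is None:
        x0 = default_x0(counts)
    T = len(counts)
    xs = np.empty(T)
    vs = np.empty(T)
    x, v = float(x0), float(var0)
    for t in range(T):
        v_pred = v + sigma_v2
        if counts.N[t] == 0:
            x, v = x, v_pred
        else:
            x, v = _newton_update(x, v_pred, int(counts.n[t]), int(counts.N[t]), t)
        xs[t] = x
        vs[t] = v
    return BSPTrajectory(xs, vs, sigma_v2, counts.epoch_len, counts, kind="filtered")


def bsp_smoother(filtered: BSPTrajectory) -> BSPTrajectory:
    """Fixed-interval (RTS) smoother over the filtered trajectory.

    For the random-walk state model the smoother gain is
    A_t = var_t / (var_t + sigma_v2); the smoothed variance is never larger than
    the filtered variance, and the final epoch is the filtered estimate itself.
    """
    if filtered.kind != "filtered":
        raise ValueError("bsp_smoother expects a filtered trajectory")
    T = len(filtered)
    xs = filtered.x.copy()
    vs = filtered.var.copy()
    q = filtered.sigma_v2
    for t in range(T - 2, -1, -1):
        v_pred = filtered.var[t] + q
        a = filtered.var[t] / v_pred
        xs[t] = filtered.x[t] + a * (xs[t + 1] - filtered.x[t])
        vs[t] = filtered.var[t] + a * a * (vs[t + 1] - v_pred)
    return BSPTrajectory(xs, vs, q, filtered.epoch_len, filtered.counts, kind="smoothed")


def estimate_bsp(
    counts: EpochCounts,
    sigma_v2: float = DEFAULT_SIGMA_V2,
    x0: float | None = None,
    var0: float = 1.0,
    use_em: bool = False,
) -> BSPTrajectory:
    """Convenience: (optionally EM-tune sigma_v2, then) filter and smooth."""
    if use_em:
        sigma_v2 = estimate_sigma_v2(counts, sigma0=sigma_v2)
    return bsp_smoother(bsp_filter(counts, sigma_v2, x0=x0, var0=var0))


def estimate_sigma_v2(
    counts: EpochCounts,
    sigma0: float = 0.005,
    max_iter: int = 200,
    tol: float = 1e-3,
) -> float:
    """EM estimate of the process-noise variance sigma_v2.

    E-step: Gaussian-approximation filter + RTS smoother at the current value;
    the lag-one smoothed covariance is A_t · var^s_{t+1}. M-step: sigma_v2 is the
    mean expected squared state increment. Iterates until the relative change
    falls below ``tol``; the result never falls below the 1e-8 floor. Requires at
    least 100 valid epochs — below that the likelihood carries too little
    information and callers should use the configured default instead.
    """
    if int(counts.valid.sum()) < 100:
        raise ValueError("EM requires at least 100 valid epochs; use the configured default")
    q = max(float(sigma0), SIGMA_V2_FLOOR)
    for _ in range(max_iter):
        filt = bsp_filter(counts, q)
        smo = bsp_smoother(filt)
        v_pred = filt.var[:-1] + q
        a = filt.var[:-1] / v_pred
        lag1 = a * smo.var[1:]
        inc = np.diff(smo.x)
        q_new = float(np.mean(inc**2 + smo.var[1:] + smo.var[:-1] - 2 * lag1))
        q_new = max(q_new, SIGMA_V2_FLOOR)
        if abs(q_new - q) / q <= tol:
            return q_new
        q = q_new
    return q


def windowed_bsr(
    signal: BinarySuppressionSignal, window: float = 60.0, epoch_len: float = 1.0
) -> np.ndarray:
    """Classical burst-suppression ratio: suppressed fraction of valid samples
    in a centered window, evaluated at each epoch midpoint. NaN where the window
    contains no valid sample."""
    if window <= 0:
        raise ValueError("window must be positive")
    nsamp = signal.n_samples
    fs = signal.fs
    ok = signal.mask.sample_mask(nsamp, fs)
    sup = np.concatenate(([0], np.cumsum(signal.values * ok)))
    val = np.concatenate(([0], np.cumsum(ok)))
    ne = int(np.ceil(nsamp / (fs * epoch_len)))
    centers = (np.arange(ne) + 0.5) * epoch_len * fs
    lo = np.clip((centers - window * fs / 2).astype(int), 0, nsamp)
    hi = np.clip((centers + window * fs / 2).astype(int), 0, nsamp)
    nval = val[hi] - val[lo]
    with np.errstate(invalid="ignore"):
        out = (sup[hi] - sup[lo]) / nval
    out[nval == 0] = np.nan
    return out
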