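"""Model-based Bayesian decoding of a fluctuating stimulus from spike trains.

Given spike trains s_j produced by cells with SRM parameters theta_j driven
by currents i_j = sigma_j * eta + mu_j, the normalized stimulus eta is
reconstructed as the maximum a posteriori estimate

    eta_MAP = argmax_eta  sum_j log P(s_j | eta; theta_j) + log P(eta)

under the Gaussian OU prior log P(eta) = -1/2 eta' Sigma^-1 eta, whose
precision is the tridiagonal AR(1) matrix

    Sigma^-1[ij] = 1/(1-beta^2) * { 1          i=j=1 or i=j=N
                                    1+beta^2   i=j interior
                                    -beta      |i-j|=1 },   beta = exp(-dt/tau).

The log-posterior is concave in eta; its Hessian is banded because the
membrane filter k has finite support, so Newton ascent, the Laplace
covariance C = (-Hessian)^-1 at the mode, its diagonal (per-time
uncertainty) and its log-determinant are all computed with banded Cholesky
factorizations. Mutual information between stimulus and spike trains is the
Gaussian prior entropy minus the average Laplace posterior entropy,

    I = H(eta) - <H(eta | s)> = (1/2) ( <log|C^-1|> - log|Sigma^-1| ),

reported in bits. Entropies are kept in natural logs internally.

Decoding may run on a coarser grid than the simulation (1 ms by default in
the experiment helpers): spikes are re-binned, kernels resampled and the
stimulus decimated, which leaves the OU prior exact (a subsampled OU process
is again AR(1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .banded import (banded_logdet, banded_solve, banded_inverse_diagonal)
from .srm import SRMParams, spike_bins, EXP_CLIP, simulate
from .stimulus import StimulusTrace, ScalingSpec, OUSpec, sample_ou
from .metrics import SpikeTrain

LN2 = np.log(2.0)


@dataclass(frozen=True)
class PriorSpec:
    """OU prior on the decode grid: tau (ms), dt (ms), length n."""

    tau: float
    dt: float
    n: int

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0 or self.n < 2:
            raise ValueError("invalid prior specification")

    @property
    def beta(self) -> float:
        return float(np.exp(-self.dt / self.tau))


def prior_precision(spec: PriorSpec) -> np.ndarray:
    """Tridiagonal AR(1) precision in upper banded form (2, n)."""
    beta = spec.beta
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie in (0, 1)")
    n = spec.n
    denom = 1.0 - beta * beta
    ab = np.zeros((2, n))
    ab[1, :] = (1.0 + beta * beta) / denom
    ab[1, 0] = ab[1, -1] = 1.0 / denom
    ab[0, 1:] = -beta / denom
    return ab


@dataclass
class EncoderEntry:
    """One cell in the decoding bank: its SRM, its current scaling, and the
    spike trains it contributed (one per trial)."""

    cell_id: str
    params: SRMParams
    scaling: ScalingSpec
    trains: list


@dataclass(frozen=True)
class DecodeConfig:
    tol: float = 1e-6
    max_iter: int = 100


@dataclass
class DecodeResult:
    eta_map: np.ndarray
    sd: np.ndarray
    logdet_post: float        # log |C| of the Laplace posterior covariance
    info_bits: float          # prior entropy minus posterior entropy, bits
    r2: float | None
    n_newton_iters: int
    dt: float


class _CellLikelihood:
    """Precomputed per-cell quantities for the banded posterior.

    For each trial of the cell, the log-intensity is
    z(t) = base(t) + (a * eta)(t) with a = (sigma/dv) * k on the decode grid
    and base the spike-history and bias terms, which are fixed given the
    spikes being decoded.
    """

    def __init__(self, entry: EncoderEntry, n: int, dt: float):
        p = entry.params
        sigma = entry.scaling.sigma
        mu = entry.scaling.mu
        k = p.k_kernel(dt)
        self.a = (sigma / p.delta_v) * k
        self.B = self.a.size
        # onset transient of the mean-current term, matching the causal
        # truncation of the convolution
        ksum = np.convolve(np.ones(n), k)[:n]
        hv_k = p.hv_kernel(dt)
        hth_k = p.hth_kernel(dt)
        self.counts = []
        self.bases = []
        for tr in entry.trains:
            times = np.asarray(getattr(tr, "times", tr), dtype=float)
            c = spike_bins(times, dt, n).astype(float)
            hv = _hist(hv_k, c)
            hth = _hist(hth_k, c)
            base = (p.v_b + mu * ksum + hv - p.v_th - hth) / p.delta_v
            self.counts.append(c)
            self.bases.append(base)
        self.n = n
        self.dt = dt
        # FFT of the reversed off-diagonal product kernels, for the banded
        # Gauss-Newton/Hessian build
        self._nfft = int(2 ** np.ceil(np.log2(n + self.B)))
        G = np.zeros((self.B, self.B))
        for d in range(self.B):
            g = self.a[: self.B - d] * self.a[d:]
            G[d, : self.B - d] = g[::-1]
        self._G_fft = np.fft.rfft(G, self._nfft, axis=1)

    def conv(self, eta: np.ndarray) -> np.ndarray:
        return np.convolve(eta, self.a)[: self.n]

    def corr(self, r: np.ndarray) -> np.ndarray:
        """Adjoint of conv: out[i] = sum_u a[u] r[i+u]."""
        full = np.convolve(r, self.a[::-1])
        return full[self.B - 1: self.B - 1 + self.n]

    def loglik_terms(self, eta: np.ndarray):
        """(log-likelihood, gradient, intensity weight sum) over trials."""
        Aeta = self.conv(eta)
        ll = 0.0
        grad = np.zeros(self.n)
        wsum = np.zeros(self.n)
        for c, base in zip(self.counts, self.bases):
            z = np.minimum(base + Aeta, EXP_CLIP)
            lam_dt = np.exp(z) * self.dt
            ll += float(c @ z - lam_dt.sum())
            grad += self.corr(c - lam_dt)
            wsum += lam_dt
        return ll, grad, wsum

    def hessian_band(self, wsum: np.ndarray) -> np.ndarray:
        """Negative likelihood Hessian K' diag(w) K in upper banded form
        ((B), n): row (B-1-d) holds M_d[i] = H[i, i+d] at column i+d."""
        W_fft = np.fft.rfft(wsum, self._nfft)
        M = np.fft.irfft(self._G_fft * W_fft, self._nfft, axis=1)
        out = np.zeros((self.B, self.n))
        col = M[:, self.B - 1: self.B - 1 + self.n]
        for d in range(self.B):
            out[self.B - 1 - d, d:] = col[d, : self.n - d]
        return out


def _hist(kernel: np.ndarray, counts: np.ndarray) -> np.ndarray:
    ker = kernel.copy()
    if ker.size:
        ker[0] = 0.0
    return np.convolve(counts, ker)[: counts.size]


def map_decode(bank: list, prior: PriorSpec,
               cfg: DecodeConfig = DecodeConfig(),
               eta_true: np.ndarray | None = None) -> DecodeResult:
    """MAP reconstruction with Laplace uncertainty.

    ``bank`` is a list of :class:`EncoderEntry`. An empty bank returns the
    prior mean (zeros) with the prior marginal uncertainty. Raises on
    Newton non-convergence, with the iterate trajectory in the message.
    """
    n, dt = prior.n, prior.dt
    P = prior_precision(prior)
    logdet_P = banded_logdet(P)
    cells = [_CellLikelihood(entry, n, dt) for entry in bank]
    bw = max([c.B for c in cells], default=1)
    bw = max(bw, 2)  # at least the prior's tridiagonal band

    def objective(eta):
        ll = -0.5 * float(eta @ _apply_prior(P, eta))
        grad = -_apply_prior(P, eta)
        wsums = []
        for c in cells:
            l, g, w = c.loglik_terms(eta)
            ll += l
            grad += g
            wsums.append(w)
        return ll, grad, wsums

    def hessian(wsums):
        ab = np.zeros((bw, n))
        ab[-1] += P[1]
        ab[-2, 1:] += P[0, 1:]
        for c, w in zip(cells, wsums):
            hb = c.hessian_band(w)
            ab[bw - c.B:] += hb
        return ab

    eta = np.zeros(n)
    val, grad, wsums = objective(eta)
    trajectory = [(val, float(np.abs(grad).max()))]
    n_iter = 0
    while np.abs(grad).max() >= cfg.tol:
        if n_iter >= cfg.max_iter:
            raise RuntimeError(
                f"MAP Newton did not converge in {cfg.max_iter} iterations; "
                f"trajectory tail: {trajectory[-5:]}")
        ab = hessian(wsums)
        step = banded_solve(ab, grad)
        scale = 1.0
        for _ in range(60):
            cand = eta + scale * step
            cval, cgrad, cwsums = objective(cand)
            if cval >= val - 1e-12:
                break
            scale *= 0.5
        eta, val, grad, wsums = cand, cval, cgrad, cwsums
        trajectory.append((val, float(np.abs(grad).max())))
        n_iter += 1

    ab = hessian(wsums)  # posterior precision C^-1 at the mode
    logdet_Cinv = banded_logdet(ab)
    var = banded_inverse_diagonal(ab)
    info_bits = 0.5 * (logdet_Cinv - logdet_P) / LN2
    r2 = None if eta_true is None else r_squared(eta_true, eta)
    return DecodeResult(eta_map=eta, sd=np.sqrt(var),
                        logdet_post=-logdet_Cinv, info_bits=info_bits,
                        r2=r2, n_newton_iters=n_iter, dt=dt)


def _apply_prior(P: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Tridiagonal matrix-vector product in upper banded form."""
    out = P[1] * eta
    out[:-1] += P[0, 1:] * eta[1:]
    out[1:] += P[0, 1:] * eta[:-1]
    return out


def r_squared(eta_true: np.ndarray, eta_map: np.ndarray) -> float:
    """Coefficient of determination 1 - MSE/Var; negative for poor fits."""
    eta_true = np.asarray(eta_true, dtype=float)
    eta_map = np.asarray(eta_map, dtype=float)
    if eta_true.size != eta_map.size:
        raise ValueError("length mismatch")
    var = np.var(eta_true)
    if var == 0:
        raise ValueError("zero-variance stimulus")
    return float(1.0 - np.mean((eta_true - eta_map) ** 2) / var)


def mutual_information(decodes: list, prior: PriorSpec | None = None) -> float:
    """Mutual information in bits: prior entropy minus the Monte-Carlo
    average of the Laplace posterior entropies across decodes.

    Each decode already stores its entropy difference, so the estimate is
    the mean of the per-decode information values (all decodes must share
    one prior).
    """
    if not decodes:
        return 0.0
    return float(np.mean([d.info_bits for d in decodes]))


def equalize_trials(rate_hz: float, duration_s: float, n_target_spikes: float) -> int:
    """Trials needed for ~n target spikes: round(n / (rate * T)), floor 1."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    return max(1, int(round(n_target_spikes / (rate_hz * duration_s))))


def spike_triggered_uncertainty(result: DecodeResult, spikes,
                                window_ms: tuple = (-150.0, 50.0)):
    """Posterior sd averaged in windows aligned to each spike (lag 0 = spike).

    Returns (lags_ms, mean_sd, min_sd, lag_at_min). Windows clipped by the
    trace edges are averaged over the available spikes only.
    """
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    if times.size == 0:
        raise ValueError("no spikes to align to")
    dt = result.dt
    lo = int(round(window_ms[0] / dt))
    hi = int(round(window_ms[1] / dt))
    lags = np.arange(lo, hi + 1)
    acc = np.zeros(lags.size)
    cnt = np.zeros(lags.size)
    n = result.sd.size
    idx0 = np.floor(times / dt + 1e-9).astype(int)
    for i0 in idx0:
        pos = i0 + lags
        ok = (pos >= 0) & (pos < n)
        acc[ok] += result.sd[pos[ok]]
        cnt[ok] += 1
    mean_sd = acc / np.maximum(cnt, 1)
    j = int(np.argmin(mean_sd))
    return lags * dt, mean_sd, float(mean_sd[j]), float(lags[j] * dt)


# --------------------------------------------------------------------------
# experiment helpers

def simulate_bank(cells: list, eta: StimulusTrace, trials: dict,
                  seed_seq: np.random.SeedSequence,
                  stimulus_per_cell: dict | None = None) -> list:
    """Simulate spike trains for each (cell_id, params, scaling) and wrap
    them as encoder entries.

    ``trials`` maps cell_id to the trial count; ``stimulus_per_cell``
    optionally overrides the normalized stimulus each cell sees (used for
    noise-corrupted encoding), while the decoder always models the clean
    stimulus.
    """
    entries = []
    children = seed_seq.spawn(len(cells))
    for (cid, params, scaling), child in zip(cells, children):
        eta_cell = eta if stimulus_per_cell is None else stimulus_per_cell[cid]
        current = StimulusTrace(scaling.sigma * eta_cell.values + scaling.mu,
                                eta_cell.dt, "pA")
        rng = np.random.default_rng(child)
        trains = [simulate(params, current, rng=rng).spikes
                  for _ in range(trials[cid])]
        entries.append(EncoderEntry(cid, params, scaling, trains))
    return entries


def decimate_stimulus(eta: StimulusTrace, decode_dt: float) -> np.ndarray:
    """Pointwise decimation onto the decode grid (OU stays AR(1))."""
    ratio = int(round(decode_dt / eta.dt))
    if abs(ratio * eta.dt - decode_dt) > 1e-9:
        raise ValueError("decode dt must be an integer multiple of the stimulus dt")
    return eta.values[::ratio]


def decode_experiment(cells: list, n_stimuli: int, duration_ms: float,
                      tau: float = 3.0, sim_dt: float = 0.1,
                      decode_dt: float = 1.0, trials_per_cell: int = 1,
                      seed: int = 0, cfg: DecodeConfig = DecodeConfig()):
    """Single-cell decoding survey: each cell decodes ``n_stimuli`` fresh
    OU stimuli on its own; returns a pandas DataFrame with per-cell firing
    rate, mean r-squared and information, and their residuals after
    removing the pooled linear dependence on firing rate.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    rows = []
    for rep in range(n_stimuli):
        rep_ss, bank_ss = np.random.SeedSequence((seed, rep)).spawn(2)
        eta = sample_ou(OUSpec(tau=tau, dt=sim_dt, duration=duration_ms),
                        rng=np.random.default_rng(rep_ss))
        eta_dec = decimate_stimulus(eta, decode_dt)
        prior = PriorSpec(tau=tau, dt=decode_dt, n=eta_dec.size)
        entries = simulate_bank(cells, eta, {c[0]: trials_per_cell for c in cells},
                                bank_ss)
        for entry in entries:
            res = map_decode([entry], prior, cfg, eta_true=eta_dec)
            nspk = sum(tr.n for tr in entry.trains)
            rows.append({"cell_id": entry.cell_id, "rep": rep,
                         "rate_hz": 1000.0 * nspk / (duration_ms * trials_per_cell),
                         "r2": res.r2, "info_bits": res.info_bits})
    df = pd.DataFrame(rows)
    per_cell = df.groupby("cell_id", sort=False).agg(
        rate_hz=("rate_hz", "mean"), r2=("r2", "mean"),
        info_bits=("info_bits", "mean")).reset_index()
    for col in ("r2", "info_bits"):
        slope, intercept = np.polyfit(per_cell["rate_hz"], per_cell[col], 1)
        per_cell[f"{col}_residual"] = per_cell[col] - (
            slope * per_cell["rate_hz"] + intercept)
    return per_cell
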