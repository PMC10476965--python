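"""Spike-train statistics: coincidences, reliability, Md similarity, PSTH,
stimulus-response cross-correlation, shuffle controls, passive-property
fits and spike detection.

A coincidence between two trains is the co-occurrence of two spikes within
a rectangular window of width Delta (8 ms by default, comparable to an
action-potential duration). The coincidence count c(s, s') is the number of
spike pairs with |t_a - t_b| <= Delta/2; a spike exactly Delta/2 away
counts (closed window). With this kernel c(s, s) = n(s) whenever the train
has no two spikes within the window.

For two sets of M trains each, the coincidence ratio is

    C(S, S') = (1/M^2) sum_{i,j} c(s_i, s'_j) / ((N(S) + N(S'))/2)

with N the mean spike count per train. The within-set reliability is

    R(S) = (1/(M(M-1))) sum_{i != j} c(s_i, s_j) / N(S)

and the Md similarity normalizes the cross-set coincidences by the sets'
internal reliabilities:

    Md(S, S') = (1/M^2) sum_{i,j} c(s_i, s'_j) / ((N(S)R(S) + N(S')R(S'))/2).

Both reliability and Md are bounded by 1 up to a small excess when a spike
has multiple partners inside one window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

DEFAULT_WINDOW_MS = 8.0


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) over a duration T (ms)."""

    times: np.ndarray
    duration: float

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float).ravel())
        if self.times.size and (self.times[0] < 0 or self.times[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def rate_hz(self) -> float:
        return 1000.0 * self.n / self.duration

    def shifted(self, offset_ms: float) -> "SpikeTrain":
        times = (self.times + offset_ms) % self.duration
        return SpikeTrain(times, self.duration)


@dataclass
class TrialSet:
    """A set of spike trains elicited by one stimulus."""

    trains: list
    stimulus_id: str = ""

    def __post_init__(self):
        if len(self.trains) < 1:
            raise ValueError("at least one train required")
        T = self.trains[0].duration
        if any(abs(tr.duration - T) > 1e-9 for tr in self.trains):
            raise ValueError("all trains must share one duration")

    @property
    def m(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        return self.trains[0].duration

    @property
    def mean_count(self) -> float:
        """N(S): mean spike count per train."""
        return float(np.mean([tr.n for tr in self.trains]))


@dataclass(frozen=True)
class CoincidenceSpec:
    """Rectangular coincidence window Delta (ms)."""

    window: float = DEFAULT_WINDOW_MS

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")


def count_coincidences(a: SpikeTrain, b: SpikeTrain,
                       spec: CoincidenceSpec = CoincidenceSpec()) -> int:
    """Number of spike pairs (t_a, t_b) with |t_a - t_b| <= Delta/2.

    Symmetric in its arguments for the rectangular kernel.
    """
    if abs(a.duration - b.duration) > 1e-9:
        raise ValueError("spike trains must share one duration")
    half = spec.window / 2.0
    lo = np.searchsorted(b.times, a.times - half, side="left")
    hi = np.searchsorted(b.times, a.times + half, side="right")
    return int(np.sum(hi - lo))


def _cross_sum(A: TrialSet, B: TrialSet, spec: CoincidenceSpec,
               exclude_diagonal: bool = False) -> float:
    total = 0
    for i, ta in enumerate(A.trains):
        for j, tb in enumerate(B.trains):
            if exclude_diagonal and i == j:
                continue
            total += count_coincidences(ta, tb, spec)
    return float(total)


def coincidence_ratio(A: TrialSet, B: TrialSet,
                      spec: CoincidenceSpec = CoincidenceSpec()) -> float:
    """Cross-set coincidence ratio C(S, S')."""
    if A.m != B.m:
        raise ValueError("trial sets must have equal trial counts")
    denom = (A.mean_count + B.mean_count) / 2.0
    if denom == 0:
        raise ValueError("coincidence ratio undefined: both sets have no spikes")
    return _cross_sum(A, B, spec) / (A.m * B.m) / denom


def reliability(A: TrialSet, spec: CoincidenceSpec = CoincidenceSpec()) -> float:
    """Within-set reliability R(S) over M >= 2 trials (diagonal excluded)."""
    if A.m < 2:
        raise ValueError("reliability requires at least two trials")
    if A.mean_count == 0:
        raise ValueError("reliability undefined: no spikes")
    s = _cross_sum(A, A, spec, exclude_diagonal=True)
    return s / (A.m * (A.m - 1)) / A.mean_count


def md_similarity(A: TrialSet, B: TrialSet,
                  spec: CoincidenceSpec = CoincidenceSpec()) -> float:
    """Md: cross-set coincidences normalized by the sets' reliabilities."""
    ra, rb = reliability(A, spec), reliability(B, spec)
    denom = (A.mean_count * ra + B.mean_count * rb) / 2.0
    if denom == 0:
        raise ValueError("Md undefined: zero within-set coincidences")
    if A.m != B.m:
        raise ValueError("trial sets must have equal trial counts")
    return _cross_sum(A, B, spec) / (A.m * B.m) / denom


def psth(A: TrialSet, window_ms: float = 40.0, dt: float = 0.1) -> np.ndarray:
    """Boxcar-smoothed trial-averaged firing rate (spikes/s).

    Each spike contributes a rectangular bump renormalized to unit mass
    where the window is clipped by the trace edges, so the integral of the
    PSTH over time times the trial count equals the total spike count
    exactly.
    """
    if window_ms < dt:
        raise ValueError("window must be at least one time bin")
    n = int(round(A.duration / dt))
    w = max(1, int(round(window_ms / dt)))
    counts = np.zeros(n)
    for tr in A.trains:
        idx = np.floor(tr.times / dt).astype(int)
        np.add.at(counts, idx, 1.0)
    coverage = np.convolve(np.ones(n), np.ones(w), mode="same")
    smoothed = np.convolve(counts / coverage, np.ones(w), mode="same")
    return smoothed * 1000.0 / (A.m * dt)


def stim_psth_xcorr(stim, rate: np.ndarray, dt: float | None = None,
                    max_lag_ms: float = 200.0):
    """Pearson correlation between stimulus and PSTH at integer-lag shifts.

    Positive lag means the response lags the stimulus. Correlations are
    computed on mean-subtracted overlapping segments. Returns
    (lags_ms, correlations, peak_lag_ms, peak_value).
    """
    x = np.asarray(getattr(stim, "values", stim), dtype=float)
    if dt is None:
        dt = getattr(stim, "dt", None)
        if dt is None:
            raise ValueError("dt required when stimulus is a bare array")
    y = np.asarray(rate, dtype=float)
    if x.size != y.size:
        raise ValueError("stimulus and PSTH must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    max_lag = int(round(max_lag_ms / dt))
    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.empty(lags.size)
    for idx, k in enumerate(lags):
        if k >= 0:
            xa, ya = x[: x.size - k], y[k:]
        else:
            xa, ya = x[-k:], y[: y.size + k]
        xa = xa - xa.mean()
        ya = ya - ya.mean()
        denom = np.sqrt(np.dot(xa, xa) * np.dot(ya, ya))
        corrs[idx] = np.dot(xa, ya) / denom if denom > 0 else 0.0
    peak = int(np.argmax(corrs))
    return lags * dt, corrs, float(lags[peak] * dt), float(corrs[peak])


def shuffle_times(A: TrialSet, seed: int | None = None) -> TrialSet:
    """Spike-time shuffle control: per-trial counts preserved, times
    redrawn uniformly on [0, T)."""
    rng = np.random.default_rng(seed)
    trains = [SpikeTrain(rng.uniform(0.0, tr.duration, size=tr.n), tr.duration)
              for tr in A.trains]
    return TrialSet(trains, stimulus_id=A.stimulus_id)


def poisson_chance_reliability(rate_hz: float, window_ms: float = DEFAULT_WINDOW_MS) -> float:
    """Expected reliability of independent Poisson trains: lambda * Delta."""
    return rate_hz * 1e-3 * window_ms


@dataclass
class PassiveFit:
    """Passive membrane properties from a hyperpolarizing current step."""

    r_in: float     # MOhm
    tau_m: float    # ms
    fit_rmse: float  # mV

    def __post_init__(self):
        if self.r_in <= 0 or self.tau_m <= 0:
            raise ValueError("r_in and tau_m must be positive")


def fit_passive(voltage: np.ndarray, dt: float, step_pa: float,
                onset_ms: float, fit_window_ms: float = 200.0) -> PassiveFit:
    """Passive properties from the exponential relaxation after a current step.

    Fits v(t) = v0 + dV*(1 - exp(-t/tau_m)) to the deviation following the
    step onset; the input resistance is dV / I in MOhm (mV / pA * 1000).
    """
    if step_pa == 0:
        raise ValueError("current step amplitude must be non-zero")
    v = np.asarray(voltage, dtype=float)
    i0 = int(round(onset_ms / dt))
    i1 = min(v.size, i0 + int(round(fit_window_ms / dt)))
    if i1 - i0 < 10:
        raise ValueError("not enough samples after step onset")
    t = (np.arange(i1 - i0)) * dt
    seg = v[i0:i1]
    v0 = v[max(0, i0 - int(5 / dt)):i0].mean() if i0 > 0 else seg[0]

    def model(t, dv, tau):
        return v0 + dv * (1.0 - np.exp(-t / tau))

    dv0 = seg[-1] - v0
    try:
        popt, _ = optimize.curve_fit(model, t, seg, p0=[dv0 if dv0 else -1.0, 20.0],
                                     maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"passive fit did not converge: {err}") from err
    dv, tau = popt
    rmse = float(np.sqrt(np.mean((model(t, *popt) - seg) ** 2)))
    r_in = abs(dv / step_pa) * 1000.0  # mV/pA -> MOhm
    return PassiveFit(r_in=r_in, tau_m=abs(tau), fit_rmse=rmse)


def detect_spikes(voltage: np.ndarray, dt: float, threshold_mv: float = 0.0,
                  refractory_ms: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings, one spike per refractory window."""
    v = np.asarray(voltage, dtype=float)
    above = v >= threshold_mv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    keep = []
    last = -np.inf
    refr = refractory_ms / dt
    for c in crossings:
        if c - last >= refr:
            keep.append(c)
            last = c
    return SpikeTrain(np.asarray(keep, dtype=float) * dt, duration=v.size * dt)
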