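"""Fluctuating current stimuli.

Two stimulus families are supported: an Ornstein-Uhlenbeck (OU) process with
exponential autocorrelation (the workhorse "frozen noise" injected in the
experiments, correlation time tau = 3 ms by default) and a theta-modulated
Gaussian process defined by the autocovariance

    rho(u) = sigma^2 * cos(2*pi*f*u) * exp(-u/tau)

sampled by Cholesky factorization of the dense covariance matrix.

Normalized stimuli eta(t) have zero mean and unit stationary variance; they
are converted to injectable currents i(t) = sigma*eta(t) + mu (pA) with
:func:`scale`. Correlated stimulus pairs for the pattern-separation task and
variance-preserving noise corruption are also generated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal, linalg

#: Acquisition/simulation time step (ms); 10 kHz sampling.
DEFAULT_DT_MS = 0.1

#: Default OU correlation time (ms).
DEFAULT_TAU_MS = 3.0

#: Cap on dense covariance size for the theta sampler.
THETA_N_CAP = 200_000


def _check_positive(name, value):
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and positive, got {value!r}")


@dataclass(frozen=True)
class OUSpec:
    """Ornstein-Uhlenbeck stimulus specification.

    The discretization is the exact AR(1) recursion

        eta(t+dt) = eta(t) * exp(-dt/tau) + sqrt(1 - exp(-2dt/tau)) * N(0,1)

    with eta(0) ~ N(0,1), so the sampled process is stationary with zero
    mean and unit variance at every time step.
    """

    tau: float = DEFAULT_TAU_MS
    dt: float = DEFAULT_DT_MS
    duration: float = 10_000.0
    seed: int | None = None

    def __post_init__(self):
        _check_positive("tau", self.tau)
        _check_positive("dt", self.dt)
        if self.duration < self.dt:
            raise ValueError("duration must be at least one time step")

    @property
    def beta(self) -> float:
        return float(np.exp(-self.dt / self.tau))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class ThetaCovSpec:
    """Theta-modulated stimulus specification (autocovariance sampler)."""

    f: float = 8.0          # Hz
    tau: float = 100.0      # ms
    sigma2: float = 1.0
    dt: float = 1.0
    duration: float = 10_000.0
    mu: float = 0.0         # offset added post-sampling
    seed: int | None = None

    def __post_init__(self):
        if self.f < 0:
            raise ValueError("f must be non-negative")
        _check_positive("tau", self.tau)
        _check_positive("sigma2", self.sigma2)
        _check_positive("dt", self.dt)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    def autocovariance(self, u_ms: np.ndarray) -> np.ndarray:
        """rho(u) = sigma^2 cos(2 pi f u) exp(-|u|/tau), u in ms."""
        u = np.abs(np.asarray(u_ms, dtype=float))
        return self.sigma2 * np.cos(2e-3 * np.pi * self.f * u) * np.exp(-u / self.tau)


@dataclass(frozen=True)
class ScalingSpec:
    """Affine conversion eta -> sigma*eta + mu from normalized units to pA."""

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class PairSpec:
    """Correlated stimulus pair: bivariate OU with innovation covariance
    K = [[1, rho], [rho, 1]]."""

    rho: float
    base: OUSpec = field(default_factory=OUSpec)

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")


#: Degrees of separation for the pattern-discrimination task. Higher rho
#: means more similar stimuli, i.e. *lower* separation.
SEPARATION_LEVELS = {"low": 0.9997, "medium": 0.999, "high": 0.99}


@dataclass(frozen=True)
class NoiseSpec:
    """Stimulus corruption level nu in [0, 1).

    The corrupted stimulus is the variance-preserving mixture
    sqrt(1-nu^2)*eta + nu*xi with xi an independent OU draw of the same tau,
    so the corrupted stimulus stays in the stationary distribution the
    decoder's prior assumes. Correlation with the original is sqrt(1-nu^2).
    """

    level: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.level < 1.0):
            raise ValueError("noise level must lie in [0, 1)")


@dataclass
class StimulusTrace:
    """A discretized stimulus time series."""

    values: np.ndarray
    dt: float
    units: str = "norm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus contains non-finite values")
        _check_positive("dt", self.dt)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def ar1_filter(drive: np.ndarray, beta: float) -> np.ndarray:
    """y[t] = drive[t] + beta * y[t-1]; implemented as an IIR filter.

    Bit-identical to the naive scalar recursion (direct form II transposed
    performs the same two rounded operations per step).
    """
    return signal.lfilter([1.0], [1.0, -beta], drive)


def sample_ou(spec: OUSpec, rng: np.random.Generator | None = None) -> StimulusTrace:
    """Sample a stationary OU trace via the exact AR(1) discretization."""
    rng = _rng(spec.seed) if rng is None else rng
    n = spec.n_samples
    beta = spec.beta
    eps = rng.standard_normal(n)
    drive = np.sqrt(1.0 - beta * beta) * eps
    drive[0] = eps[0]  # eta(0) ~ N(0,1): stationary start
    values = ar1_filter(drive, beta)
    return StimulusTrace(values, spec.dt, "norm",
                         meta={"kind": "ou", "tau": spec.tau, "seed": spec.seed})


def theta_cholesky(spec: ThetaCovSpec, jitter: float = 1e-10):
    """Lower Cholesky factor of the dense theta covariance matrix.

    A small diagonal jitter (1e-10 * sigma2, escalated up to three times) is
    added if the matrix is not numerically positive definite; the jitter
    actually used is returned alongside the factor.
    """
    n = spec.n_samples
    if n > THETA_N_CAP:
        raise ValueError(f"theta sampler limited to {THETA_N_CAP} samples, got {n}")
    lags = np.arange(n) * spec.dt
    row = spec.autocovariance(lags)
    C = linalg.toeplitz(row)
    used = 0.0
    for attempt in range(4):
        try:
            L = linalg.cholesky(C + used * np.eye(n) if used else C,
                                lower=True, check_finite=False)
            return L, used
        except linalg.LinAlgError:
            used = jitter * spec.sigma2 * (100.0 ** attempt) if used else jitter * spec.sigma2
    raise np.linalg.LinAlgError(
        f"theta covariance not positive definite after jitter {used:g} "
        f"(f={spec.f}, tau={spec.tau}, n={n})")


def sample_theta(spec: ThetaCovSpec, size: int = 1,
                 rng: np.random.Generator | None = None):
    """Sample stimuli with the theta-modulated autocovariance.

    Returns a single :class:`StimulusTrace` for ``size == 1``, otherwise a
    list. All traces share one Cholesky factorization.
    """
    rng = _rng(spec.seed) if rng is None else rng
    L, jitter_used = theta_cholesky(spec)
    traces = []
    for _ in range(size):
        values = L @ rng.standard_normal(spec.n_samples) + spec.mu
        traces.append(StimulusTrace(
            values, spec.dt, "norm",
            meta={"kind": "theta", "f": spec.f, "tau": spec.tau,
                  "jitter": jitter_used, "seed": spec.seed}))
    return traces[0] if size == 1 else traces


def sample_pair(spec: PairSpec,
                rng: np.random.Generator | None = None) -> tuple[StimulusTrace, StimulusTrace]:
    """Sample a correlated stimulus pair (eta1, eta2).

    Bivariate OU recursion with innovation covariance K = [[1, rho], [rho, 1]]:
    each marginal is a stationary unit-variance OU process with time constant
    tau, and the instantaneous cross-correlation is rho.
    """
    base = spec.base
    rng = _rng(base.seed) if rng is None else rng
    n = base.n_samples
    beta = base.beta
    Lk = np.linalg.cholesky(np.array([[1.0, spec.rho], [spec.rho, 1.0]]))
    eps = rng.standard_normal((n, 2)) @ Lk.T
    drive = np.sqrt(1.0 - beta * beta) * eps
    drive[0] = eps[0]  # stationary correlated start
    values = signal.lfilter([1.0], [1.0, -beta], drive, axis=0)
    meta = {"kind": "ou_pair", "tau": base.tau, "rho": spec.rho}
    return (StimulusTrace(values[:, 0], base.dt, "norm", meta=dict(meta)),
            StimulusTrace(values[:, 1], base.dt, "norm", meta=dict(meta)))


def scale(trace: StimulusTrace, s: ScalingSpec) -> StimulusTrace:
    """Convert a normalized stimulus to a current in pA: i = sigma*eta + mu."""
    meta = dict(trace.meta)
    meta.update({"mu": s.mu, "sigma": s.sigma})
    return StimulusTrace(s.sigma * trace.values + s.mu, trace.dt, "pA", meta=meta)


def corrupt(trace: StimulusTrace, noise: NoiseSpec, ou: OUSpec,
            rng: np.random.Generator | None = None) -> StimulusTrace:
    """Variance-preserving corruption sqrt(1-nu^2)*eta + nu*xi.

    xi is an independent OU draw with the same correlation time, so the
    output stays in the prior's stationary distribution; its correlation
    with the input is sqrt(1-nu^2).
    """
    nu = noise.level
    if nu == 0.0:
        return StimulusTrace(trace.values.copy(), trace.dt, trace.units,
                             meta=dict(trace.meta))
    rng = _rng(noise.seed) if rng is None else rng
    xi_spec = OUSpec(tau=ou.tau, dt=trace.dt, duration=trace.duration)
    xi = sample_ou(xi_spec, rng=rng)
    values = np.sqrt(1.0 - nu * nu) * trace.values + nu * xi.values
    meta = dict(trace.meta)
    meta.update({"noise_level": nu, "noise_model": "variance_preserving_ou_mixture"})
    return StimulusTrace(values, trace.dt, trace.units, meta=meta)


def fit_autocorrelation_time(trace: StimulusTrace, max_lag_ms: float = 30.0) -> float:
    """Decay constant (ms) of a single-exponential fit to the empirical
    autocorrelation up to ``max_lag_ms``."""
    from scipy import optimize

    x = trace.values - trace.values.mean()
    n = x.size
    kmax = int(round(max_lag_ms / trace.dt))
    lags = np.arange(1, kmax + 1)
    acf = np.array([np.dot(x[:-k], x[k:]) / (n - k) for k in lags]) / x.var()
    t = lags * trace.dt
    popt, _ = optimize.curve_fit(lambda t, a, tau: a * np.exp(-t / tau),
                                 t, acf, p0=[1.0, 5.0], maxfev=10000)
    return float(popt[1])


def spectral_peak_frequency(traces, smooth_hz: float = 0.5) -> float:
    """Peak frequency (Hz) of the trial-averaged periodogram.

    The averaged periodogram is smoothed with a Gaussian kernel (symmetric,
    so a symmetric spectral peak is not displaced) and the maximum is
    refined by the vertex of a quadratic fit to log-power over a +-2 Hz
    window around the argmax (log-parabolic peak interpolation).
    """
    if not isinstance(traces, (list, tuple)):
        traces = [traces]
    n = traces[0].n_samples
    dt_s = traces[0].dt / 1000.0
    power = np.mean([np.abs(np.fft.rfft(tr.values - tr.values.mean())) ** 2
                     for tr in traces], axis=0)
    freqs = np.fft.rfftfreq(n, d=dt_s)
    df = freqs[1] - freqs[0]
    half = max(1, int(round(3.0 * smooth_hz / df)))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) * df / smooth_hz) ** 2)
    kern /= kern.sum()
    coverage = np.convolve(np.ones_like(power), kern, mode="same")
    smoothed = np.convolve(power, kern, mode="same") / coverage
    k = int(np.argmax(smoothed[1:])) + 1
    half = max(1, int(round(2.0 / df)))
    lo, hi = max(1, k - half), min(freqs.size, k + half + 1)
    if hi - lo < 3:
        return float(freqs[k])
    coefs = np.polyfit(freqs[lo:hi], np.log(smoothed[lo:hi]), 2)
    if coefs[0] >= 0:
        return float(freqs[k])
    vertex = -coefs[1] / (2.0 * coefs[0])
    if not (freqs[lo] <= vertex <= freqs[hi - 1]):
        return float(freqs[k])
    return float(vertex)


# --------------------------------------------------------------------------
# persistence

def trace_to_hdf5(group, trace: StimulusTrace) -> None:
    """Write a trace into an open h5py group."""
    group.create_dataset("values", data=trace.values)
    group.attrs["dt"] = trace.dt
    group.attrs["units"] = trace.units
    group.attrs["meta"] = json.dumps(trace.meta, default=str)


def trace_from_hdf5(group) -> StimulusTrace:
    return StimulusTrace(group["values"][:], float(group.attrs["dt"]),
                         str(group.attrs["units"]),
                         meta=json.loads(group.attrs.get("meta", "{}")))


def trace_to_csv(path, trace: StimulusTrace) -> None:
    """Two-column CSV: time_ms, value."""
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, delimiter=",", header="time_ms,value", comments="")


def trace_from_csv(path, units: str = "norm") -> StimulusTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    dt = float(data[1, 0] - data[0, 0])
    return StimulusTrace(data[:, 1], dt, units)
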