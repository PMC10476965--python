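"""Spike response model (SRM): generative encoder for granule cells.

The subthreshold membrane potential is

    v(t) = v_b + sum_u k(u) i(t-u) + sum_{t_s < t} h_v(t - t_s)

a voltage bias plus the causal convolution of the injected current with a
membrane filter k, plus a post-spike voltage deflection h_v added after
every past spike. Spiking is driven by the conditional intensity

    lambda(t) = exp((v(t) - v_th - sum_{t_s < t} h_th(t - t_s)) / dv)

with a static threshold v_th, a post-spike threshold deflection h_th and a
voltage scale dv. In each time bin of width dt a spike is emitted with
probability 1 - exp(-lambda(t) * dt); lambda carries units of 1/ms so that
lambda*dt is dimensionless.

Filters live on rectangular bases. The discrete convolution convention is
that filter coefficients are per-time-bin gains at the model's dt: the
stimulus column for basis bin j is the plain sum of i(t-u) over u in the
bin (no dt factor), matching the design matrix used for fitting exactly.
Spike-history filters act on strictly past spikes (lag >= 1 bin); no
explicit voltage reset beyond h_v is modeled, and the action-potential
waveform is not represented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .stimulus import StimulusTrace, DEFAULT_DT_MS

#: Exponent clip for the conditional intensity (guards overflow).
EXP_CLIP = 20.0


@dataclass(frozen=True)
class BasisSpec:
    """Contiguous equal-width rectangular basis: bins [start + i*w, start + (i+1)*w)."""

    start: float       # ms
    bin_width: float   # ms
    n_bins: int

    def __post_init__(self):
        if self.bin_width <= 0 or self.n_bins < 1 or self.start < 0:
            raise ValueError("invalid basis specification")

    @property
    def support(self) -> float:
        """Right edge of the last bin (ms)."""
        return self.start + self.bin_width * self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return self.start + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.start + self.bin_width * (np.arange(self.n_bins) + 0.5)

    def bin_of(self, lag_ms: np.ndarray) -> np.ndarray:
        """Basis index for each lag; -1 outside the support."""
        lag = np.asarray(lag_ms, dtype=float)
        idx = np.floor((lag - self.start) / self.bin_width).astype(int)
        idx[(lag < self.start) | (idx >= self.n_bins)] = -1
        return idx

    def kernel(self, coefs: np.ndarray, dt: float) -> np.ndarray:
        """Per-sample kernel from lag 0 to the support at resolution dt.

        ``kernel[l]`` is the coefficient of the basis bin containing lag
        ``l*dt`` (zero before ``start``). Coefficients are used as-is; any
        per-sample gain rescaling between grids is the caller's concern.
        """
        coefs = np.asarray(coefs, dtype=float)
        if coefs.size != self.n_bins:
            raise ValueError("coefficient length does not match basis")
        edges = np.round(self.edges / dt).astype(int)
        out = np.zeros(edges[-1])
        for j in range(self.n_bins):
            out[edges[j]:edges[j + 1]] = coefs[j]
        return out


#: Default bases: membrane filter k, post-spike voltage filter h_v
#: (starting 25 ms after the spike; the first 25 ms are outside the
#: subthreshold model), post-spike threshold filter h_th.
def default_k_basis() -> BasisSpec:
    return BasisSpec(start=0.0, bin_width=8.0, n_bins=44)


def default_hv_basis() -> BasisSpec:
    return BasisSpec(start=25.0, bin_width=25.0, n_bins=17)


def default_hth_basis() -> BasisSpec:
    return BasisSpec(start=0.0, bin_width=25.0, n_bins=18)


@dataclass
class SRMParams:
    """Full SRM encoder parameters.

    ``k_coefs`` are per-time-bin gains (mV per pA per sample at ``dt``),
    ``hv_coefs`` and ``hth_coefs`` are in mV.
    """

    v_b: float
    k_coefs: np.ndarray
    hv_coefs: np.ndarray
    v_th: float
    hth_coefs: np.ndarray
    delta_v: float
    k_basis: BasisSpec = field(default_factory=default_k_basis)
    hv_basis: BasisSpec = field(default_factory=default_hv_basis)
    hth_basis: BasisSpec = field(default_factory=default_hth_basis)
    dt: float = DEFAULT_DT_MS

    def __post_init__(self):
        self.k_coefs = np.asarray(self.k_coefs, dtype=float)
        self.hv_coefs = np.asarray(self.hv_coefs, dtype=float)
        self.hth_coefs = np.asarray(self.hth_coefs, dtype=float)
        if self.delta_v <= 0:
            raise ValueError("delta_v must be positive")
        for coefs, basis, name in ((self.k_coefs, self.k_basis, "k"),
                                   (self.hv_coefs, self.hv_basis, "h_v"),
                                   (self.hth_coefs, self.hth_basis, "h_th")):
            if coefs.size != basis.n_bins:
                raise ValueError(f"{name} coefficients do not match basis")

    def k_kernel(self, dt: float | None = None) -> np.ndarray:
        """Membrane-filter kernel as per-sample gains at resolution dt.

        Gains rescale with the grid (they absorb the integration step), so
        resampling multiplies by dt/self.dt.
        """
        dt = self.dt if dt is None else dt
        return self.k_basis.kernel(self.k_coefs, dt) * (dt / self.dt)

    def hv_kernel(self, dt: float | None = None) -> np.ndarray:
        """Post-spike voltage kernel (mV, additive; no grid rescaling)."""
        dt = self.dt if dt is None else dt
        return self.hv_basis.kernel(self.hv_coefs, dt)

    def hth_kernel(self, dt: float | None = None) -> np.ndarray:
        dt = self.dt if dt is None else dt
        return self.hth_basis.kernel(self.hth_coefs, dt)

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("k_coefs", "hv_coefs", "hth_coefs"):
            d[key] = d[key].tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SRMParams":
        d = json.loads(text)
        for key in ("k_basis", "hv_basis", "hth_basis"):
            d[key] = BasisSpec(**d[key])
        return cls(**d)


@dataclass
class Recording:
    """One trial: stimulus (pA), subthreshold voltage (mV) and spike times (ms)."""

    stimulus: StimulusTrace
    voltage: np.ndarray | None
    spikes: "SpikeTrain"
    cell_id: str = ""
    trial_id: int = 0

    def __post_init__(self):
        if self.voltage is not None:
            self.voltage = np.asarray(self.voltage, dtype=float)
            if self.voltage.size != self.stimulus.n_samples:
                raise ValueError("voltage and stimulus lengths differ")


def spike_bins(times_ms: np.ndarray, dt: float, n: int) -> np.ndarray:
    """Spike counts per time bin (int array of length n)."""
    # tolerant floor: grid-aligned times (idx*dt) must land in their own bin
    idx = np.floor(np.asarray(times_ms, dtype=float) / dt + 1e-9).astype(int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise ValueError("spike time outside the trace")
    counts = np.zeros(n, dtype=np.int64)
    np.add.at(counts, idx, 1)
    return counts


def _history_sum(kernel: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """sum over past spikes of kernel(t - t_s), strictly past (lag >= 1)."""
    n = counts.size
    ker = kernel.copy()
    if ker.size:
        ker[0] = 0.0  # lag-0 (same bin) contributions excluded
    out = np.convolve(counts.astype(float), ker)[:n]
    return out


def subthreshold_voltage(p: SRMParams, i: StimulusTrace, spikes) -> np.ndarray:
    """Deterministic subthreshold voltage given stimulus and spike times."""
    if abs(i.dt - p.dt) > 1e-12:
        raise ValueError("stimulus dt does not match model dt")
    n = i.n_samples
    v = p.v_b + np.convolve(i.values, p.k_kernel())[:n]
    counts = spike_bins(np.asarray(getattr(spikes, "times", spikes), dtype=float), p.dt, n)
    v += _history_sum(p.hv_kernel(), counts)
    return v


def threshold_trace(p: SRMParams, spikes, n: int) -> np.ndarray:
    """v_th + sum of h_th over past spikes, per bin."""
    counts = spike_bins(np.asarray(getattr(spikes, "times", spikes), dtype=float), p.dt, n)
    return p.v_th + _history_sum(p.hth_kernel(), counts)


def conditional_intensity(p: SRMParams, v: np.ndarray, spikes) -> np.ndarray:
    """lambda(t) in 1/ms; exponent clipped at +20 to guard overflow."""
    theta = threshold_trace(p, spikes, v.size)
    expo = np.minimum((v - theta) / p.delta_v, EXP_CLIP)
    return np.exp(expo)


@njit(cache=True)
def _simulate_core(drive, hv_k, hth_k, v_th, delta_v, dt, u):  # pragma: no cover
    n = drive.size
    v_extra = np.zeros(n)
    th_extra = np.zeros(n)
    spike_idx = np.empty(n, dtype=np.int64)
    n_spk = 0
    n_clip = 0
    for t in range(n):
        expo = (drive[t] + v_extra[t] - v_th - th_extra[t]) / delta_v
        if expo > 20.0:
            expo = 20.0
            n_clip += 1
        lam = np.exp(expo)
        if u[t] < 1.0 - np.exp(-lam * dt):
            spike_idx[n_spk] = t
            n_spk += 1
            top = min(n - t - 1, hv_k.size - 1)
            for l in range(1, top + 1):
                v_extra[t + l] += hv_k[l]
            top = min(n - t - 1, hth_k.size - 1)
            for l in range(1, top + 1):
                th_extra[t + l] += hth_k[l]
    return spike_idx[:n_spk], v_extra, n_clip


def simulate(p: SRMParams, i: StimulusTrace,
             seed: int | None = None,
             rng: np.random.Generator | None = None,
             cell_id: str = "", trial_id: int = 0) -> Recording:
    """Simulate the SRM response to a current trace.

    At each bin a spike is drawn with probability 1 - exp(-lambda(t)*dt);
    on a spike the post-spike kernels are appended to all subsequent bins.
    Returns the subthreshold voltage and the spike train. Fixed seed gives
    bit-identical output. Exponent clip events, if any, are counted in the
    returned recording's stimulus metadata.
    """
    from .metrics import SpikeTrain

    if abs(i.dt - p.dt) > 1e-12:
        raise ValueError("stimulus dt does not match model dt")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = i.n_samples
    drive = p.v_b + np.convolve(i.values, p.k_kernel())[:n]
    u = rng.random(n)
    idx, v_extra, n_clip = _simulate_core(
        drive, p.hv_kernel(), p.hth_kernel(), p.v_th, p.delta_v, p.dt, u)
    times = idx * p.dt
    rec = Recording(stimulus=i, voltage=drive + v_extra,
                    spikes=SpikeTrain(times, duration=i.duration),
                    cell_id=cell_id, trial_id=trial_id)
    if n_clip:
        rec.stimulus.meta = dict(rec.stimulus.meta, intensity_clip_events=int(n_clip))
    return rec
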