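"""Ground-truth synthetic cohorts of simulated granule cells.

Real granule-cell pools are age-heterogeneous: adult-born cells at 4 and 5
weeks post-birth coexist with mature cells. Electrophysiologically,
younger cells integrate input over longer membrane timescales, have larger
input resistance, lower spike thresholds and weaker post-spike
(refractory) effects. This module samples SRM parameter cohorts whose age
groups reproduce those orderings, calibrates each cell's stimulus scaling
(mean mu, amplitude sigma = mu/2) to a target firing rate by bisection —
mirroring the per-cell online adaptation of the stimulus in the
experiments — and synthesizes the full recording protocol: one 99 s
single-trial training recording plus nine repeated 10 s validation trials
per cell, sampled at 10 kHz, with optional Gaussian voltage observation
noise.

Cohort parameter centers are modeling choices that encode the age
*orderings*, not measured values: membrane-filter timescale tau_k =
55/40/25 ms, filter resistance 450/350/250 MOhm, post-spike voltage
deflection hv1 = -0.5/-1.5/-3 mV, threshold deflection hth1 = 2/4/6 mV and
static threshold -53/-51.5/-50 mV for 4w/5w/mature cells respectively.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .stimulus import OUSpec, ScalingSpec, StimulusTrace, sample_ou, scale
from .srm import (SRMParams, BasisSpec, Recording, simulate,
                  default_k_basis, default_hv_basis, default_hth_basis)
from .population import PoolCell, CellPool

#: Conversion MOhm * pA -> mV.
_MOHM_PA_TO_MV = 1e-3


@dataclass(frozen=True)
class AgeParams:
    """Parameter distribution of one age group (centers + dispersions)."""

    tau_k: float          # ms, slow membrane-filter timescale
    resistance: float     # MOhm, area of the slow filter component
    hv1: float            # mV, first post-spike voltage coefficient (<= 0)
    hth1: float           # mV, first post-spike threshold coefficient (> 0)
    v_th: float           # mV
    v_b: float = -70.0    # mV
    delta_v: float = 1.0  # mV
    rel_sd: float = 0.12      # lognormal dispersion of positive magnitudes
    volt_sd: float = 0.8      # mV, normal dispersion of voltages


DEFAULT_AGES = {
    "4w": AgeParams(tau_k=55.0, resistance=450.0, hv1=-0.5, hth1=2.0,
                    v_th=-53.0, delta_v=1.4),
    "5w": AgeParams(tau_k=40.0, resistance=350.0, hv1=-1.5, hth1=4.0,
                    v_th=-51.5, delta_v=1.2),
    "mature": AgeParams(tau_k=25.0, resistance=250.0, hv1=-3.0, hth1=6.0,
                        v_th=-50.0, delta_v=1.0),
}


@dataclass(frozen=True)
class CohortSpec:
    ages: dict = field(default_factory=lambda: dict(DEFAULT_AGES))
    n_cells: dict = field(default_factory=lambda: {"4w": 20, "5w": 17, "mature": 18})
    target_rate_hz: float = 2.0
    dt: float = 0.1
    seed: int = 0
    calib_duration_ms: float = 20_000.0
    rate_tolerance: float = 0.10
    #: secondary filter timescales shared across ages
    tau_hv: float = 100.0
    tau_hth: float = 100.0
    pipette_amp: float = 20.0   # MOhm/ms fast transient, tau 1 ms

    def __post_init__(self):
        for age, p in self.ages.items():
            if p.tau_k <= 0 or p.resistance <= 0 or p.delta_v <= 0:
                raise ValueError(f"invalid parameters for age {age!r}")


@dataclass(frozen=True)
class ProtocolSpec:
    train_duration_ms: float = 99_000.0
    n_validation_trials: int = 9
    validation_duration_ms: float = 10_000.0
    dt: float = 0.1
    voltage_noise_sd: float = 0.3  # mV


def _build_params(age: AgeParams, draw: dict, spec: CohortSpec) -> SRMParams:
    kb, hvb, htb = default_k_basis(), default_hv_basis(), default_hth_basis()
    dt = spec.dt
    tc = kb.centers
    slow = (draw["resistance"] / draw["tau_k"]) * np.exp(-tc / draw["tau_k"])
    fast = spec.pipette_amp * np.exp(-tc / 1.0)
    k = (slow + fast) * dt * _MOHM_PA_TO_MV
    hv = draw["hv1"] * np.exp(-(hvb.centers - hvb.centers[0]) / spec.tau_hv)
    hth = draw["hth1"] * np.exp(-(htb.centers - htb.centers[0]) / spec.tau_hth)
    return SRMParams(v_b=draw["v_b"], k_coefs=k, hv_coefs=hv,
                     v_th=draw["v_th"], hth_coefs=hth,
                     delta_v=draw["delta_v"], k_basis=kb, hv_basis=hvb,
                     hth_basis=htb, dt=dt)


def _draw_cell(age: AgeParams, rng: np.random.Generator) -> dict:
    logn = lambda center: center * rng.lognormal(0.0, age.rel_sd)
    return {
        "tau_k": logn(age.tau_k),
        "resistance": logn(age.resistance),
        "hv1": -logn(-age.hv1),
        "hth1": logn(age.hth1),
        "v_th": age.v_th + rng.normal(0.0, age.volt_sd),
        "v_b": age.v_b + rng.normal(0.0, age.volt_sd),
        "delta_v": logn(age.delta_v),
    }


def _measure_rate(params: SRMParams, mu: float, duration_ms: float,
                  rng_key) -> float:
    eta = sample_ou(OUSpec(tau=3.0, dt=params.dt, duration=duration_ms),
                    rng=np.random.default_rng(rng_key))
    current = scale(eta, ScalingSpec(mu=mu, sigma=0.5 * mu))
    rec = simulate(params, current, rng=np.random.default_rng(rng_key))
    return rec.spikes.rate_hz


def calibrate_scaling(params: SRMParams, target_hz: float,
                      duration_ms: float = 20_000.0, tol: float = 0.10,
                      seed: int = 0, max_iter: int = 40) -> tuple[ScalingSpec, float]:
    """Bisection on the mean current mu (sigma fixed at mu/2) to reach the
    target firing rate within a relative tolerance.

    The firing rate is monotone in mu for fixed sigma/mu ratio. Raises if
    the calibrated rate ends up outside the physiological [0.5, 10] Hz
    window.
    """
    lo, hi = 1.0, 500.0
    mu = 0.5 * (lo + hi)
    rate = 0.0
    for _ in range(max_iter):
        mu = 0.5 * (lo + hi)
        rate = _measure_rate(params, mu, duration_ms, (seed, 17))
        if abs(rate - target_hz) <= tol * target_hz:
            break
        if rate < target_hz:
            lo = mu
        else:
            hi = mu
    if not (0.5 <= rate <= 10.0):
        raise RuntimeError(
            f"rate calibration failed: {rate:.2f} Hz at mu={mu:.1f} pA "
            f"(target {target_hz} Hz)")
    return ScalingSpec(mu=mu, sigma=0.5 * mu), rate


def sample_cohort(spec: CohortSpec = CohortSpec()) -> CellPool:
    """Draw an age-structured pool of simulated cells with calibrated
    stimulus scalings."""
    rng = np.random.default_rng(spec.seed)
    cells = []
    for age_label, age in spec.ages.items():
        for idx in range(spec.n_cells.get(age_label, 0)):
            draw = _draw_cell(age, rng)
            params = _build_params(age, draw, spec)
            scaling, rate = calibrate_scaling(
                params, spec.target_rate_hz, spec.calib_duration_ms,
                spec.rate_tolerance, seed=int(rng.integers(2**31)))
            cells.append(PoolCell(cell_id=f"{age_label}-{idx:02d}",
                                  age=age_label, params=params,
                                  scaling=scaling, rate_hz=rate))
    return CellPool(cells)


def synthesize_recordings(pool: CellPool,
                          protocol: ProtocolSpec = ProtocolSpec(),
                          seed: int = 0) -> dict:
    """Full recording protocol for every cell in the pool.

    One independent 99 s training stimulus per cell; a single 10 s
    validation stimulus template shared by all cells (scaled per cell, as
    in the experiment); nine validation trials; optional additive Gaussian
    voltage noise. Returns {cell_id: {"train": Recording,
    "validation": [Recording, ...]}}.
    """
    ss = np.random.SeedSequence(seed)
    template_rng = np.random.default_rng(ss.spawn(1)[0])
    template = sample_ou(OUSpec(tau=3.0, dt=protocol.dt,
                                duration=protocol.validation_duration_ms),
                         rng=template_rng)
    out = {}
    for cell in pool.cells:
        cell_ss = np.random.SeedSequence((seed, zlib.crc32(cell.cell_id.encode())))
        streams = cell_ss.spawn(protocol.n_validation_trials + 2)
        train_eta = sample_ou(OUSpec(tau=3.0, dt=protocol.dt,
                                     duration=protocol.train_duration_ms),
                              rng=np.random.default_rng(streams[0]))
        noise_rng = np.random.default_rng(streams[1])
        train = simulate(cell.params, scale(train_eta, cell.scaling),
                         rng=np.random.default_rng(streams[0].spawn(1)[0]),
                         cell_id=cell.cell_id, trial_id=0)
        if protocol.voltage_noise_sd > 0:
            train.voltage = train.voltage + noise_rng.normal(
                0.0, protocol.voltage_noise_sd, train.voltage.size)
        validation = []
        current = scale(template, cell.scaling)
        for trial, stream in enumerate(streams[2:]):
            rec = simulate(cell.params, current,
                           rng=np.random.default_rng(stream),
                           cell_id=cell.cell_id, trial_id=trial + 1)
            if protocol.voltage_noise_sd > 0:
                rec.voltage = rec.voltage + noise_rng.normal(
                    0.0, protocol.voltage_noise_sd, rec.voltage.size)
            validation.append(rec)
        out[cell.cell_id] = {"train": train, "validation": validation}
    return out


def load_real(path) -> dict:
    """Load deposited intracellular recordings into Recording objects.

    ``path`` points at a local copy of the study's published dataset
    (current-clamp voltage at 10 kHz; one 99 s training trial and nine
    10 s validation trials per cell). Raw acquisition files require an ABF
    reader; recordings repackaged into this package's HDF5 container (see
    :mod:`dgdecode.io`) are loaded directly. Optional — nothing else
    depends on it.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(
            f"real dataset not found at {path!r}; download the deposited "
            "recordings and point at the local copy")
    if os.path.isdir(path):
        h5s = [f for f in sorted(os.listdir(path)) if f.endswith((".h5", ".hdf5"))]
        abfs = [f for f in os.listdir(path) if f.endswith(".abf")]
        if h5s:
            from .io import read_recordings
            out = {}
            for f in h5s:
                out.update(read_recordings(os.path.join(path, f)))
            return out
        if abfs:
            raise RuntimeError(
                "found raw .abf acquisition files; convert them to the "
                "package's HDF5 recording container (dgdecode.io.write_recordings) "
                "with an ABF reader such as pyabf, then reload")
        raise RuntimeError(f"unrecognized dataset layout under {path!r}")
    from .io import read_recordings
    return read_recordings(path)
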