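"""Shared fixtures: small fast cells with compact filter bases.

The "mini" cells use a 50 ms membrane-filter support and coarse post-spike
bases so that simulation, fitting and (especially) banded decoding stay
fast; the physiology (filter shapes, thresholds, scaling) mirrors the
full-size default cells.
"""

import numpy as np
import pytest

from dgdecode import srm
from dgdecode.stimulus import OUSpec, ScalingSpec, sample_ou, scale
from dgdecode.population import PoolCell, CellPool

MINI_DT = 0.1


def mini_bases():
    return (srm.BasisSpec(0.0, 5.0, 10),    # k: 50 ms
            srm.BasisSpec(25.0, 25.0, 4),   # h_v: 25-125 ms
            srm.BasisSpec(0.0, 25.0, 4))    # h_th: 0-100 ms


def make_mini_params(tau_k=15.0, R=150.0, hv1=-2.5, hth1=5.0, v_th=-52.0,
                     v_b=-70.0, delta_v=1.0):
    kb, hvb, htb = mini_bases()
    k = (R / tau_k) * np.exp(-kb.centers / tau_k) * MINI_DT * 1e-3
    hv = hv1 * np.exp(-(hvb.centers - hvb.centers[0]) / 80.0)
    hth = hth1 * np.exp(-(htb.centers - htb.centers[0]) / 80.0)
    return srm.SRMParams(v_b=v_b, k_coefs=k, hv_coefs=hv, v_th=v_th,
                         hth_coefs=hth, delta_v=delta_v, k_basis=kb,
                         hv_basis=hvb, hth_basis=htb, dt=MINI_DT)


def make_mini_cell(cell_id, age, mu, seed, **params_kw):
    params = make_mini_params(**params_kw)
    scaling = ScalingSpec(mu=mu, sigma=0.5 * mu)
    eta = sample_ou(OUSpec(tau=3.0, dt=MINI_DT, duration=10_000.0, seed=seed))
    rec = srm.simulate(params, scale(eta, scaling), seed=seed)
    return PoolCell(cell_id=cell_id, age=age, params=params, scaling=scaling,
                    rate_hz=max(rec.spikes.rate_hz, 0.5))


@pytest.fixture(scope="session")
def mini_cell():
    """A single mature-like mini cell with a healthy firing rate."""
    return make_mini_cell("m0", "mature", mu=120.0, seed=1)


@pytest.fixture(scope="session")
def mini_pool():
    """Four mini cells spanning the age range (precision decreasing with
    membrane timescale, as in the cohorts)."""
    return CellPool([
        make_mini_cell("m0", "mature", mu=120.0, seed=1,
                       tau_k=15, R=150, hv1=-2.5, hth1=5.0, v_th=-52, delta_v=1.0),
        make_mini_cell("m1", "mature", mu=110.0, seed=2,
                       tau_k=18, R=170, hv1=-2.0, hth1=4.5, v_th=-52, delta_v=1.1),
        make_mini_cell("w0", "4w", mu=60.0, seed=3,
                       tau_k=40, R=300, hv1=-0.5, hth1=1.5, v_th=-54, delta_v=1.4),
        make_mini_cell("w1", "5w", mu=80.0, seed=4,
                       tau_k=30, R=250, hv1=-1.0, hth1=3.0, v_th=-53, delta_v=1.2),
    ])
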