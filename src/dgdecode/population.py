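"""Greedy construction of decoding-optimized populations.

Starting from a single mature cell, the greedy procedure extends the
population one cell at a time: at each step every pool cell (selection with
replacement, so the same neuron can appear multiple times) is tentatively
added, the stimulus is decoded from the extended group's spike trains over
a set of freshly sampled OU stimuli, and the candidate with the largest
mean r-squared is kept. Each cell contributes round(n/(lambda*T)) trials so
that its expected spike contribution matches a common target (1200 by
default), removing the trivial preference for high-rate cells.

Candidate evaluations within one step share the same stimulus seeds
(common random numbers) to reduce selection noise; ties in the argmax are
broken deterministically toward the lowest cell id and logged. A
constrained variant restricts the candidate set to mature cells for the
first steps; a random-selection baseline and a bootstrap comparison of
reconstruction MSE between two groups of populations complete the
module.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .stimulus import OUSpec, ScalingSpec, sample_ou
from .srm import SRMParams
from .decoding import (PriorSpec, DecodeConfig, map_decode, simulate_bank,
                       decimate_stimulus, equalize_trials)

AGES = ("4w", "5w", "mature")


@dataclass
class PoolCell:
    cell_id: str
    age: str
    params: SRMParams
    scaling: ScalingSpec
    rate_hz: float

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")


@dataclass
class CellPool:
    cells: list

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell ids must be unique")
        self._by_id = {c.cell_id: c for c in self.cells}

    def __len__(self):
        return len(self.cells)

    def __getitem__(self, cell_id: str) -> PoolCell:
        return self._by_id[cell_id]

    @property
    def ids(self):
        return [c.cell_id for c in self.cells]

    def of_age(self, age: str):
        return [c.cell_id for c in self.cells if c.age == age]


@dataclass(frozen=True)
class GreedyConfig:
    duration_ms: float = 10_000.0
    tau: float = 3.0
    decode_dt: float = 1.0
    spikes_per_cell: float = 1200.0
    repeats: int = 20
    decode: DecodeConfig = DecodeConfig()


@dataclass
class PopulationSelection:
    """Ordered greedy selection (repeats allowed) with per-step performance."""

    cell_ids: list
    trial_counts: dict
    r2_trace: list
    info_trace: list
    mse_trace: list
    constraint: int = 0   # mature-only steps
    ties: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.cell_ids)


def _cell_tuple(cell: PoolCell):
    return (cell.cell_id, cell.params, cell.scaling)


def _member_entries(pool, member_ids, trials, eta, step, rep, seed):
    """Entries for current members; instance index keeps repeated cells on
    independent simulation streams."""
    cells = []
    counts = {}
    for pos, cid in enumerate(member_ids):
        key = f"{cid}#{pos}"
        c = pool[cid]
        cells.append((key, c.params, c.scaling))
        counts[key] = trials[cid]
    ss = np.random.SeedSequence((seed, step, rep, 0))
    return simulate_bank(cells, eta, counts, ss)


def _evaluate(pool, member_ids, candidate_id, stimuli, trials, prior, cfg,
              step, seed, member_cache):
    """Mean r2 / info / mse of (members + candidate) over the step's stimuli."""
    r2s, infos, mses = [], [], []
    for rep, (eta, eta_dec) in enumerate(stimuli):
        members = member_cache.setdefault(
            rep, _member_entries(pool, member_ids, trials, eta, step, rep, seed))
        entries = list(members)
        if candidate_id is not None:
            c = pool[candidate_id]
            ss = np.random.SeedSequence((seed, step, rep, 1,
                                         zlib.crc32(candidate_id.encode())))
            entries = entries + simulate_bank(
                [(f"{candidate_id}#cand", c.params, c.scaling)], eta,
                {f"{candidate_id}#cand": trials[candidate_id]}, ss)
        res = map_decode(entries, prior, cfg.decode, eta_true=eta_dec)
        r2s.append(res.r2)
        infos.append(res.info_bits)
        mses.append(float(np.mean((eta_dec - res.eta_map) ** 2)))
    return float(np.mean(r2s)), float(np.mean(infos)), float(np.mean(mses))


def _step_stimuli(cfg: GreedyConfig, sim_dt: float, seed: int, step: int):
    stimuli = []
    for rep in range(cfg.repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, step, rep, 7)))
        eta = sample_ou(OUSpec(tau=cfg.tau, dt=sim_dt, duration=cfg.duration_ms),
                        rng=rng)
        stimuli.append((eta, decimate_stimulus(eta, cfg.decode_dt)))
    return stimuli


def greedy_build(pool: CellPool, start_id: str, K: int,
                 cfg: GreedyConfig = GreedyConfig(), seed: int = 0,
                 mature_only_steps: int = 0) -> PopulationSelection:
    """Build a K-cell population by greedy r2 maximization.

    ``mature_only_steps`` restricts the candidate set to mature cells for
    that many selection steps (step 1 is the fixed start cell and counts
    toward it).
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if start_id not in pool.ids:
        raise ValueError(f"start cell {start_id!r} not in pool")
    sim_dt = pool.cells[0].params.dt
    T_s = cfg.duration_ms / 1000.0
    trials = {c.cell_id: equalize_trials(c.rate_hz, T_s, cfg.spikes_per_cell)
              for c in pool.cells}
    n_dec = int(round(cfg.duration_ms / sim_dt)) // int(round(cfg.decode_dt / sim_dt))
    prior = PriorSpec(tau=cfg.tau, dt=cfg.decode_dt, n=n_dec)

    members = [start_id]
    stimuli0 = _step_stimuli(cfg, sim_dt, seed, 0)
    r2_0, info_0, mse_0 = _evaluate(pool, [start_id], None, stimuli0, trials,
                                    prior, cfg, 0, seed, {})
    sel = PopulationSelection(cell_ids=[start_id], trial_counts=trials,
                              r2_trace=[r2_0], info_trace=[info_0],
                              mse_trace=[mse_0], constraint=mature_only_steps)
    for step in range(1, K):
        candidates = (pool.of_age("mature") if step < mature_only_steps
                      else pool.ids)
        stimuli = _step_stimuli(cfg, sim_dt, seed, step)
        cache = {}
        scores = {}
        for cid in sorted(candidates):
            scores[cid] = _evaluate(pool, members, cid, stimuli, trials,
                                    prior, cfg, step, seed, cache)
        best_r2 = max(s[0] for s in scores.values())
        winners = sorted(cid for cid, s in scores.items() if s[0] == best_r2)
        if len(winners) > 1:
            sel.ties.append((step, winners))
        chosen = winners[0]
        members.append(chosen)
        sel.cell_ids.append(chosen)
        sel.r2_trace.append(scores[chosen][0])
        sel.info_trace.append(scores[chosen][1])
        sel.mse_trace.append(scores[chosen][2])
    return sel


def constrained_greedy(pool: CellPool, start_id: str, K: int,
                       mature_only_steps: int,
                       cfg: GreedyConfig = GreedyConfig(),
                       seed: int = 0) -> PopulationSelection:
    """Greedy build restricted to mature candidates for the first steps."""
    if mature_only_steps > K:
        raise ValueError("mature_only_steps cannot exceed K")
    return greedy_build(pool, start_id, K, cfg=cfg, seed=seed,
                        mature_only_steps=mature_only_steps)


def random_baseline(pool: CellPool, K: int, n_pops: int,
                    cfg: GreedyConfig = GreedyConfig(), seed: int = 0):
    """Uniform random selection with replacement; per-size mean performance.

    Returns (selections, r2_per_size, info_per_size, mse_per_size), the
    arrays shaped (n_pops, K).
    """
    rng = np.random.default_rng(seed)
    sim_dt = pool.cells[0].params.dt
    T_s = cfg.duration_ms / 1000.0
    trials = {c.cell_id: equalize_trials(c.rate_hz, T_s, cfg.spikes_per_cell)
              for c in pool.cells}
    n_dec = int(round(cfg.duration_ms / sim_dt)) // int(round(cfg.decode_dt / sim_dt))
    prior = PriorSpec(tau=cfg.tau, dt=cfg.decode_dt, n=n_dec)
    ids = pool.ids
    selections = []
    r2 = np.zeros((n_pops, K))
    info = np.zeros((n_pops, K))
    mse = np.zeros((n_pops, K))
    for p in range(n_pops):
        chosen = [ids[i] for i in rng.integers(0, len(ids), size=K)]
        sel = PopulationSelection(cell_ids=chosen, trial_counts=trials,
                                  r2_trace=[], info_trace=[], mse_trace=[])
        stimuli = _step_stimuli(cfg, sim_dt, seed + 1000 + p, 0)
        for k in range(1, K + 1):
            cache = {}
            r, i, m = _evaluate(pool, chosen[:k], None, stimuli, trials, prior,
                                cfg, 0, seed + 1000 + p, cache)
            r2[p, k - 1], info[p, k - 1], mse[p, k - 1] = r, i, m
            sel.r2_trace.append(r)
            sel.info_trace.append(i)
            sel.mse_trace.append(m)
        selections.append(sel)
    return selections, r2, info, mse


def selection_census(selections: list, pool: CellPool) -> dict:
    """Tally how often each cell was selected and the per-step age mix.

    Returns per-cell counts, per-step and cumulative age fractions, the
    conservation total, and the expected per-cell count under uniform
    random selection of the non-start steps, n_pops*(K-1)/pool_size.
    """
    counts = {cid: 0 for cid in pool.ids}
    K = max(sel.size for sel in selections)
    step_age = np.zeros((K, len(AGES)))
    for sel in selections:
        for step, cid in enumerate(sel.cell_ids):
            counts[cid] += 1
            step_age[step, AGES.index(pool[cid].age)] += 1
    step_totals = step_age.sum(axis=1, keepdims=True)
    step_fractions = step_age / np.maximum(step_totals, 1)
    cum = np.cumsum(step_age, axis=0)
    cum_fractions = cum / np.maximum(cum.sum(axis=1, keepdims=True), 1)
    n_pops = len(selections)
    total = sum(counts.values())
    return {
        "counts": counts,
        "ages": AGES,
        "step_fractions": step_fractions,
        "cumulative_fractions": cum_fractions,
        "total_selections": total,
        "expected_uniform_count": n_pops * (K - 1) / len(pool),
    }


def relative_mse_bootstrap(mse_a: np.ndarray, mse_b: np.ndarray,
                           n_boot: int = 1000, seed: int = 0):
    """Bootstrap ratio of group-mean reconstruction MSE per population size.

    ``mse_a``/``mse_b``: arrays (n_populations, n_sizes) of per-population
    MSE evaluated on common stimulus seeds. Returns (ratio, ci_low,
    ci_high) per size, with a symmetric 95% percentile interval of
    mean(A)/mean(B) over resampled populations.
    """
    mse_a = np.atleast_2d(np.asarray(mse_a, dtype=float))
    mse_b = np.atleast_2d(np.asarray(mse_b, dtype=float))
    rng = np.random.default_rng(seed)
    ratio = mse_a.mean(axis=0) / mse_b.mean(axis=0)
    boots = np.empty((n_boot, mse_a.shape[1]))
    for i in range(n_boot):
        ia = rng.integers(0, mse_a.shape[0], size=mse_a.shape[0])
        ib = rng.integers(0, mse_b.shape[0], size=mse_b.shape[0])
        boots[i] = mse_a[ia].mean(axis=0) / mse_b[ib].mean(axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return ratio, lo, hi
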