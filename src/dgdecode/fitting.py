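"""Two-stage SRM estimation.

Stage 1 (subthreshold): the predicted voltage is linear in the parameters,

    v_hat(t) = x(t)' theta_sub,   x(t) = (1, stimulus-basis convolutions,
                                          spike-history basis sums)

and theta_sub = (v_b, a_1..a_J, b_1..b_L) is obtained by linear least
squares on the recorded subthreshold potential after removing the first
25 ms of voltage following every spike. The solve uses an SVD-based
least-squares factorization rather than the normal equations.

Stage 2 (threshold): with v_hat fixed, the spike-train point-process
log-likelihood

    log P(s | i; theta_th) = sum_s y(t_s)' theta_th - dt * sum_t exp(y(t)' theta_th)

with y(t) = (v_hat(t), -1, threshold-history basis sums) and
theta_th = (1/dv) * (1, v_th, c_1..c_M) is concave and maximized by a
safeguarded Newton ascent. A quadratic smoothness penalty
-alpha * sum_m (theta_{m+1} - theta_m)^2 on the threshold-filter tail of
theta_th keeps h_th smooth; alpha is selected by the largest unpenalized
log-likelihood on held-out validation trials. (The penalty is written on
the scaled coefficients dv^{-1} c_m, which preserves concavity in
theta_th; it equals the penalty on c_m up to a rescaling of alpha.)

Validation metrics: subthreshold RMSE under the same post-spike mask, the
log-likelihood in bits per spike relative to a homogeneous Poisson process
of the same rate, and the Md coincidence similarity between simulated and
recorded spike-train sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .srm import (SRMParams, BasisSpec, Recording, spike_bins,
                  default_k_basis, default_hv_basis, default_hth_basis)
from .metrics import SpikeTrain, TrialSet, md_similarity, CoincidenceSpec

LN2 = np.log(2.0)


@dataclass(frozen=True)
class FitConfig:
    alpha_grid: tuple = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)
    newton_tol: float = 1e-6
    max_iter: int = 100
    postspike_mask_ms: float = 25.0
    delta_v_init: float = 1.0


@dataclass
class DesignMatrix:
    """Rows are time bins; columns are [1, J stimulus cols, L history cols].

    ``mask`` flags rows usable by the subthreshold stage (True = keep);
    masked rows are flagged, not dropped, so the threshold stage can reuse
    the unmasked matrix.
    """

    X: np.ndarray
    mask: np.ndarray
    spike_counts: np.ndarray
    dt: float
    n_stim_cols: int
    n_hist_cols: int


def _basis_sample_edges(basis: BasisSpec, dt: float) -> np.ndarray:
    return np.round(basis.edges / dt).astype(int)


def _windowed_sums(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """out[t] = sum_{u=lo}^{hi-1} x[t-u], truncated at t-u >= 0."""
    n = x.size
    P = np.concatenate([[0.0], np.cumsum(x)])  # P[m] = sum_{<m} x
    t = np.arange(n)
    b = np.minimum(t - lo, n - 1)       # last index included
    a = np.maximum(t - hi + 1, 0)       # first index included
    out = np.where(b >= 0, P[np.maximum(b, -1) + 1] - P[np.clip(a, 0, n)], 0.0)
    return out


def postspike_mask(spike_counts: np.ndarray, dt: float, mask_ms: float) -> np.ndarray:
    """True where the bin is *outside* every post-spike exclusion window
    [t_s, t_s + mask_ms)."""
    w = max(1, int(round(mask_ms / dt)))
    hit = np.convolve(spike_counts.astype(float), np.ones(w))[: spike_counts.size]
    return hit == 0


def build_design(i, spikes, k_basis: BasisSpec | None = None,
                 hv_basis: BasisSpec | None = None,
                 dt: float | None = None,
                 mask_ms: float = 25.0) -> DesignMatrix:
    """Assemble the subthreshold design matrix.

    Stimulus columns sum i(t-u) over each membrane-filter basis bin;
    spike-history columns count past spikes (lag >= 1 bin) per
    voltage-filter basis bin, matching the simulator's convolution
    convention exactly.
    """
    k_basis = k_basis or default_k_basis()
    hv_basis = hv_basis or default_hv_basis()
    x = np.asarray(getattr(i, "values", i), dtype=float)
    if dt is None:
        dt = getattr(i, "dt", None)
        if dt is None:
            raise ValueError("dt required when stimulus is a bare array")
    n = x.size
    if int(round(max(k_basis.support, hv_basis.support) / dt)) >= n:
        raise ValueError("basis support exceeds trace length")
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    counts = spike_bins(times, dt, n).astype(float)

    cols = [np.ones(n)]
    ke = _basis_sample_edges(k_basis, dt)
    for j in range(k_basis.n_bins):
        cols.append(_windowed_sums(x, ke[j], ke[j + 1]))
    he = _basis_sample_edges(hv_basis, dt)
    for l in range(hv_basis.n_bins):
        cols.append(_windowed_sums(counts, max(he[l], 1), max(he[l + 1], 1)))
    X = np.column_stack(cols)
    return DesignMatrix(X=X, mask=postspike_mask(counts, dt, mask_ms),
                        spike_counts=counts, dt=dt,
                        n_stim_cols=k_basis.n_bins, n_hist_cols=hv_basis.n_bins)


def fit_subthreshold(v: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Least-squares estimate of theta_sub = (v_b, a_j, b_l) on masked rows.

    Identically-zero columns (e.g. spike-history columns of a spikeless
    recording) get zero coefficients; any other rank deficiency raises,
    naming the degenerate columns.
    """
    v = np.asarray(v, dtype=float)
    X = design.X[design.mask]
    nonzero = np.flatnonzero(np.abs(X).max(axis=0) > 0)
    Xr = X[:, nonzero]
    sol, _, rank, _ = np.linalg.lstsq(Xr, v[design.mask], rcond=None)
    if rank < Xr.shape[1]:
        _, s, vt = np.linalg.svd(Xr, full_matrices=False)
        bad = nonzero[np.abs(vt[rank:]).max(axis=0) > 1e-3]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {Xr.shape[1]}); "
            f"degenerate columns {bad.tolist()}")
    theta = np.zeros(X.shape[1])
    theta[nonzero] = sol
    return theta


def build_threshold_design(v_hat: np.ndarray, spikes, hth_basis: BasisSpec | None = None,
                           dt: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Y matrix (n x (2+M)) of rows y(t) = (v_hat, -1, -history sums), plus
    the binned spike counts.

    The history columns carry a minus sign so that y(t)' theta_th with
    theta_th = (1/dv)(1, v_th, c_1..c_M) reproduces the conditional
    intensity exp((v - v_th - sum h_th)/dv) with c_m the h_th coefficients
    on the same sign convention as the simulator.
    """
    hth_basis = hth_basis or default_hth_basis()
    n = v_hat.size
    times = np.asarray(getattr(spikes, "times", spikes), dtype=float)
    counts = spike_bins(times, dt, n).astype(float)
    cols = [v_hat, -np.ones(n)]
    ed = _basis_sample_edges(hth_basis, dt)
    for m in range(hth_basis.n_bins):
        cols.append(-_windowed_sums(counts, max(ed[m], 1), max(ed[m + 1], 1)))
    return np.column_stack(cols), counts


def _penalty_matrix(p: int, n_filter: int) -> np.ndarray:
    """D'D for first differences over the last n_filter parameters."""
    D = np.zeros((max(n_filter - 1, 0), p))
    for m in range(n_filter - 1):
        D[m, p - n_filter + m] = -1.0
        D[m, p - n_filter + m + 1] = 1.0
    return D.T @ D


def loglik(theta: np.ndarray, Y: np.ndarray, counts: np.ndarray, dt: float,
           alpha: float = 0.0, pen: np.ndarray | None = None):
    """Penalized point-process log-likelihood with gradient and Hessian.

    Concave in theta. The exponent is clipped at +50 only as an overflow
    guard far outside the region explored by the safeguarded Newton steps.
    """
    if pen is None:
        pen = _penalty_matrix(theta.size, theta.size - 2)
    z = np.minimum(Y @ theta, 50.0)
    lam = np.exp(z)
    ll = float(counts @ z - dt * lam.sum() - alpha * (theta @ pen @ theta))
    grad = Y.T @ counts - dt * (Y.T @ lam) - 2.0 * alpha * (pen @ theta)
    hess = -dt * (Y.T * lam) @ Y - 2.0 * alpha * pen
    return ll, grad, hess


def newton_ascent(f, theta0: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Safeguarded Newton maximization of a concave objective.

    ``f(theta) -> (value, grad, hess)``. Halves the step while the value
    decreases. Raises on non-convergence with the iterate trajectory.
    """
    theta = theta0.astype(float).copy()
    val, grad, hess = f(theta)
    trajectory = [(val, float(np.abs(grad).max()))]
    for _ in range(max_iter):
        if np.abs(grad).max() < tol:
            return theta, trajectory
        step = np.linalg.solve(-hess + 1e-12 * np.eye(theta.size), grad)
        scale = 1.0
        for _ in range(50):
            cand = theta + scale * step
            cval, cgrad, chess = f(cand)
            if cval >= val - 1e-12:
                break
            scale *= 0.5
        theta, val, grad, hess = cand, cval, cgrad, chess
        trajectory.append((val, float(np.abs(grad).max())))
    if np.abs(grad).max() < tol:
        return theta, trajectory
    raise RuntimeError(f"Newton did not converge in {max_iter} iterations; "
                       f"trajectory: {trajectory}")


def fit_threshold(v_hat: np.ndarray, spikes, hth_basis: BasisSpec | None = None,
                  dt: float = 0.1, cfg: FitConfig = FitConfig(),
                  validation: list | None = None):
    """Penalized MLE of theta_th; alpha selected on validation data.

    ``validation`` is a list of (v_hat, spikes) pairs; when given, each
    alpha on the grid is fitted on the training data and scored by the
    summed unpenalized log-likelihood on the validation pairs. Returns
    (theta_th, alpha_selected, info dict).
    """
    hth_basis = hth_basis or default_hth_basis()
    Y, counts = build_threshold_design(v_hat, spikes, hth_basis, dt)
    p = Y.shape[1]
    pen = _penalty_matrix(p, hth_basis.n_bins)
    theta0 = np.zeros(p)
    theta0[0] = 1.0 / cfg.delta_v_init
    theta0[1] = (v_hat.mean() + 2.0 * v_hat.std()) / cfg.delta_v_init

    val_designs = None
    if validation:
        val_designs = [build_threshold_design(vh, sp, hth_basis, dt)
                       for vh, sp in validation]

    alphas = cfg.alpha_grid if (validation and len(cfg.alpha_grid) > 1) else (cfg.alpha_grid[0],)
    best = None
    for alpha in alphas:
        theta, traj = newton_ascent(
            lambda th: loglik(th, Y, counts, dt, alpha, pen),
            theta0, tol=cfg.newton_tol, max_iter=cfg.max_iter)
        if val_designs:
            score = sum(loglik(theta, Yv, cv, dt, 0.0, pen)[0]
                        for Yv, cv in val_designs)
        else:
            score = loglik(theta, Y, counts, dt, 0.0, pen)[0]
        if best is None or score > best[0]:
            best = (score, alpha, theta, traj)
    score, alpha_sel, theta, traj = best
    return theta, alpha_sel, {"validation_score": score, "n_iter": len(traj),
                              "trajectory": traj}


def unpack_threshold(theta_th: np.ndarray):
    """(delta_v, v_th, c) from theta_th = (1/dv)(1, v_th, c_1..c_M)."""
    if theta_th[0] <= 0:
        raise ValueError("invalid threshold solution: non-positive voltage-scale gain")
    delta_v = 1.0 / theta_th[0]
    v_th = theta_th[1] * delta_v
    c = theta_th[2:] * delta_v
    return delta_v, v_th, c


def unpack_subthreshold(theta_sub: np.ndarray, n_stim: int):
    v_b = theta_sub[0]
    a = theta_sub[1:1 + n_stim]
    b = theta_sub[1 + n_stim:]
    return v_b, a, b


def normalized_loglik(theta_th: np.ndarray, Y: np.ndarray, counts: np.ndarray,
                      dt: float) -> float:
    """Log-likelihood in bits per spike relative to a homogeneous Poisson
    process of the same empirical rate.

    L = (1/n) log2 [ P(s|i;theta) / P(n | lambda_bar) ] with
    log P(n|lambda) = n log(lambda) - lambda*T; the comparison is invariant
    to the units of lambda.
    """
    n_s = counts.sum()
    if n_s == 0:
        raise ValueError("normalized log-likelihood undefined for an empty train")
    T = counts.size * dt
    ll_model = loglik(theta_th, Y, counts, dt, 0.0)[0]
    lam_bar = n_s / T
    ll_pois = n_s * np.log(lam_bar) - lam_bar * T
    return float((ll_model - ll_pois) / (n_s * LN2))


@dataclass
class FilterSummary:
    tau: float         # ms
    resistance: float  # MOhm
    amplitude: float   # MOhm/ms


def filter_summary(k_coefs: np.ndarray, basis: BasisSpec, dt: float,
                   skip_bins: int = 2) -> FilterSummary:
    """Exponential fit to the tail of the membrane filter k(t).

    The first ``skip_bins`` bins (fast pipette transient) are excluded. The
    continuous filter value on bin j is a_j / dt in mV/pA/ms, i.e.
    1000 * MOhm/ms; the tail is fit with A*exp(-t/tau) and the resistance
    is the analytic area A*tau in MOhm.
    """
    k_coefs = np.asarray(k_coefs, dtype=float)
    if basis.n_bins - skip_bins < 5:
        raise ValueError("need at least five tail bins for the exponential fit")
    t = basis.centers[skip_bins:]
    y = 1000.0 * k_coefs[skip_bins:] / dt  # MOhm/ms
    pos = y > 0
    if pos.sum() < 3:
        raise RuntimeError("filter tail not positive; exponential fit failed")
    # log-linear initialization, then nonlinear refinement
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else basis.support / 4
    try:
        popt, _ = optimize.curve_fit(lambda t, A, tau: A * np.exp(-t / tau),
                                     t, y, p0=[np.exp(intercept), abs(tau0)],
                                     maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"filter tail fit failed: {err}") from err
    A, tau = popt
    return FilterSummary(tau=float(tau), resistance=float(A * tau), amplitude=float(A))


@dataclass
class FitReport:
    params: SRMParams
    rmse_sub: float          # mV, on validation, post-spike mask applied
    norm_loglik: float       # bits/spike, mean over validation trials
    md_score: float
    alpha_selected: float
    diagnostics: dict = field(default_factory=dict)


def fit_srm(train: Recording, validation: list[Recording] | None = None,
            k_basis: BasisSpec | None = None, hv_basis: BasisSpec | None = None,
            hth_basis: BasisSpec | None = None,
            cfg: FitConfig = FitConfig(), seed: int = 0) -> FitReport:
    """Full two-stage SRM fit from one training recording.

    Uses one long training trial; validation trials (sharing one stimulus)
    supply the alpha selection and the report metrics.
    """
    k_basis = k_basis or default_k_basis()
    hv_basis = hv_basis or default_hv_basis()
    hth_basis = hth_basis or default_hth_basis()
    dt = train.stimulus.dt

    design = build_design(train.stimulus, train.spikes, k_basis, hv_basis,
                          dt=dt, mask_ms=cfg.postspike_mask_ms)
    theta_sub = fit_subthreshold(train.voltage, design)
    v_hat = design.X @ theta_sub
    v_b, a, b = unpack_subthreshold(theta_sub, k_basis.n_bins)

    val_pairs = None
    val_vhats = []
    if validation:
        for rec in validation:
            d = build_design(rec.stimulus, rec.spikes, k_basis, hv_basis,
                             dt=dt, mask_ms=cfg.postspike_mask_ms)
            val_vhats.append((d.X @ theta_sub, d))
        val_pairs = [(vh, rec.spikes) for (vh, _), rec in zip(val_vhats, validation)]

    theta_th, alpha_sel, info = fit_threshold(
        v_hat, train.spikes, hth_basis, dt, cfg, validation=val_pairs)
    delta_v, v_th, c = unpack_threshold(theta_th)
    params = SRMParams(v_b=v_b, k_coefs=a, hv_coefs=b, v_th=v_th,
                       hth_coefs=c, delta_v=delta_v, k_basis=k_basis,
                       hv_basis=hv_basis, hth_basis=hth_basis, dt=dt)

    rmse = np.nan
    nll = np.nan
    md = np.nan
    if validation:
        report = validate(params, validation, cfg=cfg, seed=seed)
        rmse, nll, md = report["rmse_sub"], report["norm_loglik"], report["md_score"]
    return FitReport(params=params, rmse_sub=rmse, norm_loglik=nll,
                     md_score=md, alpha_selected=alpha_sel, diagnostics=info)


def validate(params: SRMParams, validation: list[Recording],
             cfg: FitConfig = FitConfig(), seed: int = 0,
             window: CoincidenceSpec = CoincidenceSpec()) -> dict:
    """Validation metrics for a fitted SRM on held-out trials.

    Subthreshold RMSE uses the recorded spikes and the same post-spike
    mask as training; the normalized log-likelihood is computed per trial;
    Md compares as many simulated as recorded trains on the shared
    validation stimulus.
    """
    from . import srm as _srm

    dt = params.dt
    theta_th = np.concatenate([[1.0, params.v_th], params.hth_coefs]) / params.delta_v
    rmses, nlls = [], []
    for rec in validation:
        v_hat = _srm.subthreshold_voltage(params, rec.stimulus, rec.spikes)
        counts = spike_bins(rec.spikes.times, dt, rec.stimulus.n_samples)
        mask = postspike_mask(counts, dt, cfg.postspike_mask_ms)
        if rec.voltage is not None and mask.any():
            rmses.append(np.sqrt(np.mean((v_hat[mask] - rec.voltage[mask]) ** 2)))
        Y, cts = build_threshold_design(v_hat, rec.spikes, params.hth_basis, dt)
        if cts.sum() > 0:
            nlls.append(normalized_loglik(theta_th, Y, cts, dt))
    md = np.nan
    if len(validation) >= 2:
        rng = np.random.default_rng(seed)
        sim = [_srm.simulate(params, rec.stimulus, rng=rng).spikes
               for rec in validation]
        recorded = TrialSet([rec.spikes for rec in validation])
        simulated = TrialSet(sim)
        try:
            md = md_similarity(recorded, simulated, window)
        except ValueError:
            md = np.nan
    return {"rmse_sub": float(np.mean(rmses)) if rmses else np.nan,
            "norm_loglik": float(np.mean(nlls)) if nlls else np.nan,
            "md_score": float(md)}
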