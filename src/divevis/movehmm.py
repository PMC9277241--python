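"""Three-state movement HMM with turbidity-dependent transitions.

States are ``rest``, ``ars`` (area-restricted search) and ``transit``,
observed through step length (gamma, with optional zero-inflation for
coincident fixes) and turning angle (von Mises).  Off-diagonal transition
probabilities follow a multinomial logit in Secchi-disc depth ``z``:

    Gamma_ij(z)  propto  exp(beta0_ij + betaz_ij * z)   (i != j),
    Gamma_ii     propto  1.

Fitting maximizes the forward log-likelihood directly over unconstrained
working parameters (log / logit transforms), with multi-start jitter.
Fitted models are canonicalized by ascending step mean so state 0 is always
rest and state 2 transit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._hmm_kernels import (forward_backward, forward_loglik, nll_fast,
                           viterbi_path)

__all__ = [
    "STATES",
    "REST",
    "ARS",
    "TRANSIT",
    "HMMParams",
    "HMMFit",
    "transition_matrix",
    "stationary_dist",
    "hmm_loglik",
    "fit_hmm",
    "viterbi",
    "posterior_probs",
    "transition_curves",
    "bootstrap_transition_curves",
    "compare_models",
    "simulate_series",
]

logger = logging.getLogger(__name__)

STATES = ("rest", "ars", "transit")
REST, ARS, TRANSIT = 0, 1, 2
_OFFDIAG = [(i, j) for i in range(3) for j in range(3) if i != j]


@dataclass
class HMMParams:
    """State-dependent distributions plus transition coefficients.

    Arrays are indexed by state (rest, ars, transit).  ``beta0``/``beta_z``
    are 3x3 with the diagonal ignored; ``beta_z`` is on the natural Zsd (m)
    scale.  ``delta`` is the initial state distribution.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mean: np.ndarray
    turn_kappa: np.ndarray
    beta0: np.ndarray
    beta_z: np.ndarray
    delta: np.ndarray
    zero_mass: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        for name in ("step_mean", "step_sd", "turn_mean", "turn_kappa",
                     "beta0", "beta_z", "delta", "zero_mass"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("step gamma mean/sd must be positive")
        if np.any(self.turn_kappa < 0):
            raise ValueError("von Mises concentration must be >= 0")
        if not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("delta must sum to 1")
        if np.any((self.zero_mass < 0) | (self.zero_mass >= 1)):
            raise ValueError("zero-step mass must lie in [0, 1)")

    def transition_matrix(self, z):
        return transition_matrix(self.beta0, self.beta_z, z)

    def canonical(self) -> tuple["HMMParams", np.ndarray]:
        """Reorder states by ascending step mean; returns (params, perm)."""
        perm = np.argsort(self.step_mean, kind="stable")
        return (
            HMMParams(
                step_mean=self.step_mean[perm],
                step_sd=self.step_sd[perm],
                turn_mean=self.turn_mean[perm],
                turn_kappa=self.turn_kappa[perm],
                beta0=self.beta0[np.ix_(perm, perm)],
                beta_z=self.beta_z[np.ix_(perm, perm)],
                delta=self.delta[perm],
                zero_mass=self.zero_mass[perm],
            ),
            perm,
        )

    def to_dict(self) -> dict:
        return {
            "states": list(STATES),
            "step_mean": self.step_mean.tolist(),
            "step_sd": self.step_sd.tolist(),
            "turn_mean": self.turn_mean.tolist(),
            "turn_kappa": self.turn_kappa.tolist(),
            "beta0": self.beta0.tolist(),
            "beta_z": self.beta_z.tolist(),
            "delta": self.delta.tolist(),
            "zero_mass": self.zero_mass.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        kw = {k: np.asarray(v, dtype=float) for k, v in d.items() if k != "states"}
        return cls(**kw)


def transition_matrix(beta0, beta_z, z):
    """Multinomial-logit transition matrix Gamma(z), diagonal reference.

    ``z`` may be scalar (returns (3, 3)) or length-T (returns (T, 3, 3)).
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta_z = np.asarray(beta_z, dtype=float)
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite covariate value in transition_matrix")
    scalar = z.ndim == 0
    zv = np.atleast_1d(z)
    eta = beta0[None, :, :] + beta_z[None, :, :] * zv[:, None, None]
    for i in range(3):
        eta[:, i, i] = 0.0
    # guard overflow: subtract per-row max before exponentiating
    m = eta.max(axis=2, keepdims=True)
    w = np.exp(eta - m)
    gamma = w / w.sum(axis=2, keepdims=True)
    return gamma[0] if scalar else gamma


def stationary_dist(gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of a stochastic matrix (left unit eigenvector)."""
    gamma = np.asarray(gamma, dtype=float)
    n = gamma.shape[0]
    a = np.vstack([gamma.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi < -1e-8):
        raise ValueError("transition matrix appears reducible/periodic")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# data preparation and emission densities


def _prepare(data: pd.DataFrame, need_z: bool):
    """Split a (track_id, step_km, turn_rad[, zsd]) frame into arrays."""
    if "track_id" in data.columns:
        groups = [g for _, g in data.groupby("track_id", sort=True)]
    else:
        groups = [data]
    steps, turns, zs, starts, ends = [], [], [], [], []
    pos = 0
    for g in groups:
        s = np.asarray(g["step_km"], dtype=float)
        keep = np.isfinite(s)
        s = s[keep]
        if s.size == 0:
            continue
        if np.any(s < 0):
            raise ValueError("negative step length")
        t = np.asarray(g["turn_rad"], dtype=float)[keep]
        steps.append(s)
        turns.append(t)
        if need_z:
            z = np.asarray(g["zsd"], dtype=float)[keep]
            if not np.all(np.isfinite(z)):
                raise ValueError("non-finite Zsd covariate")
            zs.append(z)
        starts.append(pos)
        pos += s.size
        ends.append(pos)
    steps = np.concatenate(steps) if steps else np.empty(0)
    turns = np.concatenate(turns) if turns else np.empty(0)
    z = np.concatenate(zs) if zs else np.zeros_like(steps)
    return steps, turns, z, np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _log_emissions(params: HMMParams, steps: np.ndarray, turns: np.ndarray) -> np.ndarray:
    T = steps.size
    logb = np.zeros((T, 3))
    zero = steps <= 0
    spos = np.where(zero, 1.0, steps)
    has_turn = np.isfinite(turns)
    tv = np.where(has_turn, turns, 0.0)
    for s in range(3):
        mu, sd = params.step_mean[s], params.step_sd[s]
        a = (mu / sd) ** 2
        scale = sd * sd / mu
        g = (a - 1.0) * np.log(spos) - spos / scale - a * np.log(scale) - special.gammaln(a)
        p0 = params.zero_mass[s]
        with np.errstate(divide="ignore"):
            logb[:, s] = np.where(zero,
                                  np.log(p0) if p0 > 0 else g - 1e3,
                                  (np.log1p(-p0) if p0 > 0 else 0.0) + g)
        kappa = params.turn_kappa[s]
        logi0 = kappa + np.log(special.i0e(kappa))
        vm = kappa * np.cos(tv - params.turn_mean[s]) - np.log(2 * np.pi) - logi0
        logb[:, s] += np.where(has_turn, vm, 0.0)
    return logb


def _gamma_stack(params: HMMParams, z: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(transition_matrix(params.beta0, params.beta_z, z))


def hmm_loglik(params: HMMParams, data: pd.DataFrame, formula: str = "zsd") -> float:
    """Forward-algorithm log-likelihood of step/turn series.

    ``data`` columns: ``track_id`` (optional), ``step_km``, ``turn_rad``
    (NaN where missing, e.g. track starts) and ``zsd`` when
    ``formula == "zsd"``.  Transitions use Gamma(z_t) for the move into
    time t.
    """
    need_z = formula == "zsd"
    steps, turns, z, starts, ends = _prepare(data, need_z)
    if steps.size == 0:
        return 0.0
    logb = _log_emissions(params, steps, turns)
    gam = _gamma_stack(params, z if need_z else np.zeros_like(steps))
    return float(forward_loglik(logb, gam, params.delta, starts, ends))


# ---------------------------------------------------------------------------
# working-scale packing


def _pack(params: HMMParams, formula: str, est_zero: bool, z_mean: float, z_sd: float):
    bz_std = params.beta_z * z_sd
    b0_std = params.beta0 + params.beta_z * z_mean
    vec = [np.log(params.step_mean), np.log(params.step_sd),
           params.turn_mean, np.log(np.maximum(params.turn_kappa, 1e-6))]
    vec.append(np.array([b0_std[i, j] for i, j in _OFFDIAG]))
    if formula == "zsd":
        vec.append(np.array([bz_std[i, j] for i, j in _OFFDIAG]))
    d = np.clip(params.delta, 1e-6, None)
    vec.append(np.log(d[1:] / d[0]))
    if est_zero:
        p0 = np.clip(params.zero_mass, 1e-6, 1 - 1e-6)
        vec.append(np.log(p0 / (1 - p0)))
    return np.concatenate(vec)


def _unpack(x: np.ndarray, formula: str, est_zero: bool, z_mean: float, z_sd: float) -> HMMParams:
    i = 0
    mu = np.exp(x[i:i + 3]); i += 3
    sd = np.exp(x[i:i + 3]); i += 3
    tm = np.arctan2(np.sin(x[i:i + 3]), np.cos(x[i:i + 3])); i += 3
    kappa = np.exp(x[i:i + 3]); i += 3
    b0 = np.zeros((3, 3))
    for k, (r, c) in enumerate(_OFFDIAG):
        b0[r, c] = x[i + k]
    i += 6
    bz = np.zeros((3, 3))
    if formula == "zsd":
        for k, (r, c) in enumerate(_OFFDIAG):
            bz[r, c] = x[i + k]
        i += 6
    dl = np.concatenate([[0.0], x[i:i + 2]]); i += 2
    dl -= dl.max()
    delta = np.exp(dl) / np.exp(dl).sum()
    if est_zero:
        p0 = 1.0 / (1.0 + np.exp(-x[i:i + 3])); i += 3
    else:
        p0 = np.zeros(3)
    # back to natural Zsd scale
    bz_nat = bz / z_sd
    b0_nat = b0 - bz_nat * z_mean
    return HMMParams(step_mean=mu, step_sd=sd, turn_mean=tm, turn_kappa=kappa,
                     beta0=b0_nat, beta_z=bz_nat, delta=delta, zero_mass=p0)


@dataclass
class HMMFit:
    """A fitted movement HMM (canonicalized: rest < ars < transit by step mean)."""

    params: HMMParams
    loglik: float
    n_params: int
    formula: str
    converged: bool
    state_probs: np.ndarray
    viterbi_states: np.ndarray
    n_obs: int
    z_mean: float = 0.0
    z_sd: float = 1.0
    working: np.ndarray | None = None
    estimate_zero_mass: bool = False
    n_restarts_used: int = 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def _default_inits(steps: np.ndarray) -> HMMParams:
    """Data-driven starting values from step-length terciles."""
    s = steps[steps > 0]
    q = np.quantile(s, [1 / 3, 2 / 3]) if s.size else np.array([0.1, 1.0])
    bins = [s[s <= q[0]], s[(s > q[0]) & (s <= q[1])], s[s > q[1]]]
    mu = np.array([max(b.mean(), 1e-3) if b.size else 0.1 * 3 ** k for k, b in enumerate(bins)])
    sd = np.array([max(b.std(), 0.5 * m) for b, m in zip(bins, mu)])
    return HMMParams(
        step_mean=mu, step_sd=sd,
        turn_mean=np.zeros(3), turn_kappa=np.array([1.0, 1.0, 1.0]),
        beta0=np.full((3, 3), -2.2), beta_z=np.zeros((3, 3)),
        delta=np.full(3, 1 / 3),
    )


def fit_hmm(
    data: pd.DataFrame,
    formula: str = "zsd",
    inits: HMMParams | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    estimate_zero_mass: bool | None = None,
    maxiter: int = 400,
) -> HMMFit:
    """Maximum-likelihood fit of the 3-state HMM.

    ``formula`` is ``"zsd"`` (transitions depend on Zsd) or ``"null"``
    (intercept-only).  Zsd is standardized internally for optimizer
    conditioning; reported coefficients are on the natural metre scale.
    Best of ``n_restarts`` jittered starts is kept.
    """
    if formula not in ("zsd", "null"):
        raise ValueError("formula must be 'zsd' or 'null'")
    need_z = formula == "zsd"
    steps, turns, z, starts, ends = _prepare(data, need_z)
    if steps.size < 3 or starts.size == 0:
        raise ValueError("need at least one segment with >= 3 observations")
    if estimate_zero_mass is None:
        estimate_zero_mass = bool(np.any(steps == 0))
    z_mean = float(z.mean()) if need_z else 0.0
    z_sd = float(z.std()) if need_z and z.std() > 0 else 1.0
    z_std = (z - z_mean) / z_sd if need_z else np.zeros_like(steps)

    if inits is None:
        inits = _default_inits(steps)
    x0 = _pack(inits, formula, estimate_zero_mass, 0.0, 1.0)  # already std scale

    # emission ingredients precomputed once; the optimizer loop only does
    # cheap vector algebra plus the jitted forward recursion
    zero = steps <= 0
    spos = np.where(zero, 1.0, steps)
    log_spos = np.log(spos)
    has_turn = np.isfinite(turns)
    tv = np.where(has_turn, turns, 0.0)
    cos_t, sin_t = np.cos(tv), np.sin(tv)

    def nll(x):
        p = _unpack(x, formula, estimate_zero_mass, 0.0, 1.0)
        logi0e = np.log(special.i0e(p.turn_kappa))
        v = nll_fast(p.step_mean, p.step_sd, p.zero_mass, p.turn_mean,
                     p.turn_kappa, logi0e, p.beta0, p.beta_z, z_std,
                     log_spos, spos, zero, cos_t, sin_t, has_turn,
                     p.delta, starts, ends)
        if not np.isfinite(v):
            return 1e12
        return v

    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    for r in range(max(1, n_restarts)):
        x_start = x0 if r == 0 else x0 + rng.normal(0, 0.3, size=x0.size)
        res = optimize.minimize(nll, x_start, method="L-BFGS-B",
                                options={"maxiter": maxiter, "maxfun": 40000,
                                         "ftol": 1e-8, "gtol": 1e-4})
        n_used += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("HMM fit failed: no restart converged to finite likelihood")

    params_std = _unpack(best.x, formula, estimate_zero_mass, 0.0, 1.0)
    params = _unpack(best.x, formula, estimate_zero_mass, z_mean, z_sd)
    params, perm = params.canonical()

    logb = _log_emissions(params_std, steps, turns)
    gam = _gamma_stack(params_std, z_std)
    post = forward_backward(logb, gam, params_std.delta, starts, ends)
    vit = viterbi_path(logb, np.log(np.maximum(gam, 1e-300)),
                       np.log(np.maximum(params_std.delta, 1e-300)), starts, ends)
    # relabel decoded states to canonical order
    inv = np.argsort(perm)
    vit = inv[vit]
    post = post[:, perm]

    n_par = 12 + 6 + (6 if need_z else 0) + 2 + (3 if estimate_zero_mass else 0)
    return HMMFit(
        params=params, loglik=-float(best.fun), n_params=n_par, formula=formula,
        converged=bool(best.success), state_probs=post, viterbi_states=vit,
        n_obs=int(steps.size), z_mean=z_mean, z_sd=z_sd, working=best.x,
        estimate_zero_mass=estimate_zero_mass, n_restarts_used=n_used,
    )


def viterbi(params: HMMParams, data: pd.DataFrame, formula: str = "zsd") -> np.ndarray:
    """Most probable state path for new data under fixed parameters."""
    need_z = formula == "zsd"
    steps, turns, z, starts, ends = _prepare(data, need_z)
    logb = _log_emissions(params, steps, turns)
    gam = _gamma_stack(params, z if need_z else np.zeros_like(steps))
    return np.asarray(viterbi_path(logb, np.log(np.maximum(gam, 1e-300)),
                                   np.log(np.maximum(params.delta, 1e-300)),
                                   starts, ends))


def posterior_probs(params: HMMParams, data: pd.DataFrame, formula: str = "zsd") -> np.ndarray:
    need_z = formula == "zsd"
    steps, turns, z, starts, ends = _prepare(data, need_z)
    logb = _log_emissions(params, steps, turns)
    gam = _gamma_stack(params, z if need_z else np.zeros_like(steps))
    return np.asarray(forward_backward(logb, gam, params.delta, starts, ends))


# ---------------------------------------------------------------------------
# curves with uncertainty


def _beta_block_cov(fit: HMMFit, data: pd.DataFrame, step: float = 1e-4) -> tuple[np.ndarray, slice]:
    """Covariance of working parameters via numerical Hessian of the nll."""
    need_z = fit.formula == "zsd"
    steps, turns, z, starts, ends = _prepare(data, need_z)
    z_std = (z - fit.z_mean) / fit.z_sd if need_z else np.zeros_like(steps)

    def nll(x):
        p = _unpack(x, fit.formula, fit.estimate_zero_mass, 0.0, 1.0)
        logb = _log_emissions(p, steps, turns)
        gam = _gamma_stack(p, z_std)
        return -forward_loglik(logb, gam, p.delta, starts, ends)

    x = fit.working
    n = x.size
    h = np.full(n, step)
    hess = np.empty((n, n))
    f0 = nll(x)
    fp = np.array([nll(x + h[i] * _e(n, i)) for i in range(n)])
    fm = np.array([nll(x - h[i] * _e(n, i)) for i in range(n)])
    for i in range(n):
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for j in range(i + 1, n):
            fpp = nll(x + h[i] * _e(n, i) + h[j] * _e(n, j))
            hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    cov = np.linalg.pinv(0.5 * (hess + hess.T))
    beta_sl = slice(12, 24 if fit.formula == "zsd" else 18)
    return cov, beta_sl


def transition_curves(
    fit: HMMFit,
    z_grid: np.ndarray,
    level: float = 0.95,
    data: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Transition and stationary probabilities over a Zsd grid with CIs.

    Confidence intervals use the delta method on the working-scale
    coefficient covariance (numerical Hessian); requires the fitting data
    to recompute that Hessian.  Without ``data``, point estimates only.
    """
    if fit.formula != "zsd":
        raise ValueError("transition_curves requires a Zsd-covariate fit")
    z_grid = np.asarray(z_grid, dtype=float)
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + level / 2.0)
    cov = None
    if data is not None:
        cov_full, beta_sl = _beta_block_cov(fit, data)
        cov = cov_full[beta_sl, beta_sl]

    rows = []
    x_beta0 = fit.params.beta0 + fit.params.beta_z * fit.z_mean  # std-scale intercepts
    x_betaz = fit.params.beta_z * fit.z_sd

    def curves_at(bvec, z):
        b0 = np.zeros((3, 3))
        bz = np.zeros((3, 3))
        for k, (r, c) in enumerate(_OFFDIAG):
            b0[r, c] = bvec[k]
            bz[r, c] = bvec[6 + k]
        zs = (z - fit.z_mean) / fit.z_sd
        gam = transition_matrix(b0, bz, zs)
        pi = stationary_dist(gam)
        return gam, pi

    bhat = np.concatenate([
        np.array([x_beta0[i, j] for i, j in _OFFDIAG]),
        np.array([x_betaz[i, j] for i, j in _OFFDIAG]),
    ])
    eps = 1e-5
    for z in z_grid:
        gam, pi = curves_at(bhat, z)
        if cov is not None:
            # numerical jacobian of (vec Gamma, pi) wrt beta
            jac_g = np.zeros((9, 12))
            jac_p = np.zeros((3, 12))
            for k in range(12):
                gp, pp = curves_at(bhat + eps * _e(12, k), z)
                gm, pm = curves_at(bhat - eps * _e(12, k), z)
                jac_g[:, k] = (gp - gm).ravel() / (2 * eps)
                jac_p[:, k] = (pp - pm) / (2 * eps)
            se_g = np.sqrt(np.maximum(np.einsum("ik,kl,il->i", jac_g, cov, jac_g), 0)).reshape(3, 3)
            se_p = np.sqrt(np.maximum(np.einsum("ik,kl,il->i", jac_p, cov, jac_p), 0))
        for i in range(3):
            for j in range(3):
                lo = hi = np.nan
                if cov is not None:
                    lo = max(0.0, gam[i, j] - zcrit * se_g[i, j])
                    hi = min(1.0, gam[i, j] + zcrit * se_g[i, j])
                rows.append({"zsd": z, "kind": "transition",
                             "from": STATES[i], "to": STATES[j],
                             "estimate": gam[i, j], "lo": lo, "hi": hi})
        for i in range(3):
            lo = hi = np.nan
            if cov is not None:
                lo = max(0.0, pi[i] - zcrit * se_p[i])
                hi = min(1.0, pi[i] + zcrit * se_p[i])
            rows.append({"zsd": z, "kind": "stationary", "from": STATES[i],
                         "to": STATES[i], "estimate": pi[i], "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def _e(n, i):
    v = np.zeros(n)
    v[i] = 1.0
    return v


def bootstrap_transition_curves(
    fit: HMMFit,
    data: pd.DataFrame,
    z_grid: np.ndarray,
    n_boot: int = 50,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Parametric-bootstrap CIs for Gamma_ij(z).

    Simulates step/turn series from the fitted parameters along the
    observed Zsd series, refits (warm-started at the MLE), and takes
    percentile intervals of the transition curves.
    """
    if fit.formula != "zsd":
        raise ValueError("bootstrap curves require a Zsd-covariate fit")
    z_grid = np.asarray(z_grid, dtype=float)
    rng = np.random.default_rng(seed)
    tracks = [np.asarray(g["zsd"], dtype=float)
              for _, g in data.groupby("track_id", sort=True)] \
        if "track_id" in data.columns else [np.asarray(data["zsd"], dtype=float)]
    curves = np.empty((n_boot, z_grid.size, 3, 3))
    for b in range(n_boot):
        frames = []
        for k, z in enumerate(tracks):
            _, steps, turns = simulate_series(fit.params, z, rng)
            frames.append(pd.DataFrame({"track_id": f"t{k:03d}", "step_km": steps,
                                        "turn_rad": turns, "zsd": z}))
        boot = pd.concat(frames, ignore_index=True)
        bfit = fit_hmm(boot, formula="zsd", inits=fit.params, n_restarts=1,
                       seed=seed + b)
        curves[b] = transition_matrix(bfit.params.beta0, bfit.params.beta_z, z_grid)
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    rows = []
    point = transition_matrix(fit.params.beta0, fit.params.beta_z, z_grid)
    for iz, z in enumerate(z_grid):
        for i in range(3):
            for j in range(3):
                rows.append({
                    "zsd": z, "kind": "transition", "from": STATES[i], "to": STATES[j],
                    "estimate": point[iz, i, j],
                    "lo": float(np.percentile(curves[:, iz, i, j], lo_q)),
                    "hi": float(np.percentile(curves[:, iz, i, j], hi_q)),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model comparison / dive classification metrics


def compare_models(fit_a: HMMFit, fit_b: HMMFit,
                   decoded_a: np.ndarray, decoded_b: np.ndarray,
                   dive_presence: np.ndarray) -> dict:
    """AIC comparison plus ARS-as-dive-predictor classification metrics.

    ``dive_presence`` is boolean per fix.  Treating "decoded ARS" as the
    dive prediction: hit rate = P(ARS | dive), miss rate = P(not ARS | dive),
    precision = P(dive | ARS).
    """
    decoded_a = np.asarray(decoded_a)
    decoded_b = np.asarray(decoded_b)
    dive = np.asarray(dive_presence, dtype=bool)
    if not (decoded_a.size == decoded_b.size == dive.size):
        raise ValueError("decoded state and dive-presence lengths differ")

    def metrics(decoded):
        pred = decoded == ARS
        n_dive = dive.sum()
        n_pred = pred.sum()
        hit = float((pred & dive).sum() / n_dive) if n_dive else np.nan
        prec = float((pred & dive).sum() / n_pred) if n_pred else np.nan
        return {"hit_rate": hit,
                "miss_rate": (1.0 - hit) if n_dive else np.nan,
                "precision": prec}

    return {
        "aic_a": fit_a.aic,
        "aic_b": fit_b.aic,
        "delta_aic": fit_a.aic - fit_b.aic,
        "state_agreement": float(np.mean(decoded_a == decoded_b)),
        "metrics_a": metrics(decoded_a),
        "metrics_b": metrics(decoded_b),
    }


# ---------------------------------------------------------------------------
# simulation (shared with the synthetic-data generator)


def simulate_series(params: HMMParams, z: np.ndarray, rng: np.random.Generator):
    """Simulate states, steps and turns along a given Zsd series.

    Returns (states, step_km, turn_rad) arrays of len(z).  The transition
    into time t is Gamma(z_t), matching the likelihood.
    """
    z = np.asarray(z, dtype=float)
    T = z.size
    states = np.empty(T, dtype=np.int64)
    gam = transition_matrix(params.beta0, params.beta_z, z)
    u_state = rng.random(T)
    states[0] = np.searchsorted(np.cumsum(params.delta), u_state[0])
    for t in range(1, T):
        probs = gam[t, states[t - 1]]
        states[t] = np.searchsorted(np.cumsum(probs), u_state[t])
    states = np.clip(states, 0, 2)

    mu = params.step_mean[states]
    sd = params.step_sd[states]
    shape = (mu / sd) ** 2
    scale = sd * sd / mu
    steps = rng.gamma(shape, scale)
    zmask = rng.random(T) < params.zero_mass[states]
    steps = np.where(zmask, 0.0, steps)
    turns = np.empty(T)
    for s in range(3):
        m = states == s
        turns[m] = rng.vonmises(params.turn_mean[s], max(params.turn_kappa[s], 1e-12), size=int(m.sum()))
    turns = np.where(turns <= -np.pi, np.pi, turns)  # convention (-pi, pi]
    turns[0] = np.nan  # no turn at a track start
    return states, steps, turns
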