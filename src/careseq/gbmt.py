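"""Group-based multivariate trajectory model for three binary outcomes.

A finite mixture of K latent groups; within group k, each outcome j
(therapy, counseling, medication) at time t is Bernoulli with

    logit P(y_jt = 1 | group k) = sum_p beta_kjp * z_t^p,

where z_t is the time index standardized to mean 0 and unit range.
Outcomes and time points are conditionally independent given the group;
missing waves contribute nothing to the likelihood (ignorable given group),
which is how unequal sequence lengths are absorbed.  Fitted by EM with
random restarts; model order K is compared by BIC/AIC, subject to the 10%
minimum group-size rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .sequences import SequencePanel, decode_state

__all__ = [
    "GbmtSpec",
    "GbmtFit",
    "panel_to_outcomes",
    "gbmt_loglik",
    "fit_gbmt",
    "select_gbmt",
    "posterior_assign",
]

N_OUTCOMES = 3
RESP_FLOOR = 1e-12
RIDGE = 1e-8


@dataclass
class GbmtSpec:
    """Model order and fitting controls."""

    K: int = 2
    poly_degree: int = 2
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.poly_degree < 0:
            raise ValueError("poly_degree must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class GbmtFit:
    """A fitted mixture: mixing weights, trajectory coefficients, posteriors."""

    spec: GbmtSpec
    pi: np.ndarray  # (K,)
    beta: np.ndarray  # (K, 3, P)
    posteriors: np.ndarray  # (n, K)
    loglik: float
    bic: float
    aic: float
    converged: bool
    n_params: int
    group_sizes: np.ndarray  # modal-assignment counts, (K,)
    n_iter: int = 0
    restarts: int = 0
    ids: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.pi)


def time_design(T: int, degree: int) -> np.ndarray:
    """Polynomial design over T1..TL with time standardized to mean 0, unit range."""
    t = np.arange(1, T + 1, dtype=float)
    z = (t - t.mean()) / (t.max() - t.min()) if T > 1 else np.zeros(T)
    return np.column_stack([z**p for p in range(degree + 1)])


def panel_to_outcomes(panel: SequencePanel) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Decode a panel into (Y, mask, ids): Y is n x T x 3 in {0,1}, NaN-free;
    mask flags observed cells.  State 9 (missing wave) is unobserved."""
    T = panel.max_length
    n = panel.n
    Y = np.zeros((n, T, N_OUTCOMES))
    mask = np.zeros((n, T, N_OUTCOMES), dtype=bool)
    for i, s in enumerate(panel.sequences):
        for t, code in enumerate(s.states):
            triple = decode_state(code)
            if triple[0] is None:
                continue
            Y[i, t, :] = triple
            mask[i, t, :] = True
    return Y, mask, panel.ids


def _as_arrays(panel) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(panel, SequencePanel):
        return panel_to_outcomes(panel)
    Y, mask = panel  # (Y, mask) pair
    Y = np.asarray(Y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    return Y, mask, [str(i) for i in range(Y.shape[0])]


def _loglik_matrix(Y: np.ndarray, mask: np.ndarray, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-individual, per-group conditional log-likelihood, n x K."""
    eta = np.einsum("tp,kjp->ktj", X, beta)  # (K, T, 3)
    # stable log(sigmoid) / log(1-sigmoid)
    logp1 = -np.logaddexp(0.0, -eta)
    logp0 = -np.logaddexp(0.0, eta)
    Ym = np.where(mask, Y, 0.0)
    Cm = np.where(mask, 1.0 - Y, 0.0)
    return np.einsum("itj,ktj->ik", Ym, logp1) + np.einsum("itj,ktj->ik", Cm, logp0)


def gbmt_loglik(panel, pi: Sequence[float], beta: np.ndarray, poly_degree: Optional[int] = None) -> float:
    """Observed-data log-likelihood of the mixture at (pi, beta)."""
    Y, mask, _ = _as_arrays(panel)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be a probability distribution")
    beta = np.asarray(beta, dtype=float)
    P = beta.shape[-1]
    if poly_degree is not None and poly_degree + 1 != P:
        raise ValueError("beta incompatible with poly_degree")
    X = time_design(Y.shape[1], P - 1)
    ll = _loglik_matrix(Y, mask, beta, X)
    with np.errstate(divide="ignore"):
        return float(np.sum(logsumexp(ll + np.log(pi + RESP_FLOOR), axis=1)))


def _wlogit(A: np.ndarray, y: np.ndarray, w: np.ndarray, beta0: np.ndarray) -> np.ndarray:
    """Weighted logistic regression by damped Newton ascent (tiny ridge).

    Step-halving guarantees the penalized objective never decreases, which
    keeps the surrounding EM a monotone generalized EM.
    """
    beta = beta0.copy()
    P = A.shape[1]

    def objective(b: np.ndarray) -> float:
        eta = A @ b
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))) - 0.5 * RIDGE * b @ b)

    obj = objective(beta)
    for _ in range(30):
        eta = A @ beta
        mu = expit(eta)
        grad = A.T @ (w * (y - mu)) - RIDGE * beta
        if np.max(np.abs(grad)) < 1e-9:
            break
        Wd = w * mu * (1.0 - mu) + 1e-12
        H = (A * Wd[:, None]).T @ A + RIDGE * np.eye(P)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _h in range(25):
            cand = beta + t * step
            cobj = objective(cand)
            if cobj >= obj:
                beta, obj = cand, cobj
                break
            t *= 0.5
        else:
            break
    return beta


def _m_step(Y, mask, resp, X, beta_prev):
    n, T, J = Y.shape
    K = resp.shape[1]
    P = X.shape[1]
    pi = resp.mean(axis=0)
    beta = np.empty((K, J, P))
    for j in range(J):
        obs = mask[:, :, j]
        rows_i, rows_t = np.nonzero(obs)
        A = X[rows_t]
        y = Y[rows_i, rows_t, j]
        for k in range(K):
            w = resp[rows_i, k]
            beta[k, j] = _wlogit(A, y, w, beta_prev[k, j])
    return pi, beta


def _em_once(Y, mask, spec: GbmtSpec, rng: np.random.Generator):
    n = Y.shape[0]
    K = spec.K
    X = time_design(Y.shape[1], spec.poly_degree)
    resp = rng.dirichlet(np.ones(K), size=n)
    beta = np.zeros((K, N_OUTCOMES, spec.poly_degree + 1))
    pi, beta = _m_step(Y, mask, resp, X, beta)
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    for it in range(spec.max_iter):
        ll_ik = _loglik_matrix(Y, mask, beta, X)
        log_w = ll_ik + np.log(pi + RESP_FLOOR)
        ll = float(np.sum(logsumexp(log_w, axis=1)))
        trace.append(ll)
        if ll < prev_ll - 1e-6:  # monotonicity guard (float tolerance); should not trigger
            warnings.warn(f"EM log-likelihood decreased at iteration {it}", stacklevel=2)
        resp = np.exp(log_w - logsumexp(log_w, axis=1, keepdims=True))
        # floor for numerical safety only; no renormalization, which would
        # perturb the exact E-step and break EM monotonicity
        np.maximum(resp, RESP_FLOOR, out=resp)
        if np.any(resp.mean(axis=0) < 1.0 / n):
            return None, trace  # degenerate empty group -> caller restarts
        if ll - prev_ll < spec.tol and it > 0:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        pi, beta = _m_step(Y, mask, resp, X, beta)
    return (pi, beta, resp, prev_ll, converged, len(trace)), trace


def _n_params(K: int, poly_degree: int) -> int:
    return (K - 1) + K * N_OUTCOMES * (poly_degree + 1)


def fit_gbmt(panel, spec: GbmtSpec) -> GbmtFit:
    """Fit the K-group mixture by EM with random restarts.

    The best of ``spec.n_starts`` converged starts (by log-likelihood) is
    returned; groups are reported sorted by decreasing mixing weight.
    Starts that collapse a group below 1/n responsibility mass are redrawn
    (counted in ``fit.restarts``).
    """
    spec.validate()
    Y, mask, ids = _as_arrays(panel)
    n = Y.shape[0]
    if n < spec.K:
        raise ValueError("need at least K individuals")
    X = time_design(Y.shape[1], spec.poly_degree)

    if spec.K == 1:
        resp = np.ones((n, 1))
        beta = np.zeros((1, N_OUTCOMES, spec.poly_degree + 1))
        pi, beta = _m_step(Y, mask, resp, X, beta)
        ll = gbmt_loglik((Y, mask), pi, beta)
        return _make_fit(spec, np.array([1.0]), beta, resp, ll, True, n, ids, 1, 0, [ll])

    best = None
    best_trace: list[float] = []
    restarts = 0
    ss = np.random.SeedSequence([int(spec.seed), spec.K, 0x67626D])
    streams = ss.spawn(spec.n_starts * 4)
    s_idx = 0
    completed = 0
    while completed < spec.n_starts and s_idx < len(streams):
        rng = np.random.default_rng(streams[s_idx])
        s_idx += 1
        result, trace = _em_once(Y, mask, spec, rng)
        if result is None:
            restarts += 1
            continue
        completed += 1
        pi, beta, resp, ll, conv, iters = result
        if best is None or ll > best[3]:
            best = (pi, beta, resp, ll, conv, iters)
            best_trace = trace
    if best is None:
        raise RuntimeError("all EM starts collapsed to an empty group")
    pi, beta, resp, ll, conv, iters = best
    if not conv:
        warnings.warn("EM did not converge within max_iter in the best start", stacklevel=2)
    # sort groups by decreasing mixing weight for stable reporting
    order = np.argsort(-pi, kind="stable")
    return _make_fit(spec, pi[order], beta[order], resp[:, order], ll, conv, n, ids, iters, restarts, best_trace)


def _make_fit(spec, pi, beta, resp, ll, conv, n, ids, iters, restarts, trace) -> GbmtFit:
    p = _n_params(len(pi), spec.poly_degree)
    modal = np.argmax(resp, axis=1)
    sizes = np.bincount(modal, minlength=len(pi))
    return GbmtFit(
        spec=spec,
        pi=np.asarray(pi, dtype=float),
        beta=np.asarray(beta, dtype=float),
        posteriors=np.asarray(resp, dtype=float),
        loglik=float(ll),
        bic=float(-2.0 * ll + p * np.log(n)),
        aic=float(-2.0 * ll + 2.0 * p),
        converged=bool(conv),
        n_params=p,
        group_sizes=sizes,
        n_iter=int(iters),
        restarts=int(restarts),
        ids=list(ids),
        loglik_trace=list(trace),
    )


def posterior_assign(fit: GbmtFit) -> dict[str, int]:
    """Modal posterior assignment, 1-based; ties break toward the smaller group."""
    modal = np.argmax(fit.posteriors, axis=1) + 1
    return {i: int(g) for i, g in zip(fit.ids, modal)}


def select_gbmt(
    panel,
    K_range: Sequence[int],
    spec: Optional[GbmtSpec] = None,
    min_prop: float = 0.10,
) -> tuple[Optional[GbmtFit], pd.DataFrame, dict[int, GbmtFit]]:
    """Fit every K in ``K_range``; choose the admissible fit with lowest BIC.

    A fit is admissible iff its smallest modal-assignment group holds at
    least ``ceil(min_prop * n)`` individuals.  Returns (chosen fit or None,
    comparison table, all fits).  AIC disagreement with the BIC choice is
    flagged in the table.
    """
    if not len(K_range):
        raise ValueError("K_range must be nonempty")
    base = spec or GbmtSpec()
    Y, mask, ids = _as_arrays(panel)
    n = Y.shape[0]
    floor = ceil(min_prop * n)
    fits: dict[int, GbmtFit] = {}
    rows = []
    for K in sorted(K_range):
        s = GbmtSpec(K=K, poly_degree=base.poly_degree, n_starts=base.n_starts,
                     max_iter=base.max_iter, tol=base.tol, seed=base.seed)
        fit = fit_gbmt((Y, mask), s)
        fit.ids = list(ids)
        fits[K] = fit
        rows.append(
            dict(K=K, loglik=fit.loglik, n_params=fit.n_params, bic=fit.bic, aic=fit.aic,
                 min_group_pct=100.0 * fit.group_sizes.min() / n,
                 admissible=bool(fit.group_sizes.min() >= floor))
        )
    table = pd.DataFrame(rows)
    admissible = table[table["admissible"]]
    if admissible.empty:
        warnings.warn("no admissible GBMT model in the examined K range", stacklevel=2)
        table["selected"] = False
        return None, table, fits
    k_bic = int(admissible.loc[admissible["bic"].idxmin(), "K"])
    k_aic = int(admissible.loc[admissible["aic"].idxmin(), "K"])
    table["selected"] = table["K"] == k_bic
    table.attrs["aic_agrees"] = k_aic == k_bic
    if k_aic != k_bic:
        warnings.warn(f"AIC prefers K={k_aic} while BIC selects K={k_bic}", stacklevel=2)
    return fits[k_bic], table, fits
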