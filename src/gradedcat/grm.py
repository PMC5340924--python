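"""Samejima's graded response model: probabilities, information, calibration.

The GRM for a three-category item links the latent trait theta to the
cumulative ("boundary") probabilities

    P*_k(theta) = 1 / (1 + exp(-alpha (theta - beta_k))),   k = 1, 2,

so the category probabilities are adjacent differences
p0 = 1 - P*_1, p1 = P*_1 - P*_2, p2 = P*_2. The logistic metric is used as
is, without the 1.7 normal-ogive scaling constant: discriminations such as
alpha = 7.377 are logistic slopes.

Calibration is marginal maximum likelihood via EM with a fixed quadrature
grid over a standard-normal population distribution. The M-step improves the
expected complete-data log-likelihood item by item (a generalized EM step),
which keeps the marginal log-likelihood monotone across iterations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .bank import GrmItem, ItemBank
from .responses import ResponseMatrix

__all__ = [
    "boundary_prob",
    "category_probs",
    "item_information",
    "test_information",
    "se_from_information",
    "fit_grm_mml",
    "GrmFitResult",
    "GrmConvergenceError",
    "crc_table",
    "detect_crc_anomaly",
]

# optimizer box constraints; wide enough for extreme slopes like alpha=7.4
ALPHA_BOUNDS = (0.05, 50.0)
BETA_BOUNDS = (-10.0, 10.0)
LOG_SPACING_BOUNDS = (np.log(1e-3), np.log(20.0))
_PCLIP = 1e-10


# ---------------------------------------------------------------------------
# model probabilities
# ---------------------------------------------------------------------------

def boundary_prob(item: GrmItem, k: int, theta):
    """Boundary probability P(X >= k | theta), k in {1, 2}.

    Strictly increasing in theta; equals 0.5 at theta = beta_k.
    """
    if k not in (1, 2):
        raise ValueError(f"boundary index k must be 1 or 2, got {k!r}")
    beta = item.beta1 if k == 1 else item.beta2
    return expit(item.alpha * (np.asarray(theta, dtype=float) - beta))


def category_probs(item: GrmItem, theta):
    """Category probabilities (p0, p1, p2) at theta.

    Sums to one; all entries nonnegative because beta1 < beta2.
    """
    s1 = boundary_prob(item, 1, theta)
    s2 = boundary_prob(item, 2, theta)
    return 1.0 - s1, s1 - s2, s2


def _probs_grid(alphas: np.ndarray, b1: np.ndarray, b2: np.ndarray,
                theta: np.ndarray) -> np.ndarray:
    """(J, Q, 3) category probabilities for J items on a Q-point grid."""
    t = theta[None, :]
    s1 = expit(alphas[:, None] * (t - b1[:, None]))
    s2 = expit(alphas[:, None] * (t - b2[:, None]))
    return np.stack([1.0 - s1, s1 - s2, s2], axis=-1)


def item_information(item: GrmItem, theta):
    """Fisher information of the 3-category response at theta.

    I(theta) = sum_k (dp_k/dtheta)^2 / p_k, with boundary derivatives
    dP*_k/dtheta = alpha P*_k (1 - P*_k). Nonnegative everywhere.
    """
    s1 = boundary_prob(item, 1, theta)
    s2 = boundary_prob(item, 2, theta)
    d1 = item.alpha * s1 * (1.0 - s1)
    d2 = item.alpha * s2 * (1.0 - s2)
    p = np.stack([1.0 - s1, s1 - s2, s2], axis=-1)
    dp = np.stack([-d1, d1 - d2, d2], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > _PCLIP, dp * dp / np.clip(p, _PCLIP, None), 0.0)
    return terms.sum(axis=-1)


def test_information(items, theta):
    """Sum of item informations over a bank subset (additivity of Fisher
    information under local independence)."""
    items = list(items)
    if not items:
        raise ValueError("test information requires a nonempty item subset")
    return sum(item_information(it, theta) for it in items)


def se_from_information(info):
    """Standard error of theta: 1/sqrt(information); infinite at zero."""
    info = np.asarray(info, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(info > 0, 1.0 / np.sqrt(np.clip(info, 1e-300, None)),
                        np.inf)


# ---------------------------------------------------------------------------
# marginal maximum likelihood (EM)
# ---------------------------------------------------------------------------

class GrmConvergenceError(RuntimeError):
    """EM failed to reach the parameter-change tolerance.

    Carries the iteration trace (marginal log-likelihood per iteration) in
    ``loglik_trace`` and the last parameter table in ``last_params``.
    """

    def __init__(self, msg, loglik_trace, last_params):
        super().__init__(msg)
        self.loglik_trace = loglik_trace
        self.last_params = last_params


@dataclasses.dataclass
class GrmFitResult:
    """Calibrated bank plus diagnostics.

    ``diagnostics`` has one row per item: standard errors of alpha/beta1/
    beta2 (block-wise observed-information approximation), a ``collapsed``
    flag for items calibrated with fewer than three observed categories, and
    the CRC anomaly flag.
    """

    bank: ItemBank
    diagnostics: pd.DataFrame
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


def quadrature(quad_points: int = 61, span: float = 4.5):
    """Fixed grid on [-span, span] with weights proportional to the standard
    normal density (normalized)."""
    grid = np.linspace(-span, span, quad_points)
    w = np.exp(-0.5 * grid**2)
    return grid, w / w.sum()


def _mstep_objective(x, r, grid, collapsed_top):
    """Negative expected complete-data log-lik for one item, with gradient.

    x = (alpha, beta1, log spacing); r is the (Q, 3) expected count table.
    ``collapsed_top`` fits a 2-category item: only the first threshold is
    free and categories are {0, 1}.
    """
    a, b1, logd = x
    b2 = b1 + np.exp(logd)
    s1 = expit(a * (grid - b1))
    ds1 = s1 * (1.0 - s1)
    if collapsed_top:
        p = np.stack([1.0 - s1, s1], axis=-1)
        p = np.clip(p, _PCLIP, None)
        f = -(r[:, :2] * np.log(p)).sum()
        # d f / d s1 then chain to (a, b1)
        g_s1 = -(-r[:, 0] / p[:, 0] + r[:, 1] / p[:, 1])
        ga = (g_s1 * ds1 * (grid - b1)).sum()
        gb1 = (g_s1 * ds1 * (-a)).sum()
        return f, np.array([ga, gb1, 0.0])
    s2 = expit(a * (grid - b2))
    ds2 = s2 * (1.0 - s2)
    p = np.stack([1.0 - s1, s1 - s2, s2], axis=-1)
    p = np.clip(p, _PCLIP, None)
    f = -(r * np.log(p)).sum()
    g_s1 = -(-r[:, 0] / p[:, 0] + r[:, 1] / p[:, 1])
    g_s2 = -(-r[:, 1] / p[:, 1] + r[:, 2] / p[:, 2])
    ga = (g_s1 * ds1 * (grid - b1) + g_s2 * ds2 * (grid - b2)).sum()
    gb = -a * (g_s1 * ds1 + g_s2 * ds2).sum()        # shared beta1 shift
    gd = (g_s2 * ds2 * (-a)).sum() * np.exp(logd)    # spacing only moves b2
    return f, np.array([ga, gb, gd])


def _item_logprob_cols(params_row, grid, collapsed_top):
    a, b1, b2 = params_row
    s1 = expit(a * (grid - b1))
    if collapsed_top:
        p = np.stack([1.0 - s1, s1, np.full_like(s1, _PCLIP)], axis=-1)
    else:
        s2 = expit(a * (grid - b2))
        p = np.stack([1.0 - s1, s1 - s2, s2], axis=-1)
    return np.log(np.clip(p, _PCLIP, None))


def fit_grm_mml(
    rm: ResponseMatrix,
    scale: str,
    quad_points: int = 61,
    max_iter: int = 500,
    tol: float = 1e-5,
    compute_se: bool = True,
) -> GrmFitResult:
    """Calibrate one scale's items by marginal ML (EM over a fixed grid).

    The population distribution is standard normal, discretized on
    ``quad_points`` equally spaced nodes over [-4.5, 4.5] weighted by the
    normal density. Convergence is declared when the maximum absolute
    parameter change falls below ``tol``; otherwise a
    :class:`GrmConvergenceError` carrying the log-likelihood trace is
    raised. Items never observed in their top category are calibrated as
    two-category items and flagged ``collapsed`` (their beta2 is a
    placeholder far above beta1).
    """
    X = rm.values_for(scale)          # (n, J) complete-case int codes
    item_ids = rm.items_in(scale)
    n, J = X.shape
    if J < 2:
        raise ValueError("calibration needs at least 2 items")
    grid, w = quadrature(quad_points)
    logw = np.log(w)

    # degenerate-category screen: single observed category is uncalibratable
    collapsed = np.zeros(J, dtype=bool)
    for j in range(J):
        cats = np.unique(X[:, j])
        if cats.size < 2:
            raise ValueError(
                f"item {item_ids[j]!r} shows a single observed category; "
                "it cannot be calibrated"
            )
        if 2 not in cats:
            collapsed[j] = True
        elif 1 not in cats:
            # middle category unobserved: keep 3-category fit; the EM drives
            # the spacing to its lower bound, and the item is flagged
            collapsed[j] = False

    # indicators per category, used by both E-step and expected counts
    Y = [(X == k).astype(float) for k in range(3)]   # each (n, J)

    # starting values from marginal endorsement rates at alpha = 1
    params = np.zeros((J, 3))
    for j in range(J):
        p_ge1 = np.clip(np.mean(X[:, j] >= 1), 1e-3, 1 - 1e-3)
        p_ge2 = np.clip(np.mean(X[:, j] >= 2), 1e-3, 1 - 1e-3)
        b1 = float(-np.log(p_ge1 / (1 - p_ge1)))
        b2 = float(-np.log(p_ge2 / (1 - p_ge2)))
        if b2 <= b1 + 0.05:
            b2 = b1 + 0.05
        params[j] = (1.0, b1, b2)

    bounds = [ALPHA_BOUNDS, BETA_BOUNDS, LOG_SPACING_BOUNDS]
    loglik_trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior over grid nodes per person
        logP = np.stack(
            [_item_logprob_cols(params[j], grid, collapsed[j]) for j in range(J)]
        )                                              # (J, Q, 3)
        logL = sum(Y[k] @ logP[:, :, k] for k in range(3))  # (n, Q)
        joint = logL + logw[None, :]
        ll = logsumexp(joint, axis=1)
        loglik_trace.append(ll.sum())
        post = np.exp(joint - ll[:, None])             # (n, Q)

        # expected counts r[j, q, k]
        r = np.stack([post.T @ Y[k] for k in range(3)], axis=-1)  # (Q, J, 3)

        # M-step: a few bounded quasi-Newton steps per item (generalized EM)
        new = params.copy()
        for j in range(J):
            a, b1, b2 = params[j]
            x0 = np.array([a, b1, np.log(max(b2 - b1, 1.1e-3))])
            res = minimize(
                _mstep_objective, x0, args=(r[:, j, :], grid, collapsed[j]),
                jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 10},
            )
            a, b1, logd = res.x
            new[j] = (a, b1, b1 + np.exp(logd))
        delta = np.max(np.abs(new - params))
        params = new
        if delta < tol:
            converged = True
            break

    if not converged:
        raise GrmConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last max parameter change {delta:.3g})",
            np.asarray(loglik_trace),
            pd.DataFrame(params, index=item_ids,
                         columns=["alpha", "beta1", "beta2"]),
        )

    # collapsed items get a placeholder top threshold far beyond the grid
    out_params = params.copy()
    for j in range(J):
        if collapsed[j]:
            out_params[j, 2] = out_params[j, 1] + 20.0 / max(out_params[j, 0], 1.0)

    ses = np.full((J, 3), np.nan)
    if compute_se:
        logP = np.stack(
            [_item_logprob_cols(params[j], grid, collapsed[j]) for j in range(J)]
        )
        logL = sum(Y[k] @ logP[:, :, k] for k in range(3))
        for j in range(J):
            ses[j] = _item_se(params[j], X[:, j], logL - sum(
                Y[k][:, [j]] * logP[j, :, k][None, :] for k in range(3)
            ), grid, logw, collapsed[j])

    bank = ItemBank(
        GrmItem(item_ids[j], scale, out_params[j, 0], out_params[j, 1],
                out_params[j, 2])
        for j in range(J)
    )
    anomalies = [detect_crc_anomaly(it) for it in bank]
    diagnostics = pd.DataFrame(
        {
            "item_id": item_ids,
            "se_alpha": ses[:, 0],
            "se_beta1": ses[:, 1],
            "se_beta2": ses[:, 2],
            "collapsed": collapsed,
            "crc_anomaly": anomalies,
        }
    ).set_index("item_id")
    return GrmFitResult(bank, diagnostics, np.asarray(loglik_trace), it,
                        converged)


def _item_se(params_row, x_j, log_others, grid, logw, collapsed_top):
    """Block observed-information SEs for one item's (alpha, beta1, beta2).

    The marginal log-likelihood is profiled with the other items' parameters
    held fixed; a central-difference 3x3 Hessian is inverted. A placeholder
    NaN is returned when the block is not positive definite (typical for
    near-boundary or collapsed items).
    """

    def nll(p):
        logPj = _item_logprob_cols(p, grid, collapsed_top)
        contrib = logPj[:, x_j].T                     # (n, Q)
        return -logsumexp(log_others + contrib + logw[None, :], axis=1).sum()

    p0 = np.asarray(params_row, dtype=float)
    k = 2 if collapsed_top else 3
    h = 1e-4 * np.maximum(1.0, np.abs(p0))
    H = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            pa, pb = np.zeros(3), np.zeros(3)
            pa[a], pb[b] = h[a], h[b]
            f_pp = nll(p0 + pa + pb)
            f_pm = nll(p0 + pa - pb)
            f_mp = nll(p0 - pa + pb)
            f_mm = nll(p0 - pa - pb)
            H[a, b] = H[b, a] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[a] * h[b])
    out = np.full(3, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            out[:k] = np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    return out


# ---------------------------------------------------------------------------
# category response curves
# ---------------------------------------------------------------------------

def default_theta_grid(step: float = 0.05, span: float = 4.5) -> np.ndarray:
    return np.arange(-span, span + step / 2, step)


def crc_table(item: GrmItem, theta_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Category response curves on a grid: columns p0, p1, p2, rows theta.

    The grid must be sorted, contain at least 3 points and span [-4, 4].
    """
    grid = _check_grid(theta_grid)
    p0, p1, p2 = category_probs(item, grid)
    return pd.DataFrame({"theta": grid, "p0": p0, "p1": p1, "p2": p2})


def detect_crc_anomaly(item: GrmItem, theta_grid: np.ndarray | None = None) -> bool:
    """True when the middle category is modal at no grid point.

    Items whose two thresholds nearly coincide never have "sometimes" as the
    most likely answer, the CRC pathology flagged during model inspection.
    """
    grid = _check_grid(theta_grid)
    p = np.stack(category_probs(item, grid), axis=-1)
    return bool(np.all(p.argmax(axis=-1) != 1))


def _check_grid(theta_grid):
    if theta_grid is None:
        return default_theta_grid()
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("theta grid must be sorted with at least 3 points")
    if grid[0] > -4.0 or grid[-1] < 4.0:
        raise ValueError("theta grid must span at least [-4, 4]")
    return grid
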