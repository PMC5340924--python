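"""Differential item functioning via nested ordinal logistic regressions.

For each item and grouping covariate, three cumulative-logit models are fit
by maximum likelihood:

    M1: response ~ theta
    M2: response ~ theta + group
    M3: response ~ theta + group + theta x group

Uniform DIF shows up as the McFadden pseudo-R-squared gain of M2 over M1,
non-uniform DIF as the gain of M3 over M2. An item is flagged when either
gain reaches 0.03 AND the corresponding likelihood-ratio test is significant
at p < .01 — a "significant and relevant" two-part rule that avoids flagging
trivial but significant effects in large samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .bank import ItemBank
from .responses import ResponseMatrix

__all__ = ["DIFResult", "ordinal_dif", "dif_screen", "R2_CRITERION",
           "P_CRITERION"]

log = logging.getLogger(__name__)

R2_CRITERION = 0.03   # pseudo-R2 change below this indicates no DIF
P_CRITERION = 0.01    # likelihood-ratio significance required alongside
MIN_GROUP = 20


@dataclass
class DIFResult:
    """DIF screen outcome for one item x covariate."""

    item_id: str
    covariate: str
    r2_uniform: float      # McFadden pseudo-R2 change, M2 - M1
    r2_nonuniform: float   # M3 - M2
    lr_p_uniform: float
    lr_p_nonuniform: float
    flagged: bool
    error: str | None = None


def _fit_ordered(y, X, start_params=None):
    """Cumulative-logit ML fit; returns the maximized log-likelihood and the
    fitted parameter vector (for warm-starting the next nested model)."""
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    model = OrderedModel(y, X, distr="logit")
    kwargs = {"method": "bfgs", "maxiter": 1000, "disp": False,
              "gtol": 1e-9}
    if start_params is not None:
        kwargs["start_params"] = start_params
    with warnings.catch_warnings():
        # near the optimum the BFGS gradient tolerance is stricter than the
        # likelihood differences we consume; the warm starts below bound the
        # nesting error regardless
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(**kwargs)
    return float(res.llf), np.asarray(res.params)


def ordinal_dif(item_responses, theta, group,
                item_id: str = "item", covariate: str = "group") -> DIFResult:
    """DIF screen for a single item.

    Nested models are warm-started from the previous fit (the new
    coefficient at zero), which guarantees the likelihood never decreases
    along the nesting and keeps the pseudo-R-squared changes nonnegative.
    """
    y = np.asarray(item_responses, dtype=int)
    theta = np.asarray(theta, dtype=float)
    group = np.asarray(group, dtype=int)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be coded 0/1")
    n0, n1 = int((group == 0).sum()), int((group == 1).sum())
    if min(n0, n1) < MIN_GROUP:
        raise ValueError(
            f"both groups need >= {MIN_GROUP} persons, got {n0} and {n1}"
        )

    # null (thresholds-only) log-likelihood has the closed multinomial form
    _, counts = np.unique(y, return_counts=True)
    n = y.size
    ll0 = float((counts * np.log(counts / n)).sum())

    y_cat = pd.Series(pd.Categorical(y, ordered=True))
    X1 = pd.DataFrame({"theta": theta})
    X2 = X1.assign(group=group.astype(float))
    X3 = X2.assign(interaction=theta * group)
    try:
        ll1, p1 = _fit_ordered(y_cat, X1)
        ll2, p2 = _fit_ordered(y_cat, X2,
                               start_params=np.insert(p1, 1, 0.0))
        ll3, _ = _fit_ordered(y_cat, X3,
                              start_params=np.insert(p2, 2, 0.0))
    except Exception as exc:  # separation / non-convergence
        return DIFResult(item_id, covariate, np.nan, np.nan, np.nan, np.nan,
                         False, error=f"{type(exc).__name__}: {exc}")
    # enforce exact nesting against optimizer jitter
    ll2 = max(ll2, ll1)
    ll3 = max(ll3, ll2)
    r2_u = (ll2 - ll1) / (-ll0)
    r2_n = (ll3 - ll2) / (-ll0)
    p_u = float(chi2.sf(2.0 * (ll2 - ll1), df=1))
    p_n = float(chi2.sf(2.0 * (ll3 - ll2), df=1))
    flagged = bool((r2_u >= R2_CRITERION and p_u < P_CRITERION)
                   or (r2_n >= R2_CRITERION and p_n < P_CRITERION))
    return DIFResult(item_id, covariate, float(r2_u), float(r2_n), p_u, p_n,
                     flagged)


def dif_screen(rm: ResponseMatrix, bank: ItemBank,
               covariates: pd.DataFrame | None = None) -> list[DIFResult]:
    """Screen every item against every grouping covariate.

    ``covariates`` needs a binary ``sex`` column; an ``age`` column, if
    present, is dichotomized at the sample median. The conditioning trait is
    the EAP estimate under the calibrated bank using all items of the item's
    scale. Per-item failures are carried in the result, never abort the
    screen.
    """
    from .cat import eap  # local import to avoid a cycle

    if covariates is None:
        covariates = rm.covariates
    if covariates is None or "sex" not in covariates.columns:
        raise ValueError("DIF screening requires a 'sex' covariate")
    covariates = covariates.loc[rm.codes.index]
    groups = {"sex": covariates["sex"].to_numpy().astype(int)}
    if "age" in covariates.columns:
        age = covariates["age"].to_numpy(dtype=float)
        groups["age"] = (age > np.median(age)).astype(int)

    results: list[DIFResult] = []
    theta_cache: dict[str, np.ndarray] = {}
    for scale in rm.scales:
        if scale not in theta_cache:
            sub = bank.subset(scale)
            X = rm.values_for(scale)
            theta_cache[scale] = np.array(
                [eap(sub, row).theta for row in X]
            )
        theta = theta_cache[scale]
        for iid in rm.items_in(scale):
            y = rm.codes[iid].to_numpy().astype(int)
            for cov_name, grp in groups.items():
                try:
                    results.append(
                        ordinal_dif(y, theta, grp, item_id=iid,
                                    covariate=cov_name)
                    )
                except ValueError as exc:
                    results.append(
                        DIFResult(iid, cov_name, np.nan, np.nan, np.nan,
                                  np.nan, False, error=str(exc))
                    )
                    log.warning("DIF screen failed for %s x %s: %s", iid,
                                cov_name, exc)
    return results


def dif_table(results: list[DIFResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": [r.item_id for r in results],
            "covariate": [r.covariate for r in results],
            "r2_uniform": [r.r2_uniform for r in results],
            "r2_nonuniform": [r.r2_nonuniform for r in results],
            "lr_p_uniform": [r.lr_p_uniform for r in results],
            "lr_p_nonuniform": [r.lr_p_nonuniform for r in results],
            "flagged": [r.flagged for r in results],
            "error": [r.error or "" for r in results],
        }
    )
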