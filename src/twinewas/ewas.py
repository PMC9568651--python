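"""Per-probe conditional logistic regression for 1:1 matched twin pairs.

For a matched pair the conditional likelihood of the case/control labels,
conditioning on one case per pair, depends only on the within-pair
difference of covariates d = x_case - x_control:

    l(b) = sum over pairs of -log(1 + exp(-d' b))

i.e. the likelihood of an intercept-free logistic regression on the
difference rows with the outcome fixed at 1. The methylation M-value is the
exposure of interest; plate indicators and cell-type proportions enter as
additional difference columns. Pair-constant covariates (sex, shared
gestational variables) difference to zero and are dropped automatically.

The maximizer is found by Newton-Raphson with step-halving, run batched
across probes: the covariate difference block is shared, so the Hessian has
a rank-structured layout that vectorizes cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr, genomic_inflation  # noqa: F401  (re-exported API)
from .pairwise import _pair_members, delta_beta

logger = logging.getLogger("twinewas")

#: |coefficient| on the M-value scale beyond which the likelihood is treated
#: as monotone (quasi-separation); Wald inference is meaningless there.
SEPARATION_BOUND = 15.0
MAX_ITER = 50
SCORE_TOL = 1e-8

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_SEPARATED = "separated"
STATUS_NOT_CONVERGED = "not_converged"


@dataclass
class CovariateSpec:
    """Which sample-sheet and deconvolution columns enter the model.

    ``plate`` is one-hot encoded (first level as reference); cell-type
    proportions enter as differences of all types except ``cell_reference``
    to avoid the sum-to-one collinearity. ``chip`` is omitted by default as
    it is nested within plate in the block-randomized design.
    """

    sheet_columns: tuple = ("plate",)
    cell_types: tuple | None = None  # None = all except the reference type
    cell_reference: str = "Gran"
    extra_columns: tuple = ()


def build_design(
    mvals: pd.DataFrame,
    sheet: pd.DataFrame,
    props: pd.DataFrame | None = None,
    spec: CovariateSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build within-pair difference rows for the conditional likelihood.

    Returns ``(dm, cov)`` where ``dm`` is the probes x pairs matrix of
    M-value differences (case minus control) and ``cov`` is the pairs x q
    matrix of shared covariate differences. Covariate columns whose
    differences are identically zero (pair-constant, e.g. sex) are dropped
    with a logged note.
    """
    spec = spec or CovariateSpec()
    pairs = _pair_members(sheet)
    dm = delta_beta(mvals, sheet)  # same case-minus-control arithmetic on M

    blocks = []
    sheet_ix = sheet.set_index("subject_id")
    for col in spec.sheet_columns:
        series = sheet_ix[col]
        if series.dtype == object or str(series.dtype) == "category":
            onehot = pd.get_dummies(series, prefix=col, dtype=float)
            onehot = onehot.iloc[:, 1:]  # first level is the reference
        else:
            onehot = series.to_frame().astype(float)
        blocks.append(onehot)
    if props is not None:
        cells = [c for c in props.columns if c != "residual"]
        use = list(spec.cell_types) if spec.cell_types is not None else [
            c for c in cells if c != spec.cell_reference
        ]
        blocks.append(props[use])
    for col in spec.extra_columns:
        blocks.append(sheet_ix[[col]].astype(float))

    if blocks:
        X = pd.concat(blocks, axis=1)
        cov = pd.DataFrame(
            X.loc[pairs["case"]].to_numpy() - X.loc[pairs["control"]].to_numpy(),
            index=pairs["pair_id"],
            columns=X.columns,
        )
        constant = cov.columns[(cov == 0).all(axis=0)]
        if len(constant):
            logger.info(
                "dropping pair-constant covariates from conditional model: %s",
                list(constant),
            )
            cov = cov.drop(columns=constant)
    else:
        cov = pd.DataFrame(index=pairs["pair_id"])
    return dm, cov


def _conditional_loglik(b: np.ndarray, X: np.ndarray) -> float:
    """Explicit 1:1 conditional log-likelihood at coefficient vector b."""
    eta = X @ b
    return float(-np.logaddexp(0.0, -eta).sum())


def fit_single(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, str, int]:
    """Newton-Raphson fit of one probe's conditional likelihood.

    ``X`` is the n_pairs x p matrix of difference rows (methylation first).
    Returns (coef, se, status, n_iter). Kept as a scalar reference path; the
    batched fitter below is the production route.
    """
    n, p = X.shape
    if not np.any(X[:, 0]):
        return np.full(p, np.nan), np.full(p, np.nan), STATUS_DEGENERATE, 0
    b = np.zeros(p)
    ll = _conditional_loglik(b, X)
    for it in range(1, MAX_ITER + 1):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (1.0 - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return np.full(p, np.nan), np.full(p, np.nan), STATUS_SEPARATED, it
        # step-halving keeps the likelihood monotone
        for _ in range(30):
            cand = b + step
            ll_new = _conditional_loglik(cand, X)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        b, ll = cand, ll_new
        if abs(b[0]) > SEPARATION_BOUND:
            return b, np.full(p, np.nan), STATUS_SEPARATED, it
    else:
        return b, np.full(p, np.nan), STATUS_NOT_CONVERGED, MAX_ITER
    eta = X @ b
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    cov = np.linalg.inv(H)
    return b, np.sqrt(np.diag(cov)), STATUS_OK, it


def _batched_newton(
    D: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Newton-Raphson over all probes simultaneously.

    D is probes x pairs (methylation differences), C is pairs x q (shared
    covariate differences). Returns (coefs, ses, status codes) where the
    first coefficient column is the methylation term.
    """
    J, n = D.shape
    q = C.shape[1]
    p = 1 + q
    b = np.zeros((J, p))
    status = np.full(J, STATUS_OK, dtype=object)
    degenerate = ~np.any(D != 0.0, axis=1)
    status[degenerate] = STATUS_DEGENERATE
    active = ~degenerate
    converged = np.zeros(J, dtype=bool)

    def loglik(bm):
        eta = D * bm[:, :1] + bm[:, 1:] @ C.T
        return -np.logaddexp(0.0, -eta).sum(axis=1)

    ll = loglik(b)
    for _ in range(MAX_ITER):
        idx = np.flatnonzero(active & ~converged)
        if idx.size == 0:
            break
        eta = D[idx] * b[idx, :1] + b[idx, 1:] @ C.T
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = 1.0 - mu
        score = np.empty((idx.size, p))
        score[:, 0] = (r * D[idx]).sum(axis=1)
        score[:, 1:] = r @ C
        done = np.max(np.abs(score), axis=1) < SCORE_TOL
        converged[idx[done]] = True
        idx = idx[~done]
        if idx.size == 0:
            continue
        eta = eta[~done]
        mu = mu[~done]
        w = mu * (1.0 - mu)
        H = np.empty((idx.size, p, p))
        wD = w * D[idx]
        H[:, 0, 0] = (wD * D[idx]).sum(axis=1)
        H[:, 0, 1:] = wD @ C
        H[:, 1:, 0] = H[:, 0, 1:]
        H[:, 1:, 1:] = np.einsum("jn,nq,nr->jqr", w, C, C)
        # tiny ridge keeps near-separated Hessians solvable; such probes are
        # flagged by the coefficient bound below, not reported
        H[:, np.arange(p), np.arange(p)] += 1e-10
        step = np.linalg.solve(H, score[~done][..., None])[..., 0]
        cand = b[idx] + step
        ll_new = (
            -np.logaddexp(0.0, -(D[idx] * cand[:, :1] + cand[:, 1:] @ C.T))
        ).sum(axis=1)
        for _ in range(30):
            worse = ll_new < ll[idx] - 1e-12
            if not worse.any():
                break
            step[worse] /= 2.0
            cand[worse] = b[idx[worse]] + step[worse]
            ll_new[worse] = (
                -np.logaddexp(
                    0.0,
                    -(D[idx[worse]] * cand[worse][:, :1]
                      + cand[worse][:, 1:] @ C.T),
                )
            ).sum(axis=1)
        b[idx] = cand
        ll[idx] = ll_new
        sep = np.abs(b[idx, 0]) > SEPARATION_BOUND
        if sep.any():
            status[idx[sep]] = STATUS_SEPARATED
            active[idx[sep]] = False

    not_conv = active & ~converged
    status[not_conv] = STATUS_NOT_CONVERGED

    ses = np.full((J, p), np.nan)
    ok = status == STATUS_OK
    idx = np.flatnonzero(ok)
    if idx.size:
        eta = D[idx] * b[idx, :1] + b[idx, 1:] @ C.T
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = np.empty((idx.size, p, p))
        wD = w * D[idx]
        H[:, 0, 0] = (wD * D[idx]).sum(axis=1)
        H[:, 0, 1:] = wD @ C
        H[:, 1:, 0] = H[:, 0, 1:]
        H[:, 1:, 1:] = np.einsum("jn,nq,nr->jqr", w, C, C)
        H[:, np.arange(p), np.arange(p)] += 1e-10
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
        ses[idx] = np.sqrt(
            np.clip(cov[:, np.arange(p), np.arange(p)], 0.0, None)
        )
        bad = ~np.isfinite(ses[idx, 0]) | (ses[idx, 0] == 0)
        if bad.any():
            status[idx[bad]] = STATUS_NOT_CONVERGED
    b[status == STATUS_DEGENERATE] = np.nan
    return b, ses, status


def fit_conditional_logistic(
    dm: pd.DataFrame, cov: pd.DataFrame
) -> pd.DataFrame:
    """Fit the per-probe conditional logistic model for every probe.

    Returns a DataFrame indexed by probe with columns coef, se, z, p and
    status. Probes whose methylation differences are all zero are flagged
    ``degenerate``; monotone likelihoods beyond the coefficient bound are
    flagged ``separated``; both carry missing p-values.
    """
    D = dm.to_numpy(dtype=float)
    C = cov.to_numpy(dtype=float)
    if D.shape[1] < 2:
        raise ValueError("need at least 2 pairs")
    if 1 + C.shape[1] >= D.shape[1]:
        raise ValueError(
            f"conditional model with {1 + C.shape[1]} parameters cannot be "
            f"fit on {D.shape[1]} pairs; reduce covariates or add pairs"
        )
    coefs, ses, status = _batched_newton(D, C)
    coef = coefs[:, 0]
    se = ses[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    okmask = status == STATUS_OK
    pvals = np.where(okmask, pvals, np.nan)
    return pd.DataFrame(
        {
            "coef": np.where(status == STATUS_DEGENERATE, np.nan, coef),
            "se": se,
            "z": np.where(okmask, z, np.nan),
            "p": pvals,
            "status": status,
        },
        index=dm.index,
    )


def run_ewas(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    props: pd.DataFrame | None = None,
    spec: CovariateSpec | None = None,
    mvals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-probe EWAS: M-transform, conditional fit, FDR, summaries.

    FDR is computed over probes with status ``ok`` only; other probes carry
    missing q. Mean beta and mean within-pair delta-beta are reported on the
    beta scale for interpretability.
    """
    from .ingest import beta_to_m

    if mvals is None:
        mvals = beta_to_m(beta)
    dm, cov = build_design(mvals, sheet, props, spec)
    result = fit_conditional_logistic(dm, cov)
    result["q"] = bh_fdr(result["p"].to_numpy())
    result["mean_beta"] = beta.mean(axis=1)
    db = delta_beta(beta, sheet)
    result["mean_delta_beta"] = db.mean(axis=1)
    n_ok = int((result["status"] == STATUS_OK).sum())
    n_sig = int((result["q"] < 0.05).sum())
    lam = genomic_inflation(result["p"].to_numpy()) if n_ok >= 100 else float("nan")
    logger.info(
        "EWAS: %d/%d probes fit ok, %d significant at FDR<0.05, lambda=%.3f",
        n_ok, len(result), n_sig, lam,
    )
    result.attrs["lambda"] = lam
    return result
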