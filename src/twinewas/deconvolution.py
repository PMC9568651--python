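"""Reference-based cell-type deconvolution.

Nucleated-cell proportions (B, CD4T, CD8T, Mono, Gran, NK, nRBC in cord
blood) are estimated per subject by constrained projection: the subject's
beta values at deconvolution-informative probes are projected onto the
reference profiles of purified cell types under non-negativity and a
sum-at-most-one constraint. The unexplained fraction is reported as a
residual rather than rescaled away, since it is diagnostic of reference
mismatch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._stats import bh_fdr, wilcoxon_signed_rank
from .pairwise import _pair_members

logger = logging.getLogger("twinewas")

# weight of the penalty row enforcing sum(p) = 1 on the active-set pass
_SUM_PENALTY = 1e6


def _project_simplex(R: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimize ||y - R p|| subject to p >= 0 and sum(p) <= 1.

    Plain non-negative least squares is tried first; if the solution
    violates the sum constraint, the equality-constrained problem
    (sum(p) = 1) is solved by augmenting the system with a heavily weighted
    penalty row, which NNLS treats as an active constraint.
    """
    p, _ = nnls(R, y)
    if p.sum() > 1.0 + 1e-8:
        scale = _SUM_PENALTY * max(np.abs(R).max(), 1.0)
        R_aug = np.vstack([R, scale * np.ones((1, R.shape[1]))])
        y_aug = np.append(y, scale)
        p, _ = nnls(R_aug, y_aug)
        p = np.clip(p / max(p.sum(), 1.0), 0.0, None)
    resid = float(np.linalg.norm(y - R @ p))
    return p, resid


def estimate_proportions(beta: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type proportions for every subject.

    Parameters
    ----------
    beta : probes x subjects beta matrix.
    ref : informative probes x cell types reference beta matrix.

    Returns a subjects x cell-types DataFrame with an extra ``residual``
    column holding the per-subject residual norm of the projection.
    """
    shared = ref.index.intersection(beta.index)
    n_types = ref.shape[1]
    if len(shared) < n_types:
        raise ValueError(
            f"need at least {n_types} shared informative probes, got {len(shared)}"
        )
    R_full = ref.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R_full) < n_types:
        # name the collinear columns for the error message
        _, s, vt = np.linalg.svd(R_full)
        bad = ref.columns[np.abs(vt[-1]) > 0.3].tolist()
        raise ValueError(f"reference matrix is rank deficient; collinear cell "
                         f"types include {bad}")
    B = beta.loc[shared]
    rows = []
    for subject in beta.columns:
        y = B[subject].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < n_types:
            raise ValueError(f"subject {subject!r} has too few observed "
                             "informative probes")
        p, resid = _project_simplex(R_full[ok], y[ok])
        rows.append(np.append(p, resid))
    out = pd.DataFrame(
        rows, index=beta.columns, columns=list(ref.columns) + ["residual"]
    )
    return out


def compare_proportions_paired(
    props: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Paired Wilcoxon comparison of cell proportions between cases and
    controls, one test per cell type, FDR-corrected across cell types."""
    pairs = _pair_members(sheet)
    cell_types = [c for c in props.columns if c != "residual"]
    rows = []
    for ct in cell_types:
        d = (
            props.loc[pairs["case"], ct].to_numpy()
            - props.loc[pairs["control"], ct].to_numpy()
        )
        nz = np.count_nonzero(d)
        p = wilcoxon_signed_rank(d)
        rows.append(
            {
                "cell_type": ct,
                "n_pairs": len(pairs),
                "n_nonzero": int(nz),
                "median_difference": float(np.median(d)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
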