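"""Reading and quality control of methylation-array inputs.

The pipeline starts from a normalized beta-value matrix (probes x subjects),
a twin sample sheet, a probe manifest and optionally a detection-p matrix.
This module aligns those inputs, applies detection-p masking, the
missingness filter, k-nearest-neighbour imputation, and the beta <-> M-value
transforms used by the regression stage.

Filter order is probes before subjects: probe-level failures dominate
missingness on arrays, and removing them first prevents a handful of bad
probes from ejecting otherwise clean subjects. The order is fixed and
reported so downstream counts are auditable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("twinewas")

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
REFGENE_GROUPS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "ExonBnd", "3UTR")
REG_FEATURES = ("Promoter", "Gene", "NonGene", "Unclassified")


class PairError(ValueError):
    """A twin pair violates the 1 case + 1 control, same-sex contract."""


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate the twin sample sheet.

    Every pair must contain exactly one case and one control of the same
    sex. Returns the sheet indexed by subject_id.
    """
    required = {"subject_id", "pair_id", "role", "sex", "plate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["subject_id"].duplicated().any():
        dupes = sheet.loc[sheet["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    for pair_id, grp in sheet.groupby("pair_id"):
        roles = sorted(grp["role"])
        if roles != ["case", "control"]:
            raise PairError(
                f"pair {pair_id!r} must have exactly one case and one control, "
                f"got roles {roles}"
            )
        if grp["sex"].nunique() != 1:
            raise PairError(f"pair {pair_id!r} has mismatched sexes")
    return sheet.set_index("subject_id", drop=False)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x subjects TSV matrix (header row of subject ids)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        raise ValueError("duplicate probe ids in matrix")
    if mat.columns.duplicated().any():
        raise ValueError("duplicate subject ids in matrix")
    return mat.astype(float)


def read_manifest(path) -> pd.DataFrame:
    """Read the probe manifest CSV (probe_id, chrom, pos, annotations)."""
    man = pd.read_csv(path, dtype={"chrom": str})
    if man["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in manifest")
    man["refgene_groups"] = man["refgene_groups"].fillna("")
    return man.set_index("probe_id", drop=False)


def read_inputs(
    beta_path, sheet_path, manifest_path, detp_path=None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and axis-align the standard inputs.

    Subjects are restricted to the intersection of the sample sheet and the
    beta matrix; dropped subjects are logged. Probes are restricted to the
    intersection of the matrix and the manifest.
    """
    beta = read_beta_matrix(beta_path)
    sheet = validate_sample_sheet(pd.read_csv(sheet_path, dtype={"plate": str}))
    manifest = read_manifest(manifest_path)

    shared_subjects = [s for s in beta.columns if s in sheet.index]
    dropped = sorted(set(beta.columns) ^ set(sheet.index))
    if dropped:
        logger.warning(
            "dropping %d subjects absent from sheet/matrix intersection: %s",
            len(dropped), dropped,
        )
    # keep only complete pairs after the intersection
    sheet = sheet.loc[shared_subjects]
    complete = sheet.groupby("pair_id")["role"].transform("size") == 2
    if (~complete).any():
        logger.warning(
            "dropping incomplete pairs: %s",
            sorted(sheet.loc[~complete, "pair_id"].unique()),
        )
        sheet = sheet.loc[complete]
    beta = beta[sheet.index.tolist()]

    shared_probes = beta.index.intersection(manifest.index)
    if len(shared_probes) < len(beta.index):
        logger.warning(
            "dropping %d probes absent from manifest", len(beta.index) - len(shared_probes)
        )
    beta = beta.loc[shared_probes]
    manifest = manifest.loc[shared_probes]

    detp = None
    if detp_path is not None:
        detp = pd.read_csv(detp_path, sep="\t", index_col=0).astype(float)
        detp = detp.reindex(index=beta.index, columns=beta.columns)
    return beta, sheet, manifest, detp


def apply_detection_mask(
    beta: pd.DataFrame, detp: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Mask beta entries whose detection p-value exceeds ``threshold``.

    The inequality is strict: an entry with detection p exactly at the
    threshold is retained.
    """
    if beta.shape != detp.shape:
        raise ValueError(f"shape mismatch: beta {beta.shape} vs detp {detp.shape}")
    detp = detp.reindex(index=beta.index, columns=beta.columns)
    masked = beta.mask(detp > threshold)
    n = int((detp > threshold).sum().sum())
    if n:
        logger.info("detection mask: %d entries masked at p > %g", n, threshold)
    return masked


def filter_missingness(
    beta: pd.DataFrame, max_frac: float = 0.05
) -> tuple[pd.DataFrame, list, list]:
    """Remove probes, then subjects, with missing fraction above ``max_frac``.

    Probes are filtered first; subject missingness is then recomputed on the
    retained probes and filtered by the same strict-inequality rule. Returns
    the filtered matrix and the lists of removed probe and subject ids.
    """
    probe_frac = beta.isna().mean(axis=1)
    removed_probes = beta.index[probe_frac > max_frac].tolist()
    out = beta.drop(index=removed_probes)
    subj_frac = out.isna().mean(axis=0)
    removed_subjects = out.columns[subj_frac > max_frac].tolist()
    out = out.drop(columns=removed_subjects)
    if out.empty:
        raise ValueError("missingness filter removed the entire matrix")
    logger.info(
        "missingness filter (> %.0f%%): removed %d probes, %d subjects",
        100 * max_frac, len(removed_probes), len(removed_subjects),
    )
    return out, removed_probes, removed_subjects


def impute_knn(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing betas from the k nearest probes.

    Distance between probes is the root-mean-square difference over subjects
    observed in both rows. A missing entry for subject S is the mean of the
    values at S of the k nearest probes that are observed at S, clipped to
    [0, 1]. A probe with no usable neighbour falls back to its own row mean.
    """
    vals = beta.to_numpy(dtype=float, copy=True)
    missing_rows = np.flatnonzero(np.isnan(vals).any(axis=1))
    if missing_rows.size == 0:
        return beta.copy()
    obs = ~np.isnan(vals)
    filled = vals.copy()
    for i in missing_rows:
        xi, oi = vals[i], obs[i]
        common = obs & oi  # per-row mask of subjects shared with probe i
        n_common = common.sum(axis=1)
        with np.errstate(invalid="ignore"):
            sq = np.where(common, (vals - xi) ** 2, 0.0).sum(axis=1)
            dist = np.sqrt(sq / np.maximum(n_common, 1))
        dist[i] = np.inf
        dist[n_common == 0] = np.inf
        for j in np.flatnonzero(~oi):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if cand.size == 0:
                row_mean = np.nanmean(xi)
                logger.warning(
                    "probe %s has no imputation neighbour for subject %s; "
                    "using row mean", beta.index[i], beta.columns[j],
                )
                filled[i, j] = row_mean
                continue
            nearest = cand[np.argsort(dist[cand], kind="mergesort")[:k]]
            filled[i, j] = float(np.clip(vals[nearest, j].mean(), 0.0, 1.0))
    return pd.DataFrame(filled, index=beta.index, columns=beta.columns)


def beta_to_m(beta: pd.DataFrame, eps: float = 1e-6) -> pd.DataFrame:
    """M-value transform, M = log2(beta / (1 - beta)).

    Betas are clipped to [eps, 1 - eps] so boundary values map to finite M;
    missing entries propagate.
    """
    clipped = beta.clip(lower=eps, upper=1 - eps)
    return np.log2(clipped / (1 - clipped))


def m_to_beta(mvals: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` away from the clipping bounds."""
    x = np.power(2.0, mvals)
    return x / (1 + x)


def flag_failed_pairs(
    sheet: pd.DataFrame,
    detp: pd.DataFrame | None,
    abs_threshold: float = 0.01,
    mad_multiplier: float = 3.0,
) -> pd.DataFrame:
    """Flag pairs with an elevated mean detection p-value in either member.

    A subject fails if its mean detection p exceeds ``abs_threshold`` or
    exceeds the cohort median by ``mad_multiplier`` median absolute
    deviations; the whole pair is then flagged (column ``qc_fail``) and
    excluded from analysis sets downstream.
    """
    out = sheet.copy()
    if detp is None:
        logger.warning("no detection-p matrix; pair QC skipped")
        out["qc_fail"] = False
        return out
    means = detp.mean(axis=0).reindex(out["subject_id"])
    out["mean_detection_p"] = means.to_numpy()
    med = means.median()
    mad = (means - med).abs().median()
    bad_subject = (means > abs_threshold) | (means > med + mad_multiplier * mad)
    bad_pairs = set(out.loc[bad_subject.to_numpy(), "pair_id"])
    out["qc_fail"] = out["pair_id"].isin(bad_pairs)
    if bad_pairs:
        logger.info("flagged pairs failing detection-p QC: %s", sorted(bad_pairs))
    return out
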