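"""Within-pair methylation statistics.

Delta-beta (case beta minus control beta) per probe per twin pair, the
recurrent-variability screen, per-pair correlation QC and the global
methylation-content comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import wilcoxon_signed_rank

logger = logging.getLogger("twinewas")


def _pair_members(sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-pair table with case and control subject ids, ordered by pair."""
    rows = []
    for pair_id, grp in sheet.groupby("pair_id", sort=True):
        roles = grp.set_index("role")["subject_id"]
        if not {"case", "control"} <= set(roles.index):
            raise ValueError(f"pair {pair_id!r} is missing a member")
        rows.append((pair_id, roles["case"], roles["control"]))
    return pd.DataFrame(rows, columns=["pair_id", "case", "control"])


def delta_beta(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Probes x pairs matrix of case-minus-control beta differences.

    Missing in either member propagates to a missing delta.
    """
    pairs = _pair_members(sheet)
    missing = [s for s in pairs[["case", "control"]].to_numpy().ravel()
               if s not in beta.columns]
    if missing:
        raise ValueError(f"subjects absent from beta matrix: {missing}")
    case = beta[pairs["case"].tolist()].to_numpy()
    ctrl = beta[pairs["control"].tolist()].to_numpy()
    return pd.DataFrame(case - ctrl, index=beta.index,
                        columns=pairs["pair_id"].tolist())


def recurrent_variable_probes(
    delta: pd.DataFrame, threshold: float = 0.15, min_pairs: int = 2
) -> pd.DataFrame:
    """Screen for probes whose within-pair difference recurs across pairs.

    A probe exceeds in a pair when |delta beta| >= threshold (the inclusive
    reading; the strict count is reported alongside). The recurrent set is
    probes exceeding in at least ``min_pairs`` pairs. Returns a per-probe
    report with exceedance counts, the recurrent flag, and the exceeding
    pair ids.
    """
    absd = delta.abs()
    hits = absd >= threshold
    n_exceed = hits.sum(axis=1)
    n_exceed_strict = (absd > threshold).sum(axis=1)
    pair_lists = [
        ";".join(delta.columns[row].astype(str)) for row in hits.to_numpy()
    ]
    report = pd.DataFrame(
        {
            "n_exceed": n_exceed,
            "n_exceed_strict": n_exceed_strict,
            "recurrent": n_exceed >= min_pairs,
            "pairs": pair_lists,
        },
        index=delta.index,
    )
    logger.info(
        "recurrence screen: %d probes exceed |delta beta| >= %g in >= %d pairs",
        int(report["recurrent"].sum()), threshold, min_pairs,
    )
    return report


def recurrent_genes(report: pd.DataFrame, manifest: pd.DataFrame) -> pd.Series:
    """Count recurrent probes per gene symbol.

    Probes annotated to multiple genes count once per gene, mirroring the
    manifest's multi-annotation convention.
    """
    if "genes" not in manifest.columns:
        raise ValueError("manifest has no 'genes' column")
    rec = report.index[report["recurrent"]]
    genes: dict[str, int] = {}
    for probe in rec:
        anno = manifest.at[probe, "genes"]
        if not isinstance(anno, str) or not anno:
            continue
        for g in set(anno.split(";")):
            genes[g] = genes.get(g, 0) + 1
    return pd.Series(genes, dtype=int).sort_values(ascending=False)


def pair_correlation(
    beta: pd.DataFrame, sheet: pd.DataFrame, method: str = "spearman"
) -> pd.Series:
    """Per-pair correlation between case and control beta vectors."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    pairs = _pair_members(sheet)
    out = {}
    for _, row in pairs.iterrows():
        x = beta[row["case"]].to_numpy()
        y = beta[row["control"]].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"pair {row['pair_id']!r} has fewer than 3 shared probes")
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            logger.warning("constant beta vector in pair %r", row["pair_id"])
            out[row["pair_id"]] = np.nan
            continue
        if method == "spearman":
            r = stats.spearmanr(x[ok], y[ok]).statistic
        else:
            r = stats.pearsonr(x[ok], y[ok]).statistic
        out[row["pair_id"]] = float(r)
    return pd.Series(out, name=f"{method}_r")


def global_content(
    beta: pd.DataFrame, sheet: pd.DataFrame, stat: str = "median"
) -> tuple[pd.Series, dict]:
    """Global methylation content per subject and its paired comparison.

    Content is the per-subject median beta over all probes (mean available
    as an option). The case-versus-control comparison is a two-sided paired
    Wilcoxon signed-rank test across pairs.
    """
    if stat == "median":
        content = beta.median(axis=0)
    elif stat == "mean":
        content = beta.mean(axis=0)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    content.name = f"global_{stat}_beta"
    pairs = _pair_members(sheet)
    diffs = (
        content[pairs["case"].tolist()].to_numpy()
        - content[pairs["control"].tolist()].to_numpy()
    )
    test = {
        "n_pairs": len(pairs),
        "median_case": float(content[pairs["case"].tolist()].median()),
        "median_control": float(content[pairs["control"].tolist()].median()),
        "median_difference": float(np.median(diffs)),
        "p": wilcoxon_signed_rank(diffs),
    }
    return content, test
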