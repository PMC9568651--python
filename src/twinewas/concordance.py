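"""Cross-platform concordance of methylation measurements.

Array beta values are compared against an orthogonal per-site assay —
methylation-specific droplet digital PCR, whose readout is the fractional
abundance of methylated droplets — by Pearson correlation and by testing
whether within-pair effect directions agree more often than chance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import binom_two_sided


def load_orthogonal(path) -> pd.DataFrame:
    """Read orthogonal measurements (subject_id, target, droplet counts).

    Fractional abundance is methylated / (methylated + unmethylated)
    droplet counts; replicate wells for the same subject and target are
    summed before the ratio.
    """
    df = pd.read_csv(path)
    agg = df.groupby(["subject_id", "target"], as_index=False)[
        ["positive_methylated", "positive_unmethylated"]
    ].sum()
    total = agg["positive_methylated"] + agg["positive_unmethylated"]
    if (total <= 0).any():
        raise ValueError("target with no positive droplets")
    agg["fractional_abundance"] = agg["positive_methylated"] / total
    return agg


def correlate_methods(
    array_beta: pd.DataFrame, ortho: pd.DataFrame
) -> tuple[dict, pd.DataFrame]:
    """Pearson correlation between array betas and fractional abundance.

    Returns the pooled result over all (subject, target) observations and a
    per-target table. Requires at least 3 paired observations; a constant
    vector yields a missing correlation.
    """
    obs = ortho.copy()
    obs["beta"] = [
        array_beta.at[t, s] if t in array_beta.index and s in array_beta.columns
        else np.nan
        for s, t in zip(obs["subject_id"], obs["target"])
    ]
    obs = obs.dropna(subset=["beta", "fractional_abundance"])
    if len(obs) < 3:
        raise ValueError("need at least 3 paired observations")

    def _pearson(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan, np.nan
        r = stats.pearsonr(x, y)
        return float(r.statistic), float(r.pvalue)

    pooled_r, pooled_p = _pearson(
        obs["beta"].to_numpy(), obs["fractional_abundance"].to_numpy()
    )
    rows = []
    for target, grp in obs.groupby("target"):
        if len(grp) < 3:
            rows.append({"target": target, "n": len(grp),
                         "r": np.nan, "p": np.nan})
            continue
        r, p = _pearson(grp["beta"].to_numpy(),
                        grp["fractional_abundance"].to_numpy())
        rows.append({"target": target, "n": len(grp), "r": r, "p": p})
    pooled = {"n": len(obs), "r": pooled_r, "p": pooled_p}
    return pooled, pd.DataFrame(rows)


def direction_concordance(delta_array, delta_ortho) -> tuple[int, int, float]:
    """Agreement of within-pair effect directions between the two methods.

    Concordance is strict sign agreement; observations where either method
    gives a zero delta are excluded. Returns (k concordant, n compared,
    two-sided exact binomial p against 0.5).
    """
    a = np.asarray(delta_array, dtype=float)
    o = np.asarray(delta_ortho, dtype=float)
    if a.shape != o.shape:
        raise ValueError("delta vectors must align")
    ok = np.isfinite(a) & np.isfinite(o) & (a != 0) & (o != 0)
    n = int(ok.sum())
    if n == 0:
        return 0, 0, float("nan")
    k = int((np.sign(a[ok]) == np.sign(o[ok])).sum())
    return k, n, binom_two_sided(k, n)
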