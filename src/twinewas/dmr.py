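"""Differentially methylated region detection from per-probe p-values.

Neighbouring CpG probes carry correlated signals, so regional evidence is
aggregated with a Stouffer-Liptak combination weighted by the empirical
autocorrelation of probit-transformed p-values as a function of genomic
distance. Candidate regions are seeded at probes whose corrected p-value
falls below a seeding threshold and extended along the chromosome while
inter-probe gaps stay small; each region's combined p-value is then adjusted
for the effective number of regions of its width by a Sidak correction.

Throughout, the one-sided probit convention z = Phi^-1(1 - p) is used, so
large z corresponds to small p; effect direction is carried separately by
the regression coefficient signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("twinewas")

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass
class DmrParams:
    """Tunable region-calling parameters (base pairs and p-value scales)."""

    window: int = 750       # neighbourhood half-width for the correction
    dist: int = 750         # maximum gap when extending a region
    seed_p: float = 0.0001  # corrected-p threshold seeding a region
    bin_size: int = 50      # autocorrelation distance-bin width
    max_dist: int = 750     # largest distance with estimated correlation
    sidak_alpha: float = 0.05
    min_pairs_per_bin: int = 10
    # search-space convention for the Sidak exponent: "covered" counts the
    # bases covered by assayed CpG sites (the region-caller tool
    # convention); "span" uses the summed per-chromosome genomic span of
    # analyzed probes (far more conservative on sparse designs)
    sidak_total: str = "covered"


def _p_to_z(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _P_FLOOR, _P_CEIL))


def estimate_acf(
    positions: pd.DataFrame,
    pvalues: np.ndarray,
    max_dist: int = 750,
    bin_size: int = 50,
    min_pairs_per_bin: int = 10,
) -> pd.DataFrame:
    """Estimate the distance-binned autocorrelation of probit p-values.

    ``positions`` must have columns ``chrom`` and ``pos`` sorted by position
    within chromosome. For each half-open distance bin [lo, lo + bin_size)
    starting at 1 bp, the Pearson correlation of z-pairs over all probe
    pairs at that distance is computed, pooled across chromosomes. Distance
    zero is anchored at correlation 1 by definition. Bins with fewer than
    ``min_pairs_per_bin`` pairs fall back to 0 with a warning.
    """
    z = _p_to_z(np.asarray(pvalues, dtype=float))
    lows = np.arange(1, max_dist + 1, bin_size)
    pair_d, pair_a, pair_b = [], [], []
    for _, grp in positions.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("positions must be sorted within chromosome")
        zz = z[positions.index.get_indexer(grp.index)]
        k = 1
        while True:
            if k >= len(pos):
                break
            d = pos[k:] - pos[:-k]
            mask = d <= max_dist
            if not mask.any():
                break
            pair_d.append(d[mask])
            pair_a.append(zz[:-k][mask])
            pair_b.append(zz[k:][mask])
            k += 1
    rows = []
    if pair_d:
        d = np.concatenate(pair_d)
        a = np.concatenate(pair_a)
        b = np.concatenate(pair_b)
    else:
        d = a = b = np.empty(0)
    for lo in lows:
        hi = lo + bin_size
        m = (d >= lo) & (d < hi)
        n = int(m.sum())
        if n < min_pairs_per_bin:
            logger.warning(
                "acf bin [%d, %d) has %d pairs (<%d); correlation set to 0",
                lo, hi, n, min_pairs_per_bin,
            )
            corr = 0.0
        else:
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(a[m], b[m])[0, 1])
            if not np.isfinite(corr):
                corr = 0.0
        rows.append({"lo": int(lo), "hi": int(hi), "n_pairs": n, "corr": corr})
    return pd.DataFrame(rows)


def _sigma_lookup(acf: pd.DataFrame):
    """Distance -> correlation function from the binned table (0 bp -> 1)."""
    lows = acf["lo"].to_numpy()
    his = acf["hi"].to_numpy()
    corrs = np.clip(acf["corr"].to_numpy(), -1.0, 1.0)

    def sigma(dist: np.ndarray) -> np.ndarray:
        dist = np.asarray(dist)
        out = np.zeros(dist.shape, dtype=float)
        out[dist == 0] = 1.0
        ix = np.searchsorted(lows, dist, side="right") - 1
        inside = (ix >= 0) & (dist > 0)
        valid = inside & (dist < np.where(inside, his[np.clip(ix, 0, None)], 0))
        out[valid] = corrs[ix[valid]]
        return out

    return sigma


def _combine(z: np.ndarray, dists: np.ndarray, sigma) -> float:
    """Stouffer-Liptak combined z for member z-scores at pairwise distances."""
    k = z.size
    if k == 1:
        return float(z[0])
    var = k + 2.0 * float(sigma(dists).sum())
    if var <= 0:
        logger.warning("non-positive combined variance; falling back to "
                       "independence")
        var = float(k)
    return float(z.sum() / np.sqrt(var))


def slk_correct(
    pvalues: np.ndarray,
    positions: pd.DataFrame,
    acf: pd.DataFrame,
    window: int = 750,
) -> np.ndarray:
    """Spatially corrected p-value per probe.

    Each probe's p-value is replaced by the Stouffer-Liptak combination of
    the probit scores of all probes within ``window`` bp on the same
    chromosome, with the pairwise correlation taken from the binned
    autocorrelation table. Isolated probes keep their original p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    z = _p_to_z(p)
    sigma = _sigma_lookup(acf)
    out = np.empty_like(p)
    for _, grp in positions.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        gidx = positions.index.get_indexer(grp.index)
        left = np.searchsorted(pos, pos - window, side="left")
        right = np.searchsorted(pos, pos + window, side="right")
        for i in range(len(pos)):
            lo, hi = left[i], right[i]
            if hi - lo == 1:
                out[gidx[i]] = p[gidx[i]]
                continue
            members = np.arange(lo, hi)
            zz = z[gidx[members]]
            pp = pos[members]
            ii, jj = np.triu_indices(len(members), k=1)
            zc = _combine(zz, pp[jj] - pp[ii], sigma)
            out[gidx[i]] = float(stats.norm.sf(zc))
    return out


def find_regions(
    corrected_p: np.ndarray,
    positions: pd.DataFrame,
    seed_p: float = 0.01,
    dist: int = 750,
) -> list[list[int]]:
    """Cluster sub-threshold probes into candidate regions.

    Probes with corrected p below ``seed_p`` are grouped along each
    chromosome while consecutive sub-threshold probes are at most ``dist``
    bp apart. Clusters with fewer than two probes are discarded. Returns
    lists of integer row indices into ``positions``.
    """
    p = np.asarray(corrected_p, dtype=float)
    regions = []
    for _, grp in positions.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        gidx = positions.index.get_indexer(grp.index)
        hits = np.flatnonzero(p[gidx] < seed_p)
        if hits.size == 0:
            continue
        current = [hits[0]]
        for h in hits[1:]:
            if pos[h] - pos[current[-1]] <= dist:
                current.append(h)
            else:
                if len(current) >= 2:
                    regions.append([int(gidx[i]) for i in current])
                current = [h]
        if len(current) >= 2:
            regions.append([int(gidx[i]) for i in current])
    return regions


def sidak(p_combined: float, total_bases: float, width: float) -> float:
    """Region-level Sidak correction 1 - (1 - p)^(total_bases / width)."""
    if width <= 0:
        raise ValueError("region width must be positive")
    exponent = total_bases / width
    # -expm1(k * log1p(-p)) is accurate for tiny combined p
    return float(-np.expm1(exponent * np.log1p(-min(p_combined, 1.0 - 1e-16))))


def score_region(
    member_idx: list[int],
    raw_p: np.ndarray,
    positions: pd.DataFrame,
    coefs: np.ndarray,
    acf: pd.DataFrame,
    total_bases: float,
) -> dict:
    """Score one candidate region: combined p, Sidak p, direction string."""
    if len(member_idx) < 2:
        raise ValueError("a region needs at least 2 probes")
    sigma = _sigma_lookup(acf)
    idx = np.asarray(member_idx)
    pos = positions["pos"].to_numpy()[idx]
    order = np.argsort(pos, kind="mergesort")
    idx, pos = idx[order], pos[order]
    z = _p_to_z(np.asarray(raw_p, dtype=float)[idx])
    ii, jj = np.triu_indices(len(idx), k=1)
    zc = _combine(z, pos[jj] - pos[ii], sigma)
    p_comb = float(stats.norm.sf(zc))
    start, end = int(pos[0]), int(pos[-1])
    width = end - start + 1
    direction = " ".join("-" if c < 0 else "+" for c in coefs[idx])
    return {
        "chrom": positions["chrom"].to_numpy()[idx[0]],
        "start": start,
        "end": end,
        "width": width,
        "n_probes": len(idx),
        "probes": ";".join(positions.index[idx].astype(str)),
        "direction": direction,
        "p_combined": p_comb,
        "p_sidak": sidak(p_comb, total_bases, width),
    }


def call_dmrs(
    ewas: pd.DataFrame,
    manifest: pd.DataFrame,
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Full region scan over an EWAS result table.

    Only probes with status ``ok`` participate. ``total_bases`` for the
    Sidak exponent is the summed per-chromosome span of analyzed probes.
    Returns all candidate regions sorted by Sidak p, with a ``significant``
    flag at the configured alpha.
    """
    params = params or DmrParams()
    ok = ewas["status"] == "ok"
    probes = ewas.index[ok]
    man = manifest.loc[probes, ["chrom", "pos"]].copy()
    man = man.sort_values(["chrom", "pos"], kind="mergesort")
    pvals = ewas.loc[man.index, "p"].to_numpy(dtype=float)
    coefs = ewas.loc[man.index, "coef"].to_numpy(dtype=float)

    acf = estimate_acf(
        man, pvals, max_dist=params.max_dist, bin_size=params.bin_size,
        min_pairs_per_bin=params.min_pairs_per_bin,
    )
    corrected = slk_correct(pvals, man, acf, window=params.window)
    regions = find_regions(corrected, man, seed_p=params.seed_p,
                           dist=params.dist)
    if params.sidak_total == "covered":
        # each assayed CpG covers 2 bases (the CpG dinucleotide)
        total_bases = 2.0 * len(man)
    elif params.sidak_total == "span":
        total_bases = float(
            man.groupby("chrom")["pos"]
            .agg(lambda s: s.max() - s.min() + 1).sum()
        )
    else:
        raise ValueError(f"unknown sidak_total {params.sidak_total!r}")
    rows = [
        score_region(r, pvals, man, coefs, acf, total_bases) for r in regions
    ]
    out = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "width", "n_probes", "probes",
                 "direction", "p_combined", "p_sidak"],
    )
    if len(out):
        out = out.sort_values("p_sidak", kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p_sidak"] < params.sidak_alpha if len(out) else []
    logger.info(
        "DMR scan: %d candidate regions, %d significant at Sidak < %g",
        len(out), int(out["significant"].sum()) if len(out) else 0,
        params.sidak_alpha,
    )
    return out
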