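"""Genomic-context stratification of the hypomethylation signal.

A negative conditional-regression coefficient at a probe means lower
methylation in cases. Stratifying coefficient signs by CpG-island relation,
RefGene group, regulatory feature and external annotation tracks (repeats,
CoRSIVs, candidate cis-regulatory elements, TF motifs), and testing each
stratum with an exact binomial test against 0.5, quantifies where in the
genome case hypomethylation concentrates. The coefficient-sign analysis is
confirmed on the raw beta scale by one-sample Wilcoxon tests of per-pair
median delta-beta values within each stratum.

Multiple-testing correction is applied within analysis families (core
annotation strata, repeats, TF motifs, ...), each family separately for the
sign tests and for the delta-beta tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._stats import (  # noqa: F401  (re-exported module surface)
    bh_fdr,
    binom_two_sided,
    fisher_enrichment,
    two_proportion_test,
    wilcoxon_signed_rank,
)
from .ingest import ISLAND_RELATIONS, REFGENE_GROUPS, REG_FEATURES

logger = logging.getLogger("twinewas")


def read_bed(path, name: str | None = None) -> pd.DataFrame:
    """Read a BED3+name track (0-based half-open intervals).

    The name field carries the class label (repeat class, cCRE class, TF
    motif name); tracks without one get a single class named after the
    track.
    """
    track = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
    )
    if track["name"].isna().all():
        track["name"] = name or "track"
    if (track["start"] >= track["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return track


def _normalize_chrom(values: pd.Series, template: set[str]) -> pd.Series:
    """Reconcile 'chr1' versus '1' naming against a template set."""
    vals = values.astype(str)
    if set(vals.unique()) <= template:
        return vals
    stripped = vals.str.removeprefix("chr")
    prefixed = "chr" + stripped
    if set(stripped.unique()) <= template:
        logger.warning("stripping 'chr' prefix to match manifest naming")
        return stripped
    if set(prefixed.unique()) <= template:
        logger.warning("adding 'chr' prefix to match manifest naming")
        return prefixed
    return vals


def overlap_probes(manifest: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Probe membership in each class of an interval track.

    A probe at 1-based position ``pos`` is a member of a 0-based half-open
    interval [start, end) iff start <= pos - 1 < end. Returns a boolean
    probes x classes DataFrame.
    """
    chroms = set(manifest["chrom"].astype(str).unique())
    track = track.copy()
    track["chrom"] = _normalize_chrom(track["chrom"], chroms)
    classes = sorted(track["name"].unique())
    out = pd.DataFrame(False, index=manifest.index, columns=classes)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for (chrom, cls), grp in track.groupby(["chrom", "name"]):
        trees[(chrom, cls)] = IntervalTree.from_tuples(
            zip(grp["start"], grp["end"])
        )
    pos0 = manifest["pos"].to_numpy() - 1
    chrom_arr = manifest["chrom"].astype(str).to_numpy()
    for i, probe in enumerate(manifest.index):
        for cls in classes:
            tree = trees.get((chrom_arr[i], cls))
            if tree is not None and tree.overlaps_point(int(pos0[i])):
                out.at[probe, cls] = True
    return out


def tally_signs(coefs: np.ndarray) -> tuple[int, int, int]:
    """Count strictly negative, strictly positive and zero coefficients.

    Zero coefficients are excluded from both signed counts (and from the
    binomial denominator) but reported so the exclusion is visible.
    """
    c = np.asarray(coefs, dtype=float)
    c = c[np.isfinite(c)]
    n_neg = int((c < 0).sum())
    n_pos = int((c > 0).sum())
    n_zero = int((c == 0).sum())
    if n_zero:
        logger.info("excluded %d exactly-zero coefficients from sign tally",
                    n_zero)
    return n_neg, n_pos, n_zero


def stratum_delta_beta(
    delta: pd.DataFrame, member: pd.Series | np.ndarray
) -> dict:
    """Per-pair median delta-beta within a stratum, with a one-sample
    Wilcoxon signed-rank test of the medians against zero."""
    sub = delta.loc[np.asarray(member, dtype=bool)]
    if sub.empty:
        return {"n_probes": 0}
    pair_medians = sub.median(axis=0, skipna=True).to_numpy()
    q1, q3 = np.nanpercentile(pair_medians, [25, 75])
    return {
        "n_probes": int(len(sub)),
        "pair_medians": pair_medians,
        "db_median": float(np.nanmedian(pair_medians)),
        "db_iqr": float(q3 - q1),
        "wilcoxon_p": wilcoxon_signed_rank(pair_medians),
    }


def _membership_strata(manifest: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    """Core annotation strata: (family, stratum name, membership mask)."""
    strata: list[tuple[str, str, pd.Series]] = []
    strata.append(("all", "All probes", pd.Series(True, index=manifest.index)))
    rel = manifest["island_relation"]
    for cat in ISLAND_RELATIONS:
        strata.append(("island_relation", cat, rel == cat))
    # collapsed stratum mirroring the shelf/shore reporting convention
    strata.append(("island_relation", "Shelf/shore", rel.isin(["Shelf", "Shore"])))
    groups = manifest["refgene_groups"].fillna("").astype(str)
    for grp in REFGENE_GROUPS:
        mask = groups.str.split(";").apply(lambda gs, g=grp: g in gs)
        strata.append(("refgene_group", grp, mask))
    for feat in REG_FEATURES:
        strata.append(("reg_feature", feat, manifest["reg_feature"] == feat))
    return strata


def run_bias_suite(
    ewas: pd.DataFrame,
    delta: pd.DataFrame,
    manifest: pd.DataFrame,
    tracks: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Sign-bias and delta-beta bias table across all annotation strata.

    One row per stratum: sign counts with exact binomial p (null 0.5),
    per-pair median delta-beta summary with one-sample Wilcoxon p, and FDR
    within each (family, test) analysis group. Island-relation strata
    partition the tested probes; RefGene strata may overlap (a probe counts
    in every group it is annotated to).
    """
    manifest = manifest.loc[ewas.index]
    delta = delta.reindex(ewas.index)
    ok = ewas["status"] == "ok"
    coefs = ewas["coef"].where(ok)
    strata = _membership_strata(manifest)
    if tracks:
        for track_name, track in tracks.items():
            membership = overlap_probes(manifest, track)
            any_mask = membership.any(axis=1)
            strata.append((track_name, f"{track_name} (any)", any_mask))
            for cls in membership.columns:
                strata.append((track_name, cls, membership[cls]))
    rows = []
    for family, name, mask in strata:
        mask = pd.Series(np.asarray(mask, dtype=bool), index=manifest.index)
        c = coefs[mask.to_numpy()].to_numpy(dtype=float)
        n_neg, n_pos, n_zero = tally_signs(c)
        n = n_neg + n_pos
        row = {
            "family": family,
            "stratum": name,
            "n_probes": int(mask.sum()),
            "n_negative": n_neg,
            "n_positive": n_pos,
            "n_zero": n_zero,
            "frac_negative": n_neg / n if n else np.nan,
            "binom_p": binom_two_sided(n_neg, n) if n else np.nan,
        }
        db = stratum_delta_beta(delta, mask)
        if db["n_probes"]:
            row.update(
                db_median=db["db_median"],
                db_iqr=db["db_iqr"],
                wilcoxon_p=db["wilcoxon_p"],
            )
        else:
            continue  # empty stratum: row omitted
        rows.append(row)
    out = pd.DataFrame(rows)
    out["binom_q"] = np.nan
    out["wilcoxon_q"] = np.nan
    for fam, grp in out.groupby("family"):
        out.loc[grp.index, "binom_q"] = bh_fdr(grp["binom_p"].to_numpy())
        out.loc[grp.index, "wilcoxon_q"] = bh_fdr(grp["wilcoxon_p"].to_numpy())
    return out


def motif_enrichment(
    ewas: pd.DataFrame,
    manifest: pd.DataFrame,
    track: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of annotation classes among significant probes.

    For each class of the track (e.g. each TF motif): a two-sided Fisher
    exact test comparing overlap frequency among EWAS-significant probes
    (FDR below threshold) with the full tested background, BH-corrected
    across classes.
    """
    ok = ewas["status"] == "ok"
    sig = ok & (ewas["q"] < fdr_threshold)
    membership = overlap_probes(manifest, track)
    bg_total = int(ok.sum())
    sig_total = int(sig.sum())
    rows = []
    for cls in membership.columns:
        m = membership[cls]
        bg_in = int((m & ok).sum())
        sig_in = int((m & sig).sum())
        odds, p = fisher_enrichment(sig_in, sig_total, bg_in, bg_total)
        rows.append(
            {"class": cls, "sig_in": sig_in, "sig_total": sig_total,
             "bg_in": bg_in, "bg_total": bg_total,
             "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
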