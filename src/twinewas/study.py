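"""Replication-study driver over simulated cohorts.

Runs the full analysis chain (deconvolution, conditional EWAS, DMR scan,
context-bias suite) on many seeded synthetic cohorts — with and without
planted signal — and summarizes recovery and calibration. Shared by the
acceptance machinery and the property-test suite so both measure the same
computation.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .deconvolution import estimate_proportions
from .dmr import DmrParams, call_dmrs
from .ewas import run_ewas
from .pairwise import delta_beta, pair_correlation
from .simulate import SimConfig, generate_cohort, generate_manifest

logger = logging.getLogger("twinewas")


def analyze_cohort(cfg: SimConfig, dmr_params: DmrParams | None = None) -> dict:
    """Generate one cohort and run the analysis chain on it."""
    manifest = generate_manifest(cfg)
    beta, sheet, truth, ref = generate_cohort(cfg, manifest)
    props = estimate_proportions(beta, ref)
    ewas = run_ewas(beta, sheet, props)
    dmrs = call_dmrs(ewas, manifest, dmr_params)
    delta = delta_beta(beta, sheet)
    return {
        "manifest": manifest,
        "beta": beta,
        "sheet": sheet,
        "truth": truth,
        "props": props,
        "ewas": ewas,
        "dmrs": dmrs,
        "delta": delta,
    }


def dmr_recovery(called: pd.DataFrame, truth_dmrs: list) -> tuple[int, int]:
    """(planted regions recovered, significant calls matching no plant).

    A planted region counts as recovered when a significant called region
    overlaps it on the same chromosome; a significant call overlapping no
    planted region is a false region.
    """
    sig = called[called["significant"]] if len(called) else called
    recovered = 0
    matched = np.zeros(len(sig), dtype=bool)
    for planted in truth_dmrs:
        hit = False
        for i, (_, row) in enumerate(sig.iterrows()):
            if (
                row["chrom"] == planted["chrom"]
                and row["start"] <= planted["end"]
                and planted["start"] <= row["end"]
            ):
                hit = True
                matched[i] = True
        recovered += int(hit)
    false_calls = int((~matched).sum()) if len(sig) else 0
    return recovered, false_calls


def _context_fractions(ewas: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Negative-coefficient fractions for the full array and key contexts."""
    ok = ewas["status"] == "ok"
    coefs = ewas.loc[ok, "coef"]
    rel = manifest.loc[coefs.index, "island_relation"]
    out = {}
    for name, mask in (
        ("all", np.ones(len(coefs), dtype=bool)),
        ("opensea", (rel == "OpenSea").to_numpy()),
        ("island", (rel == "Island").to_numpy()),
    ):
        c = coefs.to_numpy()[mask]
        c = c[c != 0]
        out[f"frac_neg_{name}"] = float((c < 0).mean()) if c.size else np.nan
        out[f"n_{name}"] = int(c.size)
    return out


def run_replication_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    cfg: SimConfig | None = None,
    dmr_params: DmrParams | None = None,
) -> pd.DataFrame:
    """Analyze ``n_seeds`` signal cohorts and matched null cohorts.

    For each seed: DMR recovery and false calls on the signal cohort, false
    significant regions and per-stratum FDR hits on the matched null,
    negative-coefficient fractions by context, the full-array binomial
    sign-bias p, genomic inflation on the null, and the per-pair
    correlation range. One row per seed.
    """
    from .context import run_bias_suite
    from ._stats import binom_two_sided
    from .ewas import genomic_inflation

    cfg = cfg or SimConfig()
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        signal_cfg = replace(cfg, seed=seed)
        res = analyze_cohort(signal_cfg, dmr_params)
        rec, false_sig = dmr_recovery(res["dmrs"], res["truth"].dmrs)
        fracs = _context_fractions(res["ewas"], res["manifest"])
        bias = run_bias_suite(res["ewas"], res["delta"], res["manifest"])
        all_row = bias[bias["stratum"] == "All probes"].iloc[0]
        corr = pair_correlation(res["beta"], res["sheet"])

        null_cfg = replace(cfg, seed=seed).null()
        nres = analyze_cohort(null_cfg, dmr_params)
        n_false_null = int(nres["dmrs"]["significant"].sum()) if len(
            nres["dmrs"]) else 0
        nbias = run_bias_suite(nres["ewas"], nres["delta"], nres["manifest"])
        n_strata_fdr = int(
            ((nbias["binom_q"] < 0.05) | (nbias["wilcoxon_q"] < 0.05)).sum()
        )
        null_frac = _context_fractions(nres["ewas"], nres["manifest"])

        rows.append(
            {
                "seed": seed,
                "n_planted": len(res["truth"].dmrs),
                "n_recovered": rec,
                "n_false_signal": false_sig,
                "n_false_null": n_false_null,
                "null_strata_fdr_hits": n_strata_fdr,
                "null_frac_neg_all": null_frac["frac_neg_all"],
                "full_array_binom_p": binom_two_sided(
                    int(all_row["n_negative"]),
                    int(all_row["n_negative"] + all_row["n_positive"]),
                ),
                "lambda_null": genomic_inflation(
                    nres["ewas"]["p"].to_numpy()
                ),
                "pair_corr_min": float(corr.min()),
                "pair_corr_max": float(corr.max()),
                **fracs,
            }
        )
        logger.info(
            "seed %d: recovered %d/%d DMRs, %d false (signal), %d false "
            "(null), %d null strata FDR hits",
            seed, rec, rows[-1]["n_planted"], false_sig, n_false_null,
            n_strata_fdr,
        )
    return pd.DataFrame(rows)
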