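"""End-to-end pipeline runner with a machine-readable run report.

A YAML configuration names the input files and surfaces every statistical
threshold (detection-p mask, missingness cap, recurrence delta-beta cut,
FDR and Sidak alphas, region-scan parameters). The runner executes
ingest -> deconvolution -> within-pair statistics -> conditional EWAS ->
DMR scan -> context-bias suite -> optional cross-platform concordance,
writes fixed-name outputs under one directory, and records every filter
count in the run report so the probe/subject trail is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import concordance as conc
from .context import motif_enrichment, read_bed, run_bias_suite
from .deconvolution import compare_proportions_paired, estimate_proportions
from .dmr import DmrParams, call_dmrs
from .ewas import run_ewas
from .ingest import (
    apply_detection_mask,
    filter_missingness,
    flag_failed_pairs,
    impute_knn,
    read_inputs,
)
from .pairwise import (
    delta_beta,
    global_content,
    pair_correlation,
    recurrent_variable_probes,
)

logger = logging.getLogger("twinewas")

_DEFAULTS = {
    "detection_p_threshold": 0.05,
    "max_missing_frac": 0.05,
    "recurrence_threshold": 0.15,
    "recurrence_min_pairs": 2,
    "fdr_alpha": 0.05,
    "sidak_alpha": 0.05,
    "dmr": {"window": 750, "dist": 750, "seed_p": 0.01, "bin_size": 50,
            "max_dist": 750},
    "impute_k": 10,
    "seed": 0,
}

_REQUIRED_INPUTS = ("beta", "samples", "manifest")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError("config must be a mapping with an 'inputs' section")
    missing_keys = [k for k in _REQUIRED_INPUTS if k not in cfg["inputs"]]
    if missing_keys:
        raise ValueError(f"config inputs missing required keys: {missing_keys}")
    for key in _REQUIRED_INPUTS:
        p = Path(cfg["inputs"][key])
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    merged = {**_DEFAULTS, **{k: v for k, v in cfg.items() if k != "dmr"}}
    merged["dmr"] = {**_DEFAULTS["dmr"], **cfg.get("dmr", {})}
    return merged


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config_path, outdir) -> dict:
    """Execute the full pipeline; returns the run report (also written)."""
    cfg = load_config(config_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    report: dict = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "input_checksums": {k: _checksum(v) for k, v in inputs.items()
                            if Path(str(v)).is_file()},
        "filters": [],
        "stages": {},
    }

    beta, sheet, manifest, detp = read_inputs(
        inputs["beta"], inputs["samples"], inputs["manifest"],
        inputs.get("detection_p"),
    )
    report["stages"]["ingest"] = {
        "n_probes": int(beta.shape[0]), "n_subjects": int(beta.shape[1]),
        "n_pairs": int(sheet["pair_id"].nunique()),
    }

    if detp is not None:
        beta = apply_detection_mask(beta, detp, cfg["detection_p_threshold"])
        sheet = flag_failed_pairs(sheet, detp)
        failed = sheet.loc[sheet["qc_fail"], "pair_id"].unique().tolist()
        if failed:
            keep = ~sheet["qc_fail"]
            sheet = sheet.loc[keep]
            beta = beta[sheet.index.tolist()]
            report["filters"].append(
                {"rule": "pair_detection_p", "removed_pairs": failed}
            )
    beta, rm_probes, rm_subjects = filter_missingness(
        beta, cfg["max_missing_frac"]
    )
    report["filters"].append(
        {"rule": "missingness", "removed_probes": len(rm_probes),
         "removed_subjects": len(rm_subjects)}
    )
    if rm_subjects:
        sheet = sheet.loc[[s for s in sheet.index if s not in rm_subjects]]
        complete = sheet.groupby("pair_id")["role"].transform("size") == 2
        sheet = sheet.loc[complete]
        beta = beta[sheet.index.tolist()]
    manifest = manifest.loc[beta.index]
    beta = impute_knn(beta, cfg["impute_k"])

    props = None
    if "cell_reference" in inputs:
        ref = pd.read_csv(inputs["cell_reference"], index_col=0)
        props = estimate_proportions(beta, ref)
        props.to_csv(out / "cell_proportions.csv")
        compare_proportions_paired(props, sheet).to_csv(
            out / "cell_proportion_tests.csv", index=False
        )

    delta = delta_beta(beta, sheet)
    delta.round(6).to_csv(out / "delta_beta.tsv", sep="\t",
                          float_format="%.6f")
    recurrence = recurrent_variable_probes(
        delta, cfg["recurrence_threshold"], cfg["recurrence_min_pairs"]
    )
    recurrence.to_csv(out / "recurrence.csv")
    corr = pair_correlation(beta, sheet)
    corr.to_csv(out / "pair_correlation.csv")
    content, content_test = global_content(beta, sheet)
    report["stages"]["pairwise"] = {
        "n_recurrent_probes": int(recurrence["recurrent"].sum()),
        "pair_correlation_range": [float(corr.min()), float(corr.max())],
        "global_content_p": content_test["p"],
    }

    ewas = run_ewas(beta, sheet, props)
    ewas.to_csv(out / "ewas.tsv", sep="\t")
    report["stages"]["ewas"] = {
        "n_ok": int((ewas["status"] == "ok").sum()),
        "n_significant_fdr": int((ewas["q"] < cfg["fdr_alpha"]).sum()),
        "lambda": ewas.attrs.get("lambda"),
    }

    params = DmrParams(sidak_alpha=cfg["sidak_alpha"], **cfg["dmr"])
    dmrs = call_dmrs(ewas, manifest, params)
    dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)
    if len(dmrs):
        sig = dmrs[dmrs["significant"]]
        bed = sig.assign(start0=sig["start"] - 1)[
            ["chrom", "start0", "end", "p_sidak"]
        ]
        bed.to_csv(out / "dmrs_significant.bed", sep="\t", header=False,
                   index=False)
    report["stages"]["dmr"] = {
        "n_candidates": int(len(dmrs)),
        "n_significant": int(dmrs["significant"].sum()) if len(dmrs) else 0,
    }

    tracks = {
        name: read_bed(path, name)
        for name, path in cfg.get("tracks", {}).items()
    }
    bias = run_bias_suite(ewas, delta, manifest, tracks or None)
    bias.to_csv(out / "bias_table.tsv", sep="\t", index=False)
    all_row = bias[bias["stratum"] == "All probes"].iloc[0]
    report["stages"]["bias"] = {
        "frac_negative_all": float(all_row["frac_negative"]),
        "binom_p_all": float(all_row["binom_p"]),
        "n_strata": int(len(bias)),
    }
    if "tf_motifs" in tracks:
        motif_enrichment(ewas, manifest, tracks["tf_motifs"]).to_csv(
            out / "tf_enrichment.tsv", sep="\t", index=False
        )

    if "orthogonal" in inputs:
        ortho = conc.load_orthogonal(inputs["orthogonal"])
        pooled, per_target = conc.correlate_methods(beta, ortho)
        per_target.to_csv(out / "concordance.csv", index=False)
        report["stages"]["concordance"] = pooled

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    logger.info("pipeline complete; report at %s", report_path)
    return report
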