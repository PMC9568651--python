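"""Synthetic twin-cohort methylation generator with known ground truth.

Real disease-discordant twin registry data are legally restricted, so every
downstream stage of the pipeline is exercised on simulated cohorts that
emulate the statistical structure of neonatal blood-spot EPIC-array data:

* beta values are logit-normal: logit(beta) is an additive combination of a
  per-probe baseline (bimodal by CpG context: islands unmethylated, open sea
  methylated), a shared within-pair effect, a plate batch effect, the
  planted case effect, a cell-mixture term on a designated informative-probe
  subset, and individual noise; logits are clipped to +/-12 so betas stay
  strictly inside (0, 1);
* the planted case effect is drawn per probe with a context-specific mean:
  negative (hypomethylating) in open-sea/shelf/shore probes and zero-mean in
  island probes, reproducing regionally specific case hypomethylation as
  ground truth;
* contiguous DMR blocks add a shared shift to runs of >= 3 probes within a
  500 bp span;
* within-pair correlation of beta values lands in the high-0.96 to low-0.99
  range typical of monozygotic twins;
* nucleated-cell composition is Dirichlet-distributed per subject and leaks
  into betas only at the informative probes, mirroring how deconvolution
  reference libraries are designed.

All randomness derives from one integer seed; component streams use fixed
sub-seed offsets so a given component regenerates identically in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .ingest import ISLAND_RELATIONS, REFGENE_GROUPS, REG_FEATURES

logger = logging.getLogger("twinewas")

CELL_TYPES = ("B", "CD4T", "CD8T", "Mono", "Gran", "NK", "nRBC")

#: maximum span (bp) of a planted DMR block
DMR_SPAN = 500
#: logit clipping bound keeping betas strictly inside (0, 1)
LOGIT_CLIP = 12.0

# fixed sub-seed offsets per generator component
_SS_MANIFEST = 1
_SS_BASELINE = 2
_SS_PAIR = 3
_SS_NOISE = 4
_SS_EFFECT = 5
_SS_DMR = 6
_SS_CELLS = 7
_SS_SHEET = 8
_SS_TRACKS = 9
_SS_PLATE = 10


@dataclass
class SimConfig:
    """Generator configuration; the defaults define the study conditions."""

    n_pairs: int = 40
    n_probes: int = 20000
    n_chroms: int = 4
    n_plates: int = 2
    context_probs: dict = field(default_factory=lambda: {
        "OpenSea": 0.55, "Island": 0.20, "Shore": 0.15, "Shelf": 0.10,
    })
    # per-context (location, scale) of probe baselines on the logit scale
    baseline_logit: dict = field(default_factory=lambda: {
        "OpenSea": (2.6, 1.2), "Island": (-2.8, 1.2),
        "Shore": (0.0, 1.8), "Shelf": (2.2, 1.2),
    })
    pair_sd: float = 0.3      # shared within-pair effect, logit scale
    # individual measurement noise is approximately constant on the beta
    # scale: per-probe beta-scale sd tau_j is lognormal with the median and
    # log-sd below, clipped to [0.004, 0.03], then mapped to the logit scale
    # as tau_j / (beta (1 - beta)); indiv_sd multiplies the resulting
    # per-probe logit sd (1.0 = calibrated default)
    indiv_sd: float = 1.0
    beta_noise_median: float = 0.014
    beta_noise_spread: float = 0.3
    plate_sd: float = 0.08    # plate batch effect, logit scale
    # per-context (mean, sd) of the per-probe case effect on the beta
    # scale; negative means encode case hypomethylation outside islands.
    # Magnitudes match the 1e-3-scale per-stratum delta-beta medians seen
    # on arrays.
    case_effect: dict = field(default_factory=lambda: {
        "OpenSea": (-0.0019, 0.006), "Shelf": (-0.0016, 0.006),
        "Shore": (-0.0016, 0.006), "Island": (0.0, 0.006),
    })
    n_dmrs: int = 5
    dmr_effect: float = -0.022  # beta-scale shift of planted regions
    dmr_min_probes: int = 8    # probes per planted region
    dirichlet_alpha: tuple = (6, 12, 12, 10, 55, 3, 2)
    n_cell_probes: int = 500
    cell_offset_sd: float = 1.5
    cell_pair_cv: float = 0.05  # within-pair log-scale spread of proportions
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        total = sum(self.context_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"context_probs must sum to 1, got {total:.6f}"
            )
        if set(self.context_probs) != set(ISLAND_RELATIONS):
            raise ValueError("context_probs must cover exactly the four "
                             "island-relation categories")
        for name in ("pair_sd", "indiv_sd", "plate_sd", "cell_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.dirichlet_alpha) != len(CELL_TYPES):
            raise ValueError("dirichlet_alpha must have 7 entries")
        if self.n_cell_probes > self.n_probes:
            raise ValueError("n_cell_probes exceeds n_probes")

    def null(self) -> "SimConfig":
        """Copy of this configuration with no planted case signal."""
        cfg = SimConfig(**{**asdict(self)})
        cfg.case_effect = {c: (0.0, 0.0) for c in self.case_effect}
        cfg.n_dmrs = 0
        return cfg

    def _rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), offset])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    delta: pd.Series                 # per-probe case effect, logit scale
    dmrs: list                       # planted regions (chrom/start/end/...)
    cell_props: pd.DataFrame         # subjects x cell types
    plates: pd.Series                # subject -> plate
    informative_probes: list         # probes carrying the cell signal

    def to_json(self) -> str:
        return json.dumps(
            {
                "delta": {str(k): float(v) for k, v in self.delta.items()},
                "dmrs": self.dmrs,
                "cell_props": {
                    s: [float(x) for x in row]
                    for s, row in self.cell_props.iterrows()
                },
                "cell_types": list(self.cell_props.columns),
                "plates": {str(k): str(v) for k, v in self.plates.items()},
                "informative_probes": list(self.informative_probes),
            },
            indent=0,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        props = pd.DataFrame.from_dict(
            d["cell_props"], orient="index", columns=d["cell_types"]
        )
        return cls(
            delta=pd.Series(d["delta"], dtype=float),
            dmrs=d["dmrs"],
            cell_props=props,
            plates=pd.Series(d["plates"]),
            informative_probes=list(d["informative_probes"]),
        )


# probability that the next inter-probe gap continues a dense CpG cluster
_CLUSTER_PROB = 0.55
_REFGENE_WEIGHTS = {
    "Body": 0.45, "TSS1500": 0.15, "TSS200": 0.08, "5UTR": 0.10,
    "1stExon": 0.05, "ExonBnd": 0.02, "3UTR": 0.15,
}


def generate_manifest(cfg: SimConfig) -> pd.DataFrame:
    """Simulate a probe manifest with clustered positions and annotations.

    Positions are strictly increasing within each chromosome, with a
    mixture of short (dense-cluster) and long gaps so that runs of probes
    within a DMR-sized span occur naturally. Island probes are
    preferentially promoter-annotated, mirroring real array annotation.
    """
    cfg.validate()
    rng = cfg._rng(_SS_MANIFEST)
    n = cfg.n_probes
    contexts = list(cfg.context_probs)
    relation = rng.choice(
        contexts, size=n, p=[cfg.context_probs[c] for c in contexts]
    )

    per_chrom = np.array_split(np.arange(n), cfg.n_chroms)
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    for c, idx in enumerate(per_chrom):
        chroms[idx] = f"chr{c + 1}"
        m = len(idx)
        cluster = rng.random(m) < _CLUSTER_PROB
        gaps = np.where(
            cluster,
            rng.integers(20, 91, size=m),
            rng.integers(500, 3001, size=m),
        )
        pos[idx] = 1_000_000 + np.cumsum(gaps)

    n_groups = rng.choice([0, 1, 2], size=n, p=[0.35, 0.55, 0.10])
    group_names = list(_REFGENE_WEIGHTS)
    group_p = np.array(list(_REFGENE_WEIGHTS.values()))
    refgene = []
    for k in n_groups:
        if k == 0:
            refgene.append("")
        else:
            chosen = rng.choice(group_names, size=k, replace=False,
                                p=group_p / group_p.sum())
            refgene.append(";".join(sorted(chosen)))

    reg = np.empty(n, dtype=object)
    is_island = relation == "Island"
    reg[is_island] = rng.choice(
        REG_FEATURES, size=int(is_island.sum()), p=[0.55, 0.05, 0.05, 0.35]
    )
    reg[~is_island] = rng.choice(
        REG_FEATURES, size=int((~is_island).sum()), p=[0.05, 0.10, 0.10, 0.75]
    )

    gene_block = 40  # consecutive probes sharing a gene symbol
    genes = [
        f"GENE{(i // gene_block):04d}" if refgene[i] else ""
        for i in range(n)
    ]

    man = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n)],
            "chrom": chroms,
            "pos": pos,
            "island_relation": relation,
            "refgene_groups": refgene,
            "reg_feature": reg,
            "genes": genes,
        }
    ).set_index("probe_id", drop=False)
    return man


def _dmr_candidates(manifest: pd.DataFrame, min_probes: int = 3) -> list:
    """Maximal disjoint runs of >= min_probes probes within DMR_SPAN bp."""
    runs = []
    for _, grp in manifest.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp.index.to_numpy()
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[i] <= DMR_SPAN:
                j += 1
            if j - i + 1 >= min_probes:
                runs.append(list(ids[i : j + 1]))
                i = j + 1
            else:
                i += 1
    return runs


def plant_dmrs(
    cfg: SimConfig,
    manifest: pd.DataFrame,
    truth: SyntheticTruth,
    baseline: np.ndarray | None = None,
    tau: np.ndarray | None = None,
) -> SyntheticTruth:
    """Add the shared DMR effect to ``cfg.n_dmrs`` disjoint probe runs.

    ``dmr_effect`` is a beta-scale shift: each member probe receives a logit
    shift of ``dmr_effect / (beta (1 - beta))`` evaluated at its baseline
    (capped at 1.5 in magnitude), so the induced beta shift is uniform
    across probes regardless of their methylation level. Without baselines
    the slope at beta = 0.5 is used.

    When per-probe noise scales ``tau`` are given, each member's shift is
    additionally capped at its own noise sd: beyond roughly one noise sd per
    pair the matched-pair logistic likelihood turns monotone and the probe
    stops carrying usable evidence, so detectable regions — the ground
    truth this generator plants — live below that ceiling.
    """
    if cfg.n_dmrs == 0:
        return truth
    candidates = _dmr_candidates(manifest, cfg.dmr_min_probes)
    if baseline is None:
        slope = pd.Series(0.25, index=manifest.index)
    else:
        # slope at the expected realized beta (logistic-normal shrinkage);
        # runs containing boundary probes (beta outside [0.05, 0.95]) are
        # not used, because a beta-scale shift there is physically truncated
        shrink = np.sqrt(1.0 + np.pi**2 * cfg.pair_sd**2 / 8.0)
        b = expit(np.asarray(baseline, dtype=float) / shrink)
        slope = pd.Series(np.maximum(b * (1.0 - b), 0.01),
                          index=manifest.index)
        in_range = pd.Series((b >= 0.03) & (b <= 0.97), index=manifest.index)
        candidates = [
            run for run in candidates if in_range.loc[run].all()
        ]
    if len(candidates) < cfg.n_dmrs:
        raise ValueError(
            f"manifest supports only {len(candidates)} DMR regions, "
            f"{cfg.n_dmrs} requested"
        )
    rng = cfg._rng(_SS_DMR)
    chosen = rng.choice(len(candidates), size=cfg.n_dmrs, replace=False)
    if tau is not None:
        tau_series = pd.Series(np.asarray(tau, dtype=float),
                               index=manifest.index)
    dmrs = []
    for ci in sorted(chosen):
        probes = candidates[ci]
        effect = np.full(len(probes), cfg.dmr_effect)
        if tau is not None:
            cap = tau_series.loc[probes].to_numpy()
            effect = np.sign(effect) * np.minimum(np.abs(effect), cap)
        shift = np.clip(
            effect / slope.loc[probes].to_numpy(), -1.5, 1.5
        )
        # the coordinated regional effect replaces the independent
        # probe-level case effect on members, so the region's ground truth
        # is exactly the configured shift
        truth.delta.loc[probes] = shift
        sub = manifest.loc[probes]
        dmrs.append(
            {
                "chrom": str(sub["chrom"].iloc[0]),
                "start": int(sub["pos"].min()),
                "end": int(sub["pos"].max()),
                "probes": [str(p) for p in probes],
                "effect_beta": float(cfg.dmr_effect),
            }
        )
    truth.dmrs = dmrs
    return truth


def generate_cohort(
    cfg: SimConfig, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth, pd.DataFrame]:
    """Simulate betas, sample sheet, ground truth and cell reference.

    Returns ``(beta, sheet, truth, cell_reference)``. Cases and controls of
    a pair always land on different plates, emulating the block-randomized
    chip layout of the real study design.
    """
    cfg.validate()
    n, npair = cfg.n_probes, cfg.n_pairs
    relation = manifest["island_relation"].to_numpy()

    rng_base = cfg._rng(_SS_BASELINE)
    base = np.empty(n)
    for ctx, (loc, scale) in cfg.baseline_logit.items():
        m = relation == ctx
        base[m] = rng_base.normal(loc, scale, size=int(m.sum()))

    rng_eff = cfg._rng(_SS_EFFECT)
    delta_beta_scale = np.zeros(n)
    for ctx, (mu, sd) in cfg.case_effect.items():
        m = relation == ctx
        delta_beta_scale[m] = (
            rng_eff.normal(mu, sd, size=int(m.sum())) if sd > 0 else mu
        )
    # convert the beta-scale effect to the additive logit scale through the
    # slope of the inverse-logit at the probe's expected realized beta (the
    # logistic-normal mean shrinks the baseline by the pair-effect factor),
    # capped so extreme probes stay bounded
    shrink = np.sqrt(1.0 + np.pi**2 * cfg.pair_sd**2 / 8.0)
    b0 = expit(base / shrink)
    slope0 = np.maximum(b0 * (1.0 - b0), 0.01)
    delta = np.clip(delta_beta_scale / slope0, -1.0, 1.0)

    rng_sheet = cfg._rng(_SS_SHEET)
    pair_ids = [f"pair{i:03d}" for i in range(npair)]
    sexes = rng_sheet.choice(["F", "M"], size=npair, p=[0.6, 0.4])
    plates = [f"plate{p + 1}" for p in range(cfg.n_plates)]
    subjects, rows = [], []
    for i, pid in enumerate(pair_ids):
        case_plate = plates[i % cfg.n_plates]
        ctrl_plate = plates[(i + 1) % cfg.n_plates]
        for role, subj, plate in (
            ("case", f"{pid}_case", case_plate),
            ("control", f"{pid}_ctrl", ctrl_plate),
        ):
            subjects.append(subj)
            rows.append(
                {
                    "subject_id": subj, "pair_id": pid, "role": role,
                    "sex": sexes[i], "plate": plate,
                    "chip": f"{plate}_chip{(i // 4) % 8}",
                }
            )
    sheet = pd.DataFrame(rows).set_index("subject_id", drop=False)

    truth = SyntheticTruth(
        delta=pd.Series(delta, index=manifest.index),
        dmrs=[],
        cell_props=pd.DataFrame(),
        plates=sheet["plate"].copy(),
        informative_probes=[],
    )
    rng_noise = cfg._rng(_SS_NOISE)
    # individual measurement noise is near-constant on the beta scale on
    # arrays: per-probe sd tau_j, clipped so within-pair noise essentially
    # never reaches the 0.15 recurrence screen on its own
    tau = cfg.indiv_sd * np.clip(
        np.exp(rng_noise.normal(np.log(cfg.beta_noise_median),
                                cfg.beta_noise_spread, size=n)),
        0.008, 0.02,
    )

    truth = plant_dmrs(cfg, manifest, truth, baseline=base, tau=tau)
    delta = truth.delta.to_numpy()

    rng_cells = cfg._rng(_SS_CELLS)
    # monozygotic twins share the in-utero environment: composition varies
    # mostly between pairs, with a small multiplicative within-pair spread
    pair_props = rng_cells.dirichlet(cfg.dirichlet_alpha, size=npair)
    jitter = np.exp(
        rng_cells.normal(0.0, cfg.cell_pair_cv, size=(2 * npair, len(CELL_TYPES)))
    )
    props = pair_props[np.repeat(np.arange(npair), 2)] * jitter
    props /= props.sum(axis=1, keepdims=True)
    cell_props = pd.DataFrame(props, index=subjects, columns=CELL_TYPES)
    informative = rng_cells.choice(n, size=cfg.n_cell_probes, replace=False)
    informative.sort()
    offsets = rng_cells.normal(
        0.0, cfg.cell_offset_sd, size=(cfg.n_cell_probes, len(CELL_TYPES))
    )
    truth.cell_props = cell_props
    truth.informative_probes = [str(p) for p in manifest.index[informative]]

    plate_fx = dict(zip(
        plates, cfg._rng(_SS_PLATE).normal(0.0, cfg.plate_sd, size=len(plates))
    ))
    rng_pair = cfg._rng(_SS_PAIR)
    pair_effect = rng_pair.normal(0.0, cfg.pair_sd, size=(n, npair))
    noise = rng_noise.normal(0.0, 1.0, size=(n, 2 * npair)) * tau[:, None]

    is_case = np.array([r["role"] == "case" for r in rows])
    pair_index = np.repeat(np.arange(npair), 2)
    logits = (
        base[:, None]
        + pair_effect[:, pair_index]
        + np.array([plate_fx[r["plate"]] for r in rows])[None, :]
        + np.where(is_case[None, :], delta[:, None], 0.0)
    )
    np.clip(logits, -LOGIT_CLIP, LOGIT_CLIP, out=logits)
    bvals = expit(logits)
    # cell mixtures combine beta values linearly (a beta is the methylated
    # fraction of cells): at informative probes each subject's beta is the
    # proportion-weighted mixture of the per-cell-type profiles. The probes
    # of a deconvolution library are selected for low non-cell variability,
    # so they carry no pair or case effect.
    profiles = expit(
        np.clip(base[informative][:, None] + offsets, -LOGIT_CLIP, LOGIT_CLIP)
    )  # (informative probes, cell types)
    bvals[informative, :] = profiles @ props.T
    bvals = np.clip(bvals + noise, 1e-6, 1 - 1e-6)
    beta = pd.DataFrame(bvals, index=manifest.index, columns=subjects)

    cell_ref = pd.DataFrame(
        expit(np.clip(base[informative][:, None] + offsets,
                      -LOGIT_CLIP, LOGIT_CLIP)),
        index=manifest.index[informative],
        columns=CELL_TYPES,
    )
    return beta, sheet, truth, cell_ref


def generate_tracks(cfg: SimConfig, manifest: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Synthetic annotation tracks (0-based half-open BED conventions).

    Repeats (four classes, dense), CoRSIVs (sparse short regions), cCREs
    (three regulatory classes) and a handful of TF motifs. These are
    synthetic stand-ins exercising the overlap engine, not genome
    annotations.
    """
    rng = cfg._rng(_SS_TRACKS)
    tracks = {}

    def _random_track(classes, n_intervals, lo_len, hi_len):
        rows = []
        for _ in range(n_intervals):
            probe = manifest.iloc[rng.integers(len(manifest))]
            length = int(rng.integers(lo_len, hi_len))
            offset = int(rng.integers(-length + 1, 1))
            start = max(0, int(probe["pos"]) - 1 + offset)
            rows.append(
                {
                    "chrom": probe["chrom"],
                    "start": start,
                    "end": start + length,
                    "name": classes[rng.integers(len(classes))],
                }
            )
        return pd.DataFrame(rows).sort_values(
            ["chrom", "start"]).reset_index(drop=True)

    n = len(manifest)
    tracks["repeats"] = _random_track(
        ["LINE", "SINE", "LTR", "DNA"], max(n // 4, 4), 150, 2000
    )
    tracks["corsiv"] = _random_track(["CoRSIV"], max(n // 100, 2), 200, 600)
    tracks["ccre"] = _random_track(
        ["PLS", "pELS", "dELS"], max(n // 20, 3), 150, 350
    )
    tracks["tf_motifs"] = _random_track(
        [f"TF{i}" for i in range(8)], max(n // 10, 8), 10, 30
    )
    return tracks


def write_fixture(
    outdir,
    cfg: SimConfig,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    truth: SyntheticTruth,
    cell_ref: pd.DataFrame,
    tracks: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write a cohort to disk in the pipeline's input formats.

    Betas go to TSV at 6 decimals; sample sheet, manifest and cell
    reference to CSV; truth to JSON; tracks to BED3+name; the configuration
    to YAML. Round-trips losslessly through the ingest readers (at the
    stored precision).
    """
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["beta"] = out / "beta.tsv"
    beta.round(6).to_csv(paths["beta"], sep="\t", float_format="%.6f")
    paths["sheet"] = out / "samples.csv"
    sheet.to_csv(paths["sheet"], index=False)
    paths["manifest"] = out / "manifest.csv"
    manifest.to_csv(paths["manifest"], index=False)
    paths["cell_reference"] = out / "cell_reference.csv"
    cell_ref.to_csv(paths["cell_reference"])
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(truth.to_json())
    cfg_dict = asdict(cfg)
    cfg_dict["dirichlet_alpha"] = list(cfg_dict["dirichlet_alpha"])
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg_dict))
    if tracks:
        track_dir = out / "tracks"
        track_dir.mkdir(exist_ok=True)
        for name, track in tracks.items():
            p = track_dir / f"{name}.bed"
            track[["chrom", "start", "end", "name"]].to_csv(
                p, sep="\t", header=False, index=False
            )
            paths[f"track_{name}"] = p
    return paths


def simulate_fixture(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Generate a full cohort and write it as a ready-to-run fixture."""
    manifest = generate_manifest(cfg)
    beta, sheet, truth, ref = generate_cohort(cfg, manifest)
    tracks = generate_tracks(cfg, manifest)
    return write_fixture(outdir, cfg, beta, sheet, manifest, truth, ref, tracks)
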