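import numpy as np
import pandas as pd
import pytest

from twinewas.simulate import SimConfig, generate_cohort, generate_manifest


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Small but fully featured cohort configuration for unit tests."""
    return SimConfig(n_pairs=12, n_probes=1500, n_cell_probes=120,
                     n_dmrs=2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    manifest = generate_manifest(small_cfg)
    beta, sheet, truth, ref = generate_cohort(small_cfg, manifest)
    return {"cfg": small_cfg, "manifest": manifest, "beta": beta,
            "sheet": sheet, "truth": truth, "ref": ref}


@pytest.fixture()
def tiny_sheet() -> pd.DataFrame:
    """Three hand-written twin pairs."""
    rows = []
    for i, sex in enumerate(["F", "M", "F"]):
        for role in ("case", "control"):
            rows.append(
                {
                    "subject_id": f"p{i}_{role}",
                    "pair_id": f"p{i}",
                    "role": role,
                    "sex": sex,
                    "plate": "plate1" if role == "case" else "plate2",
                    "chip": "chip0",
                }
            )
    return pd.DataFrame(rows).set_index("subject_id", drop=False)


@pytest.fixture()
def tiny_beta(tiny_sheet) -> pd.DataFrame:
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.05, 0.95, size=(8, len(tiny_sheet)))
    return pd.DataFrame(
        vals,
        index=[f"cg{i:03d}" for i in range(8)],
        columns=tiny_sheet["subject_id"].tolist(),
    )
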