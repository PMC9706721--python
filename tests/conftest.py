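import numpy as np
import pandas as pd
import pytest

from bioturb.data_model import CountTable, MtdType, SampleInfo
from bioturb.synthetic_data import (
    SimConfig,
    generate_activities,
    generate_community,
    generate_design,
)


@pytest.fixture
def toy_table() -> CountTable:
    rng = np.random.default_rng(42)
    counts = rng.poisson(30, size=(8, 6))
    counts[0, :3] *= 5  # one taxon inflated in half the samples
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"asv{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(6)],
        )
    )


def make_meta(n_types=3, days=(3, 7, 15), reps=2):
    out = []
    types = ["DD", "CD", "PD"][:n_types]
    for t in types:
        for d in days:
            for r in range(1, reps + 1):
                out.append(
                    SampleInfo(
                        sample_id=f"{t}_d{d:02d}_r{r}",
                        mtd_type=MtdType(t),
                        day=d,
                        replicate=r,
                        temperature=30.0 + d,
                        moisture=0.4 - 0.01 * d,
                        acidity=1.0,
                        activities={"LA": 1.0, "SA": 1.0, "EA": 1.0, "FA": 1.0},
                    )
                )
    return out


@pytest.fixture
def toy_meta():
    return make_meta()


@pytest.fixture(scope="session")
def small_study():
    """One scaled-down synthetic study (shared, read-only)."""
    cfg = SimConfig(seed=11).small()
    design = generate_design(11)
    table, truth = generate_community(design, cfg)
    meta = generate_activities(design, table, truth, cfg)
    return {"config": cfg, "design": design, "table": table, "truth": truth,
            "meta": meta}
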