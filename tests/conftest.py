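import numpy as np
import pandas as pd
import pytest

from crossmask import (
    ChipLayout,
    IntensityMatrix,
    SampleDesign,
    SimParams,
    generate_dataset,
)


@pytest.fixture
def tiny_layout() -> ChipLayout:
    """Three probe sets (one tagged as a pathogen control), PM + MM probes."""
    pm = {
        "PSA": [f"PSA:{i:02d}" for i in range(1, 4)],
        "PSB": [f"PSB:{i:02d}" for i in range(1, 4)],
        "PSC": [f"PSC:{i:02d}" for i in range(1, 4)],
    }
    mm = {ps: [p + "m" for p in probes] for ps, probes in pm.items()}
    organism = {"PSA": "Glycine max", "PSB": "Glycine max", "PSC": "Phytophthora sojae"}
    return ChipLayout(pm_probes=pm, mm_probes=mm, organism=organism)


@pytest.fixture
def balanced_design() -> SampleDesign:
    """One species, 3 tissues x 3 replicates (Ts=9, R=3, S=3)."""
    rows = [
        {"sample_id": f"Pv_{t}_{r}", "species": "Pv", "tissue": t, "replicate": r}
        for t in ("nodule", "leaf", "root")
        for r in (1, 2, 3)
    ]
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100507 % 2**31)


@pytest.fixture
def random_matrix(tiny_layout, balanced_design, rng) -> IntensityMatrix:
    """Random positive intensities over the tiny layout's PM + MM probes."""
    probes = sorted(tiny_layout.all_probes)
    values = pd.DataFrame(
        rng.lognormal(5, 1, size=(len(probes), 9)),
        index=probes,
        columns=balanced_design.sample_ids,
    )
    return IntensityMatrix(values, balanced_design)


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-species dataset shared by non-acceptance tests."""
    return generate_dataset(SimParams(n_probesets=80, seed=7))
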