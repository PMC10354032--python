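import numpy as np
import pandas as pd
import pytest

import graftflow as gf

# one small but fully-featured simulation shared across the suite
SMALL_PARAMS = gf.SimulationParams(
    n_genes=400,
    n_mobile=40,
    n_deg_shared_nonmobile=20,
    n_deg_rootstock_only=60,
    n_deg_scion_only=20,
    genome_length=40_000,
    dispersion=0.08,
    seed=7,
)


@pytest.fixture(scope="session")
def small_params() -> gf.SimulationParams:
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_ds(small_params) -> gf.SimulatedDataset:
    return gf.simulate_dataset(small_params)


@pytest.fixture
def matrix_builder():
    """Build an ExpressionMatrix from per-gene stage-mean profiles.

    ``profiles`` maps gene id -> {(combination, tissue): [stage means]}.
    Each stage mean is replicated ``n_rep`` times (optionally jittered).
    """

    def build(profiles, stages=("CA", "DW", "DA"), n_rep=2, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cells = sorted({ct for prof in profiles.values() for ct in prof})
        columns, records = [], []
        for comb, tissue in cells:
            for stage in stages:
                for r in range(1, n_rep + 1):
                    columns.append(f"{comb}_{tissue}_{stage}_R{r}")
                    records.append((comb, tissue, stage, r))
        data = []
        for gene, prof in profiles.items():
            row = []
            for comb, tissue in cells:
                for si in range(len(stages)):
                    base = prof[(comb, tissue)][si]
                    for _ in range(n_rep):
                        v = base * (1 + jitter * rng.standard_normal()) if jitter else base
                        row.append(max(v, 0.0))
            data.append(row)
        values = pd.DataFrame(data, index=pd.Index(list(profiles), name="gene_id"), columns=columns)
        sheet = pd.DataFrame(records, index=columns,
                             columns=["combination", "tissue", "stage", "replicate"])
        sheet.index.name = "sample_id"
        return gf.ExpressionMatrix(values, sheet, stages=tuple(stages))

    return build
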