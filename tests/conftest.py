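import numpy as np
import pytest

from cormclust import ExpressionDataset, Observation


def make_dataset(
    G=3,
    conditions=("WT", "SM"),
    replicates=2,
    times=(0.0, 5.0, 10.0),
    seed=0,
    fill=None,
):
    """Small complete dataset with deterministic or random values."""
    obs = sorted(
        Observation(c, f"r{r + 1}", float(t))
        for c in conditions
        for r in range(replicates)
        for t in times
    )
    rng = np.random.default_rng(seed)
    if fill is None:
        values = rng.normal(size=(G, len(obs)))
    else:
        values = np.full((G, len(obs)), float(fill))
    return ExpressionDataset(
        [f"g{i + 1}" for i in range(G)], obs, values, np.ones((G, len(obs)), bool)
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


def long_table_text(rows, header="gene\tcondition\treplicate\ttime\tvalue"):
    return header + "\n" + "\n".join("\t".join(str(v) for v in r) for r in rows) + "\n"
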