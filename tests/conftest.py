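import numpy as np
import pandas as pd
import pytest

from genefabric import ProbeTable, SyntheticSpec, generate_dataset, gene_profiles

# The four illustrative genes: same AVE, different variability/coordination.
QUADRUPLES = {
    "A": [96.0, 98.0, 102.0, 104.0],
    "B": [87.0, 83.0, 110.0, 120.0],
    "C": [105.0, 102.0, 98.0, 95.0],
    "D": [103.0, 97.0, 97.0, 103.0],
}


def make_table(gene_values: dict[str, list[float]], conditions: dict[str, int] | None = None) -> ProbeTable:
    """Build a one-spot-per-gene ProbeTable; values repeat per condition."""
    conditions = conditions or {"CO": 4}
    cols, data = [], {}
    for cond, nrep in conditions.items():
        for j in range(nrep):
            cols.append(f"{cond}_r{j + 1}")
    values = pd.DataFrame(
        {g: vals for g, vals in gene_values.items()}
    ).T
    values.columns = cols
    values.index = pd.Index([f"{g}_s1" for g in gene_values], name="spot")
    return ProbeTable(
        values=values,
        gene_of_spot=pd.Series(list(gene_values), index=values.index, name="gene"),
        replicate_columns={
            c: [f"{c}_r{j + 1}" for j in range(n)] for c, n in conditions.items()
        },
    )


@pytest.fixture(scope="session")
def toy_table() -> ProbeTable:
    """The four-gene quadruple table, one condition, one spot per gene."""
    return make_table(QUADRUPLES)


@pytest.fixture(scope="session")
def toy_profiles(toy_table):
    return gene_profiles(toy_table, "CO")


@pytest.fixture(scope="session")
def small_synthetic():
    """A small 4-condition synthetic dataset with planted structure."""
    spec = SyntheticSpec(n_genes=60, seed=11)
    return generate_dataset(spec)


def brute_pearson(a, b) -> float:
    """Textbook Pearson coefficient, independent of numpy.corrcoef."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, db = a - a.mean(), b - b.mean()
    return float((da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum()))
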