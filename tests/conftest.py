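import numpy as np
import pandas as pd
import pytest

from dysreg.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def two_group_expr():
    """Small two-condition expression matrix with a few DE genes."""
    rng = np.random.default_rng(7)
    n1 = n2 = 8
    genes = [f"g{i}" for i in range(60)]
    a = rng.normal(6, 0.5, (60, n1))
    b = rng.normal(6, 0.5, (60, n2))
    b[:5] += 2.5          # clear DE
    cols = [f"N{i}" for i in range(n1)] + [f"T{i}" for i in range(n2)]
    values = pd.DataFrame(np.hstack([a, b]), index=genes, columns=cols)
    cond = pd.Series(["normal"] * n1 + ["tumor"] * n2, index=cols)
    pairing = {f"T{i}": f"N{i}" for i in range(n1)}
    return ExpressionMatrix(values, cond, pairing)


@pytest.fixture(scope="session")
def survival_cohort():
    """A 200-sample tumor cohort with one truly prognostic gene (g0)."""
    rng = np.random.default_rng(11)
    n, ngen = 200, 60
    genes = [f"g{i}" for i in range(ngen)]
    values = pd.DataFrame(rng.standard_normal((ngen, n)) + 6, index=genes,
                          columns=[f"S{i}" for i in range(n)])
    expr = ExpressionMatrix(values, pd.Series("tumor", index=values.columns))
    eta = 1.0 * (values.loc["g0"] - values.loc["g0"].mean()).to_numpy()
    T = rng.exponential(np.exp(-eta)) * 5
    C = rng.uniform(0, 12, n)
    clinical = pd.DataFrame({
        "sample": values.columns,
        "os_time": np.minimum(T, C), "os_event": (T <= C).astype(int),
        "rfs_time": np.minimum(T, C), "rfs_event": (T <= C).astype(int),
        "age": rng.normal(65, 10, n).round(1), "gender": rng.integers(0, 2, n),
        "stage": rng.choice([1, 2, 3, 4], n), "adjc": rng.integers(0, 2, n),
        "adjc_type": "",
    }).set_index("sample")
    return expr, clinical
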