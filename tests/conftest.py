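import numpy as np
import pandas as pd
import pytest

from seednet import SimConfig, fit_region_expression, generate


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(
        n_genes=80, n_seed=10, n_brains=3,
        regions_per_structure={"cerebrum_late": 12, "cerebellum": 8},
        samples_per_region_per_brain=2,
        seed_module_loading={"cerebrum_late": 0.7, "cerebellum": 0.0},
        n_signal_genes=5, frac_ad_phenotype=0.4, rng_seed=42)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return generate(tiny_config)


@pytest.fixture(scope="session")
def tiny_region_expr(tiny_study):
    return fit_region_expression(tiny_study.expression, tiny_study.annotations)


@pytest.fixture()
def small_annotations() -> pd.DataFrame:
    rows = []
    for b in ("B1", "B2"):
        for r, mid, high in (("r1", "m1", "cerebrum"), ("r2", "m1", "cerebrum"),
                             ("r3", "m2", "cerebellum")):
            for k in (1, 2):
                rows.append((f"{b}_{r}_{k}", b, high, mid, r))
    return (pd.DataFrame(rows, columns=["sample_id", "brain_id",
                                        "structure_high", "structure_mid",
                                        "region_low"])
            .set_index("sample_id"))


@pytest.fixture()
def small_expression(small_annotations) -> pd.DataFrame:
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.normal(5, 1, (6, len(small_annotations))),
                        index=[f"g{i}" for i in range(6)],
                        columns=small_annotations.index)


# --- independent brute-force oracles -------------------------------------

def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float); y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def rank_desc_brute(values, target) -> float:
    """Average descending rank of ``target`` within ``values`` (incl. target)."""
    greater = sum(1 for v in values if v > target)
    equal = sum(1 for v in values if v == target)
    return greater + (equal + 1) / 2.0


def bh_brute(p, m=None):
    """Textbook step-up: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    p = list(p)
    m = m or len(p)
    order = sorted(range(len(p)), key=lambda i: p[i])
    q = [0.0] * len(p)
    for pos, i in enumerate(order):
        q[i] = min(min(1.0, m * p[order[j]] / (j + 1))
                   for j in range(pos, len(order)))
    return np.array(q)
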