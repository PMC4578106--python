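import pandas as pd
import pytest

from cmzcycle import CycleParams
from cmzcycle import counts_norm as cn


@pytest.fixture
def control_params() -> CycleParams:
    """Deterministic control-like cycle: T_C = 20 h, GF = 0.8."""
    return CycleParams(gf=0.8, t_g1=12.5, t_s=4.0, t_g2=2.5, t_m=1.0,
                       cv=0.0, n_cells=10_000)


@pytest.fixture
def small_codeset():
    """A tiny count matrix with the worked-example negatives and two lanes
    where lane B doubles lane A."""
    probes = [f"NEG{i}" for i in range(8)] + [f"POS{i}" for i in range(3)] + \
             ["HK0", "HK1", "HK2"] + ["G0", "G1"]
    cls = pd.Series(["negative"] * 8 + ["positive"] * 3 + ["housekeeping"] * 3
                    + ["endogenous"] * 2, index=pd.Index(probes))
    a = pd.Series([5, 7, 6, 8, 6, 7, 5, 6] + [1000, 500, 250] + [800, 400, 200]
                  + [20, 150], index=pd.Index(probes), dtype=float)
    counts = pd.DataFrame({"A": a, "B": 2 * a})
    lane_condition = pd.Series({"A": "ctrl", "B": "ctrl"})
    return cn.CountMatrix(counts=counts, probe_class=cls,
                          lane_condition=lane_condition)
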