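import numpy as np
import pytest

from mmcompare.multi import PerformanceMatrix
from mmcompare.simulate import demo_screen_pair

# 3 methods x 5 systems benchmark grid with method means 0.580 / 0.754 / 0.748
BENCH_A = [0.60, 0.65, 0.70, 0.45, 0.50]
BENCH_B = [0.81, 0.75, 0.72, 0.69, 0.80]
BENCH_C = [0.74, 0.70, 0.85, 0.70, 0.75]

# Two p-value families tested against a common reference method
PFAMILY_1 = {"B": 0.02, "C": 0.005, "D": 0.01, "E": 0.03, "F": 0.008}
PFAMILY_2 = {"B": 0.01, "C": 0.025, "D": 0.005, "E": 0.03, "F": 0.015}


@pytest.fixture
def bench_matrix() -> PerformanceMatrix:
    return PerformanceMatrix(
        ("A", "B", "C"),
        ("s1", "s2", "s3", "s4", "s5"),
        np.array([BENCH_A, BENCH_B, BENCH_C]),
    )


@pytest.fixture
def screen_pair():
    return demo_screen_pair()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160304)
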