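import numpy as np
import pandas as pd
import pytest

from hpapredict.datatypes import DataType, DifferentialCalls, MarkerMatrix, MatingDesign, TraitTable
from hpapredict.differential import call_differential
from hpapredict.simulate import SimulationConfig, simulate_dataset


def make_calls(array, hybrids, markers=None, data_type="sRNA"):
    """Boolean DifferentialCalls from a plain array and (flint, dent) pairs."""
    array = np.asarray(array, dtype=bool)
    markers = markers or [f"m{i}" for i in range(array.shape[1])]
    idx = pd.MultiIndex.from_tuples(hybrids, names=["flint", "dent"])
    return DifferentialCalls(data_type, pd.DataFrame(array, index=idx, columns=markers))


def make_traits(values, hybrids, name="GY"):
    idx = pd.MultiIndex.from_tuples(hybrids, names=["flint", "dent"])
    return TraitTable(name, pd.Series(np.asarray(values, float), index=idx))


@pytest.fixture(scope="session")
def small_design():
    return MatingDesign.full_factorial(["F1", "F2", "F3"], ["D1", "D2", "D3", "D4"])


@pytest.fixture(scope="session")
def default_dataset():
    """One study-shaped synthetic dataset shared across tests (seed 1)."""
    mats, design, traits, truth = simulate_dataset(SimulationConfig(seed=1))
    calls = call_differential(mats["sRNA"], design)
    return {"matrices": mats, "design": design, "traits": traits, "truth": truth, "calls": calls}
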