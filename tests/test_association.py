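import numpy as np
import pandas as pd
import pytest

from conftest import make_calls, make_traits
from hpapredict.association import (
    BinomialTraitAssociation,
    association_table,
    binomial_association,
    fdr_select,
    permutation_test,
    split_classes,
)
from hpapredict.datatypes import ValidationError
from hpapredict.simulate import SimulationConfig, simulate_dataset
from hpapredict.differential import call_differential


def _hybrids(n):
    return [("F1", f"D{i:02d}") for i in range(n)]


def _split_with_counts(o_l, o_h, class_size=12):
    """Calls and split realizing the given per-class differential counts."""
    hybrids = _hybrids(2 * class_size)
    col = [i < o_l for i in range(class_size)] + [i < o_h for i in range(class_size)]
    calls = make_calls(np.array(col)[:, None], hybrids)
    traits = make_traits(
        [0.0] * class_size + [1.0] * class_size, hybrids
    )
    split = split_classes(traits, hybrids)
    return calls, split


def test_split_even_and_odd():
    hybrids = _hybrids(4)
    traits = make_traits([1, 2, 3, 4], hybrids)
    split = split_classes(traits, hybrids)
    assert split.low == hybrids[:2] and split.high == hybrids[2:]
    hybrids5 = _hybrids(5)
    split5 = split_classes(make_traits([5, 3, 1, 2, 4], hybrids5), hybrids5)
    assert len(split5.low) == len(split5.high) == 2
    # sorted order is h2(1), h3(2), h1(3), h4(4), h0(5): median hybrid excluded
    assert split5.excluded == [hybrids5[1]]
    assert split5.low == [hybrids5[2], hybrids5[3]]
    assert split5.high == [hybrids5[4], hybrids5[0]]


def test_split_tie_break_deterministic():
    hybrids = _hybrids(4)
    traits = make_traits([7, 7, 7, 7], hybrids)
    s1 = split_classes(traits, hybrids)
    s2 = split_classes(traits, hybrids)
    assert s1.low == s2.low == hybrids[:2]  # lexicographic id order


def test_split_requires_two_hybrids():
    with pytest.raises(ValidationError):
        split_classes(make_traits([1.0], _hybrids(1)), _hybrids(1))


def test_binomial_tail_examples():
    calls, split = _split_with_counts(0, 10)
    rec = binomial_association(calls, split, "m0")
    assert rec["o_L"] == 0 and rec["o_H"] == 10 and rec["k_min"] == 10
    assert rec["p_value"] == pytest.approx(0.5**10)
    assert rec["direction"] == "positive"

    calls, split = _split_with_counts(5, 5)
    rec = binomial_association(calls, split, "m0")
    assert rec["p_value"] == pytest.approx(638 / 1024)
    assert rec["direction"] == "negative"  # tie labelled by the o_L <= o_H branch


def test_binomial_no_evidence():
    calls, split = _split_with_counts(3, 0)
    table = association_table(calls, split)
    assert table.loc["m0", "p_value"] == pytest.approx(0.5**3)
    with pytest.raises(ValidationError):
        binomial_association(calls, split, "not_a_marker")


def test_swapping_classes_swaps_direction_keeps_p():
    calls, split = _split_with_counts(2, 9)
    rec = association_table(calls, split).loc["m0"]
    swapped = type(split)(low=split.high, high=split.low, excluded=split.excluded)
    rec_sw = association_table(calls, swapped).loc["m0"]
    assert rec["p_value"] == rec_sw["p_value"]
    assert {rec["direction"], rec_sw["direction"]} == {"positive", "negative"}


def test_fdr_select_printed_example():
    records = pd.DataFrame(
        {
            "p_value": [0.01, 0.02, 0.04, 0.5],
            "direction": ["positive", "negative", "positive", "negative"],
            "o_L": 0, "o_H": 0, "n": 0, "k_min": 0,
        },
        index=pd.Index(["a", "b", "c", "d"], name="marker"),
    )
    result = fdr_select(records, level=0.05)
    assert set(result.positive) | set(result.negative) == {"a", "b"}
    assert result.positive == ["a"] and result.negative == ["b"]


def test_fdr_single_and_all_null():
    one = pd.DataFrame({"p_value": [0.04], "direction": ["positive"]},
                       index=pd.Index(["a"], name="marker"))
    res = fdr_select(one, level=0.05)
    assert res.positive == ["a"]
    nul = pd.DataFrame({"p_value": [1.0, 1.0], "direction": ["positive", "negative"]},
                       index=pd.Index(["a", "b"], name="marker"))
    res = fdr_select(nul, level=0.05)
    assert res.n_positive == res.n_negative == 0


def test_direction_convention_switch():
    calls, split = _split_with_counts(9, 1)
    records = association_table(calls, split)
    default = fdr_select(records, level=0.05)
    swapped = fdr_select(records, level=0.05, direction_convention="low_enriched")
    assert default.negative == ["m0"] and swapped.positive == ["m0"]


def test_permutation_determinism_and_config():
    rng = np.random.default_rng(3)
    hybrids = _hybrids(12)
    calls = make_calls(rng.random((12, 30)) < 0.4, hybrids)
    traits = make_traits(rng.normal(size=12), hybrids)
    p1 = permutation_test(calls, traits, n_perm=10, seed=5)
    p2 = permutation_test(calls, traits, n_perm=10, seed=5)
    pd.testing.assert_frame_equal(p1, p2)
    assert len(p1) == 10 and (p1["min_p"] > 0).all()
    with pytest.raises(ValidationError):
        permutation_test(calls, traits, n_perm=0, seed=5)


def test_null_pvalues_superuniform():
    """Under exchangeable traits the binomial tail p-values are conservative."""
    rng = np.random.default_rng(8)
    hybrids = [(f"F{i}", f"D{j}") for i in range(7) for j in range(14)]
    calls = make_calls(rng.random((98, 1000)) < 0.3, hybrids)
    traits = make_traits(rng.normal(size=98), hybrids)
    split = split_classes(traits, hybrids)
    p = association_table(calls, split)["p_value"].to_numpy()
    for t in (0.001, 0.01, 0.05, 0.2):
        frac = (p <= t).mean()
        se = np.sqrt(t * (1 - t) / len(p))
        assert frac <= t + 4 * se


def test_null_generator_yields_no_associations():
    """Pure-noise datasets produce 0 FDR hits in nearly all seeds (scaled down)."""
    n_hits = 0
    for seed in range(15):
        cfg = SimulationConfig(seed=seed, n_pos_planted=0, n_neg_planted=0,
                               n_snp=50, n_mrna=50, n_srna=800)
        mats, design, traits, _ = simulate_dataset(cfg)
        calls = call_differential(mats["sRNA"], design)
        split = split_classes(traits, calls.hybrids)
        res = fdr_select(association_table(calls, split))
        n_hits += (res.n_positive + res.n_negative) > 0
    assert n_hits <= 1  # >= 95% of seeds clean


def test_estimator_fit_support(default_dataset):
    calls, traits = default_dataset["calls"], default_dataset["traits"]
    est = BinomialTraitAssociation().fit(
        calls, traits.values.loc[calls.calls.index].to_numpy()
    )
    assert set(est.positive_).isdisjoint(est.negative_)
    mask = est.get_support()
    assert mask.sum() == len(est.positive_) + len(est.negative_)
    assert est.transform(calls).shape[1] == mask.sum()
    assert est.get_params()["fdr_level"] == 0.05
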