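"""Unit tests for the shared NB count engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from thermomethyl import core_stats as cs

from conftest import DESIGN6, SIX, nb_matrix


# ---------------------------------------------------------------- helpers

def brute_force_conditional_p(k_c, k_t, n_c, n_t, dispersion):
    """Independent oracle: full enumeration of the conditional split.

    Uses log-gamma NB pmfs written from the textbook formula (no scipy),
    equal unit size factors, group-sum dispersion phi/n.
    """
    total = k_c + k_t

    def logpmf(k, mean, phi_group):
        if phi_group == 0:
            return k * math.log(mean) - mean - math.lgamma(k + 1)
        r = 1.0 / phi_group
        return (
            math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(r / (r + mean)) + k * math.log(mean / (r + mean))
        )

    mu_c = total * n_c / (n_c + n_t)
    mu_t = total * n_t / (n_c + n_t)
    logs = [
        logpmf(a, mu_c, dispersion / n_c) + logpmf(total - a, mu_t, dispersion / n_t)
        for a in range(total + 1)
    ]
    mx = max(logs)
    probs = np.exp(np.array(logs) - mx)
    probs /= probs.sum()
    lo = probs[: k_c + 1].sum()
    hi = probs[k_c:].sum()
    return min(1.0, 2.0 * min(lo, hi))


def unit_factors():
    return pd.Series(1.0, index=SIX)


# ------------------------------------------------------------ size factors

def test_size_factors_doubled_sample():
    df = pd.DataFrame({"A": [10, 20, 30, 5], "B": [20, 40, 60, 10]})
    f = cs.estimate_size_factors(df).size_factors
    assert f["A"] == pytest.approx(1 / math.sqrt(2), abs=1e-4)
    assert f["B"] == pytest.approx(math.sqrt(2), abs=1e-4)


def test_size_factors_identical_samples():
    df = pd.DataFrame({s: [3, 8, 1, 9] for s in SIX})
    assert np.allclose(cs.estimate_size_factors(df).size_factors, 1.0)


def test_size_factors_single_feature_closed_form():
    df = pd.DataFrame([[5, 10, 20]], columns=["a", "b", "c"])
    f = cs.estimate_size_factors(df).size_factors
    geo = (5 * 10 * 20) ** (1 / 3)
    assert np.allclose(f, np.array([5, 10, 20]) / geo)


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.poisson(20, size=(100, 4)), columns=list("wxyz")) + 1
    base = cs.estimate_size_factors(df).size_factors
    scaled = df.copy()
    scaled["x"] *= 3
    f = cs.estimate_size_factors(scaled).size_factors
    # factors are defined against the geometric-mean reference, so the
    # equivariance is a ratio property: x gains a factor 3 relative to the
    # untouched samples, and untouched samples keep their relative factors
    assert f["x"] / f["w"] == pytest.approx(3 * base["x"] / base["w"], rel=1e-12)
    assert f["y"] / f["w"] == pytest.approx(base["y"] / base["w"], rel=1e-12)


def test_size_factors_all_zero_errors():
    with pytest.raises(cs.DegenerateDataError, match="no usable features"):
        cs.estimate_size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


def test_size_factors_normalized_identity():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.poisson(15, size=(60, 3)) + 1, columns=list("abc"))
    res = cs.estimate_size_factors(df)
    assert np.allclose(res.normalized, df / res.size_factors)


# ------------------------------------------------------------- dispersion

def test_dispersion_poisson_is_near_zero():
    rng = np.random.default_rng(2)
    df, design = nb_matrix(rng, 2000, mean=50, dispersion=0.0)
    m = cs.CountMatrix(df, design)
    phi = cs.estimate_common_dispersion(m, cs.estimate_size_factors(df).size_factors)
    assert abs(phi) < 0.05


def test_dispersion_recovers_truth():
    rng = np.random.default_rng(3)
    df, design = nb_matrix(rng, 2000, mean=50, dispersion=0.2)
    m = cs.CountMatrix(df, design)
    phi = cs.estimate_common_dispersion(m, cs.estimate_size_factors(df).size_factors)
    assert 0.1 <= phi <= 0.3


def test_dispersion_constant_counts_zero():
    df = pd.DataFrame({s: [7, 7, 7] for s in SIX})
    m = cs.CountMatrix(df, DESIGN6)
    assert cs.estimate_common_dispersion(m, unit_factors()) == 0.0


def test_dispersion_unreplicated_errors():
    df = pd.DataFrame({"a": [5], "b": [9]})
    m = cs.CountMatrix(df, {"a": "control", "b": "treatment"})
    with pytest.raises(cs.DegenerateDataError, match="not estimable"):
        cs.estimate_common_dispersion(m, pd.Series(1.0, index=["a", "b"]))


# ------------------------------------------------------------- exact test

def test_exact_test_symmetric_groups():
    counts = pd.Series([4, 5, 6, 6, 5, 4], index=SIX)
    lfc, p = cs.nb_exact_test(counts, DESIGN6, unit_factors(), 0.1)
    assert lfc == 0.0
    assert p == 1.0


def test_exact_test_all_zero():
    counts = pd.Series(0, index=SIX)
    lfc, p = cs.nb_exact_test(counts, DESIGN6, unit_factors(), 0.0)
    assert (lfc, p) == (0.0, 1.0)


@pytest.mark.parametrize("dispersion", [0.0, 0.1, 0.5])
@pytest.mark.parametrize(
    "ctrl,trt",
    [((0, 1, 1), (6, 6, 6)), ((3, 3, 4), (1, 2, 2)), ((0, 0, 0), (5, 7, 8))],
)
def test_exact_test_matches_enumeration_oracle(ctrl, trt, dispersion):
    """Windowed implementation equals full-range enumeration (totals <= 40)."""
    counts = pd.Series(list(ctrl) + list(trt), index=SIX)
    _, p = cs.nb_exact_test(counts, DESIGN6, unit_factors(), dispersion)
    expected = brute_force_conditional_p(sum(ctrl), sum(trt), 3, 3, dispersion)
    assert p == pytest.approx(expected, rel=1e-9)


def test_exact_test_poisson_case_is_binomial():
    """phi=0 with equal sizes: the split of 20 is Binomial(20, 1/2)."""
    from scipy.stats import binom

    counts = pd.Series([1, 1, 0, 6, 6, 6], index=SIX)
    _, p = cs.nb_exact_test(counts, DESIGN6, unit_factors(), 0.0)
    oracle = min(1.0, 2 * min(binom.cdf(2, 20, 0.5), binom.sf(1, 20, 0.5)))
    assert p == pytest.approx(oracle, rel=1e-9)


def test_exact_test_log2fc_pseudocount():
    counts = pd.Series([10, 10, 10, 40, 40, 40], index=SIX)
    lfc, _ = cs.nb_exact_test(counts, DESIGN6, unit_factors(), 0.0)
    assert lfc == pytest.approx(math.log2(40.5 / 10.5))


def test_exact_test_negative_counts_error():
    counts = pd.Series([1, -2, 3, 4, 5, 6], index=SIX)
    with pytest.raises(ValueError, match="negative"):
        cs.nb_exact_test(counts, DESIGN6, unit_factors(), 0.0)


def test_null_type_i_error_calibrated():
    rng = np.random.default_rng(7)
    df, design = nb_matrix(rng, 2000, mean=10, dispersion=0.2)
    res = cs.run_differential(cs.CountMatrix(df, design))
    frac = float((res["p_value"] < 0.05).mean())
    assert 0.03 <= frac <= 0.07


# ---------------------------------------------------------------------- BH

def test_bh_hand_example():
    assert np.allclose(cs.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_trivial_cases():
    assert np.allclose(cs.bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert np.allclose(cs.bh_adjust([0.2]), [0.2])
    assert cs.bh_adjust([]).size == 0


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cs.bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        cs.bh_adjust([-0.1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
             max_size=40)
)
def test_bh_matches_reference_and_permutation_invariant(p):
    q = cs.bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, ref)
    perm = np.random.default_rng(0).permutation(len(p))
    assert np.allclose(cs.bh_adjust(np.asarray(p)[perm]), q[perm])


# --------------------------------------------------------- hypergeometric

def test_hypergeometric_enumeration_example():
    assert cs.hypergeometric_tail(10, 5, 4, 4) == pytest.approx(5 / 210)


def test_hypergeometric_trivial_tails():
    assert cs.hypergeometric_tail(10, 5, 4, 0) == 1.0
    assert cs.hypergeometric_tail(8, 8, 3, 3) == 1.0


def test_hypergeometric_inconsistent_errors():
    with pytest.raises(ValueError, match="inconsistent"):
        cs.hypergeometric_tail(10, 12, 4, 2)
    with pytest.raises(ValueError, match="inconsistent"):
        cs.hypergeometric_tail(10, 5, 4, 5)


# ---------------------------------------------------------------- Pearson

def test_pearson_perfect_lines():
    x = np.array([1.0, 2, 3, 4, 5])
    assert cs.pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert cs.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_hand_value():
    r, p = cs.pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)
    assert 0 < p < 1


def test_pearson_zero_variance_errors():
    with pytest.raises(cs.DegenerateDataError, match="zero variance"):
        cs.pearson_correlation([1, 1, 1], [1, 2, 3])


# --------------------------------------------------------- run_differential

def test_run_differential_direction_consistency():
    rng = np.random.default_rng(8)
    df, design = nb_matrix(rng, 200, mean=30, dispersion=0.1)
    df.iloc[:20] = np.column_stack(
        [df.iloc[:20, :3].to_numpy(), df.iloc[:20, 3:].to_numpy() * 8]
    )
    res = cs.run_differential(cs.CountMatrix(df, design))
    sig = res[res["significant"]]
    assert ((sig["log2fc"] > 0) == (sig["direction"] == "up")).all()
    assert (res.loc[~res["significant"], "direction"] == "none").all()
    assert (res["q_value"] >= res["p_value"] - 1e-12).all()
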