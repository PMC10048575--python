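"""PSI estimation, the marginal binomial/logit-normal fit, the LRT and BH."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import binom as sp_binom

from exonskip.model import (
    DifferentialSplicing,
    bh_fdr,
    fit_group,
    lrt_differential,
    normalized_inclusion,
    psi_point_estimate,
    replicate_loglik,
)

from _oracles import bh_adjust, grid_fit_oracle, grid_lrt_oracle

# ---------------------------------------------------------------- psi / f ---


def test_psi_hand_example(lengths):
    assert psi_point_estimate(10, 10, lengths) == pytest.approx(1 / 3, abs=1e-12)


def test_psi_boundaries_and_missing(lengths):
    assert psi_point_estimate(5, 0, lengths) == 1.0
    assert psi_point_estimate(0, 7, lengths) == 0.0
    assert math.isnan(psi_point_estimate(0, 0, lengths))


def test_normalized_inclusion_examples(lengths):
    assert normalized_inclusion(0.0, lengths) == 0.0
    assert normalized_inclusion(1.0, lengths) == 1.0
    assert normalized_inclusion(0.5, lengths) == pytest.approx(2 / 3, abs=1e-12)


@given(I=st.integers(0, 500), S=st.integers(0, 500))
@settings(max_examples=200, deadline=None)
def test_psi_and_f_are_inverse_linked(I, S, lengths):
    # f(psi_hat(I, S)) recovers the raw read proportion I / (I + S) exactly.
    if I + S == 0:
        return
    psi = psi_point_estimate(I, S, lengths)
    assert normalized_inclusion(psi, lengths) == pytest.approx(I / (I + S), abs=1e-10)


@given(I=st.integers(1, 300), S=st.integers(1, 300))
@settings(max_examples=100, deadline=None)
def test_psi_monotone_in_counts(I, S, lengths):
    psi = psi_point_estimate(I, S, lengths)
    assert psi_point_estimate(I + 1, S, lengths) > psi
    assert psi_point_estimate(I, S + 1, lengths) < psi


# --------------------------------------------------------- replicate loglik ---


def test_replicate_loglik_closed_form(lengths):
    # With f = 0.5 (psi giving equal normalized rates): log C(2I, I) + 2I log 0.5.
    I = 12
    psi_half = psi_point_estimate(I, I, lengths)  # f(psi) = 0.5 at I = S
    ll = replicate_loglik(I, I, 0.5, lengths)
    assert normalized_inclusion(0.5, lengths) == pytest.approx(2 / 3)
    expected = sp_binom.logpmf(I, 2 * I, normalized_inclusion(0.5, lengths))
    assert ll == pytest.approx(float(expected), abs=1e-10)
    # psi chosen so f = 0.5 gives the symmetric closed form
    ll_half = replicate_loglik(I, I, psi_half, lengths)
    assert ll_half == pytest.approx(
        math.lgamma(2 * I + 1) - 2 * math.lgamma(I + 1) + 2 * I * math.log(0.5), abs=1e-10
    )


def test_replicate_loglik_empty_and_impossible(lengths):
    assert replicate_loglik(0, 0, 0.5, lengths) == 0.0
    assert replicate_loglik(10, 3, 1.0, lengths) <= -1e11  # capped, not -inf
    assert np.isfinite(replicate_loglik(10, 3, 1.0, lengths))


# ------------------------------------------------------------- group fit ---


def test_fit_group_identical_replicates(lengths):
    # psi_hat = (20/68)/((20/68)+(10/34)) = 0.5 exactly; no overdispersion.
    fit = fit_group([20, 20, 20], [10, 10, 10], lengths, sigma_floor=0.01)
    assert fit.psi == pytest.approx(0.5, abs=1e-3)
    assert fit.mu == pytest.approx(0.0, abs=5e-3)
    assert fit.sigma == pytest.approx(0.01, abs=1e-9)


def test_fit_group_single_replicate(lengths):
    fit = fit_group([20], [10], lengths, sigma_floor=0.01)
    assert fit.psi == pytest.approx(0.5, abs=1e-3)
    assert fit.sigma == pytest.approx(0.01, abs=1e-9)
    assert fit.n_replicates == 1


def test_fit_group_drops_empty_replicates(lengths):
    fit = fit_group([20, 0], [10, 0], lengths)
    assert fit.n_replicates == 1
    with pytest.raises(ValueError):
        fit_group([0, 0], [0, 0], lengths)


def test_fit_group_matches_grid_search_oracle(lengths):
    I, S = [30, 22, 26], [10, 18, 12]
    fit = fit_group(I, S, lengths, sigma_floor=0.01)
    mu_grid = np.arange(-1.0, 1.0001, 0.02)
    sigma_grid = np.concatenate([[0.01], np.arange(0.05, 1.0001, 0.05)])
    oracle = grid_fit_oracle(I, S, lengths.l_inclusion, lengths.l_skip, mu_grid, sigma_grid)
    assert fit.mu == pytest.approx(oracle["mu"], abs=0.02)
    assert fit.sigma == pytest.approx(oracle["sigma"], abs=0.05)
    assert fit.loglik >= oracle["loglik"] - 1e-3


# ------------------------------------------------------------------- LRT ---


def test_lrt_identical_groups_is_null(lengths):
    res = lrt_differential([20, 25], [10, 12], [20, 25], [10, 12], lengths, e=0.01)
    assert res.lrt_stat == pytest.approx(0.0, abs=1e-8)
    assert res.p_value == pytest.approx(1.0)


def test_lrt_within_e_threshold_is_null(lengths):
    # delta psi well under e = 0.5 -> H0 contains the MLE.
    res = lrt_differential([20, 21], [10, 10], [21, 20], [10, 11], lengths, e=0.5)
    assert res.lrt_stat == 0.0


def test_lrt_group_relabeling_flips_delta_only(lengths):
    I1, S1 = [40, 38, 45], [5, 8, 6]
    I2, S2 = [10, 12, 9], [30, 28, 33]
    a = lrt_differential(I1, S1, I2, S2, lengths, e=0.01)
    b = lrt_differential(I2, S2, I1, S1, lengths, e=0.01)
    assert a.lrt_stat == pytest.approx(b.lrt_stat, rel=1e-6, abs=1e-8)
    assert a.delta_psi == pytest.approx(-b.delta_psi, abs=1e-8)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-6, abs=1e-12)


def test_lrt_matches_grid_search_oracle(lengths):
    I1, S1 = [35, 40], [10, 8]
    I2, S2 = [15, 12], [25, 30]
    res = lrt_differential(I1, S1, I2, S2, lengths, e=0.01, sigma_floor=0.01)
    mu_grid = np.arange(-2.0, 2.0001, 0.05)
    sigma_grid = np.concatenate([[0.01], np.arange(0.05, 1.0001, 0.05)])
    oracle = grid_lrt_oracle(
        I1, S1, I2, S2, lengths.l_inclusion, lengths.l_skip, 0.01, mu_grid, sigma_grid
    )
    # Grid resolution limits the oracle; agree within a loose LRT-scale bound.
    assert res.lrt_stat == pytest.approx(oracle["stat"], abs=0.5)
    assert res.lrt_stat >= oracle["stat"] - 0.5


def test_lrt_strong_separation_is_significant(lengths):
    rng = np.random.default_rng(3)

    def draw(psi, n=6, cov=100):
        z = rng.normal(math.log(psi / (1 - psi)), 0.1, size=n)
        f = normalized_inclusion(expit(z), lengths)
        N = rng.poisson(cov, size=n)
        I = rng.binomial(N, f)
        return I, N - I

    I1, S1 = draw(0.1)
    I2, S2 = draw(0.9)
    res = lrt_differential(I1, S1, I2, S2, lengths, e=0.01)
    assert res.p_value < 1e-4


def test_lrt_rejects_invalid_e(lengths):
    with pytest.raises(ValueError):
        lrt_differential([1], [1], [1], [1], lengths, e=1.5)


# -------------------------------------------------------------------- BH ---


def test_bh_known_example():
    assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_degenerate_inputs():
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
@settings(max_examples=100, deadline=None)
def test_bh_matches_textbook_oracle(ps):
    assert bh_fdr(ps) == pytest.approx(bh_adjust(ps), abs=1e-12)


# ----------------------------------------------------------- model object ---


def _toy_counts():
    import pandas as pd

    rows = []
    for ev, (i1, i2) in {"evA": (40, 10), "evB": (20, 20)}.items():
        for r in range(3):
            rows.append({"event_id": ev, "sample_id": f"c{r}", "I": i1 + r, "S": 10})
            rows.append({"event_id": ev, "sample_id": f"t{r}", "I": i2 + r, "S": 10})
    return pd.DataFrame(rows)


def test_model_fit_produces_results_table(lengths):
    counts = _toy_counts()
    groups = {f"c{r}": "ctrl" for r in range(3)} | {f"t{r}": "case" for r in range(3)}
    model = DifferentialSplicing(counts, groups, lengths=lengths, e=0.0)
    res = model.fit()
    assert set(res.frame["event_id"]) == {"evA", "evB"}
    assert res.frame["fdr"].notna().all()
    evA = res.frame.set_index("event_id").loc["evA"]
    evB = res.frame.set_index("event_id").loc["evB"]
    assert evA["p_value"] < evB["p_value"]
    assert "ctrl vs case" in res.summary() or "case vs ctrl" in res.summary()


def test_model_requires_two_groups():
    counts = _toy_counts()
    with pytest.raises(ValueError):
        DifferentialSplicing(counts, {s: "only" for s in counts["sample_id"].unique()})
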