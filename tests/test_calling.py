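"""Normalization, imputation, permutation test, peptide rule, combined call."""
import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from surfacer import CallParams, CohortConfig, generate_cohort
from surfacer.calling import (bh_qvalues, call_surface, enrichment_test,
                              impute_downshift, median_normalize,
                              peptide_rule, permutation_pvalues, welch_t)
from surfacer.errors import DegenerateDesignError, SurfacerError
from surfacer.tables import ProteinQuantTable

from conftest import make_quant_table


# ---------------------------------------------------------------------------
# oracles, written independently of the implementation under test
# ---------------------------------------------------------------------------

def oracle_pooled_permutation_p(X, n_biot, s0):
    """Brute-force pooled permutation p-values for one table.

    Enumerates every way of assigning the runs to a biot group of the
    original size, pools the moderated statistics of the non-observed
    labelings over all proteins, and counts tail mass per protein.
    """
    n_prot, n_runs = X.shape
    ident = tuple(range(n_biot))

    def tstat(row, bi):
        b = [row[i] for i in bi]
        n = [row[i] for i in range(n_runs) if i not in bi]
        mb = sum(b) / len(b)
        mn = sum(n) / len(n)
        vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
        vn = sum((x - mn) ** 2 for x in n) / (len(n) - 1)
        return (mb - mn) / ((vb / len(b) + vn / len(n)) ** 0.5 + s0)

    null = []
    for bi in combinations(range(n_runs), n_biot):
        if bi == ident:
            continue
        for i in range(n_prot):
            null.append(abs(tstat(X[i], bi)))
    p = []
    for i in range(n_prot):
        t = abs(tstat(X[i], ident))
        count = sum(1 for v in null if v >= t)
        p.append(max(count, 1) / len(null))
    return np.array(p)


def oracle_bh(p):
    """Independent Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# median normalization
# ---------------------------------------------------------------------------

def test_normalize_is_fixed_point_on_equal_medians():
    t = make_quant_table(missing_frac=0.0, seed=1)
    for run in t.runs:
        t.intensity[run] -= t.intensity[run].median()
    out = median_normalize(t)
    pd.testing.assert_frame_equal(out.intensity, t.intensity)


def test_normalize_splits_shift_symmetrically():
    runs = ["biot.1", "nb.1"]
    ids = pd.Index(["A", "B", "C"], name="protein_id")
    x = pd.DataFrame({"biot.1": [23.0, 24.0, 25.0],
                      "nb.1": [25.0, 26.0, 27.0]}, index=ids)
    t = ProteinQuantTable("X", x, pd.DataFrame(0, index=ids, columns=runs))
    out = median_normalize(t)
    assert out.intensity["biot.1"].median() == pytest.approx(25.0)
    assert out.intensity["nb.1"].median() == pytest.approx(25.0)
    assert (out.intensity["biot.1"] - x["biot.1"]).iloc[0] == pytest.approx(1.0)
    assert (out.intensity["nb.1"] - x["nb.1"]).iloc[0] == pytest.approx(-1.0)


@pytest.mark.parametrize("seed", range(4))
def test_normalize_postcondition_on_random_tables(seed):
    t = make_quant_table(missing_frac=0.25, seed=seed, n_proteins=60)
    grand = np.median(t.intensity.median(axis=0).to_numpy())
    out = median_normalize(t)
    for run in out.runs:
        assert out.intensity[run].median() == pytest.approx(grand, abs=1e-9)
    # missing cells stay missing
    assert out.intensity.isna().equals(t.intensity.isna())


def test_normalize_rejects_all_missing_run():
    t = make_quant_table(missing_frac=0.0, seed=2)
    t.intensity["nb.2"] = np.nan
    with pytest.raises(SurfacerError, match="nb.2"):
        median_normalize(t)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_identity_without_missing(call_params):
    t = make_quant_table(missing_frac=0.0, seed=3)
    out = impute_downshift(t, call_params)
    pd.testing.assert_frame_equal(out.intensity, t.intensity)


def test_impute_matches_downshifted_gaussian_law(call_params):
    """Imputed values follow Normal(mu - 1.8 sd, (0.3 sd)^2) of the run."""
    rng = np.random.default_rng(0)
    n, n_obs = 120_000, 10_000
    runs = ["biot.1", "biot.2", "nb.1"]
    ids = pd.Index([f"P{i}" for i in range(n)], name="protein_id")
    obs = rng.normal(25, 2, n)
    col2 = obs.copy()
    col2[n_obs:] = np.nan  # 110k cells to impute from the first 10k observed
    x = pd.DataFrame({"biot.1": obs, "biot.2": col2, "nb.1": obs}, index=ids)
    t = ProteinQuantTable("X", x, pd.DataFrame(0, index=ids, columns=runs))
    out = impute_downshift(t, call_params)
    mu = obs[:n_obs].mean()
    sd = obs[:n_obs].std(ddof=1)
    imputed = out.intensity["biot.2"].iloc[n_obs:]
    assert imputed.mean() == pytest.approx(mu - 1.8 * sd, rel=0.02)
    assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.02)


def test_impute_is_seeded(call_params):
    t = make_quant_table(missing_frac=0.3, seed=4)
    a = impute_downshift(t, call_params)
    b = impute_downshift(t, call_params)
    pd.testing.assert_frame_equal(a.intensity, b.intensity)
    c = impute_downshift(t, dataclasses.replace(call_params, seed=99))
    assert not a.intensity.equals(c.intensity)


def test_impute_requires_two_observed(call_params):
    t = make_quant_table(n_proteins=5, missing_frac=0.0, seed=5)
    t.intensity.loc[t.protein_ids[:4], "nb.1"] = np.nan
    with pytest.raises(SurfacerError, match="nb.1"):
        impute_downshift(t, call_params)


# ---------------------------------------------------------------------------
# the moderated permutation test
# ---------------------------------------------------------------------------

def test_exchangeable_groups_give_p_one(call_params):
    runs = ["biot.1", "biot.2", "nb.1", "nb.2"]
    ids = pd.Index(["A"], name="protein_id")
    x = pd.DataFrame([[24.0, 26.0, 24.0, 26.0]], index=ids, columns=runs)
    t = ProteinQuantTable("X", x, pd.DataFrame(0, index=ids, columns=runs))
    res = enrichment_test(
        t, dataclasses.replace(call_params, min_biot_quantified=2))
    assert res["log2fc"].iloc[0] == 0.0
    assert res["p_value"].iloc[0] == 1.0


def test_permutation_p_matches_bruteforce_oracle(call_params):
    t = make_quant_table(n_proteins=40, missing_frac=0.0, seed=6)
    res = enrichment_test(t, call_params)
    expected = oracle_pooled_permutation_p(
        t.intensity.to_numpy(), n_biot=4, s0=call_params.s0)
    np.testing.assert_array_equal(res["p_value"].to_numpy(), expected)


def test_welch_closed_form_when_unmoderated():
    t = make_quant_table(n_proteins=50, missing_frac=0.0, seed=7)
    X = t.intensity.to_numpy()
    ours = welch_t(X, np.arange(4), np.arange(4, 6), s0=0.0)
    ref = sps.ttest_ind(X[:, :4], X[:, 4:], axis=1, equal_var=False).statistic
    np.testing.assert_allclose(ours, ref, atol=1e-9)


def test_sampling_path_converges_to_enumeration():
    """With a design too large to enumerate, sampled p-values approach the
    exact enumerated ones."""
    rng = np.random.default_rng(8)
    X = rng.normal(25, 2, (30, 8))
    X[:3, :4] += 3  # a few enriched rows
    t_exact, p_exact, exact = permutation_pvalues(
        X, np.arange(4), np.arange(4, 8), s0=0.1, n_perm=0, seed=0)
    assert exact
    _, p_samp, exact2 = permutation_pvalues(
        X, np.arange(4), np.arange(4, 8), s0=0.1, n_perm=4000, seed=1,
        max_enumerate=1)
    assert not exact2
    np.testing.assert_allclose(p_samp, p_exact, atol=0.03)


def test_degenerate_design_raises():
    X = np.random.default_rng(0).normal(size=(5, 1))
    with pytest.raises(DegenerateDesignError):
        permutation_pvalues(X, np.array([0]), np.array([]), 0.1, 10, 0)


def test_bh_qvalues_match_independent_stepup_and_are_monotone():
    rng = np.random.default_rng(9)
    p = rng.uniform(size=200)
    q = bh_qvalues(p)
    np.testing.assert_allclose(q, oracle_bh(p), atol=1e-12)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    # step-up bounds: p <= q <= p * m / rank
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    assert (q <= p * len(p) / ranks + 1e-12).all()
    assert (q >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# peptide rule
# ---------------------------------------------------------------------------

def _pep_table(biot_counts, nb_counts):
    runs = [f"biot.{i+1}" for i in range(len(biot_counts))] + \
           [f"nb.{i+1}" for i in range(len(nb_counts))]
    ids = pd.Index(["A"], name="protein_id")
    x = pd.DataFrame([[25.0] * len(runs)], index=ids, columns=runs)
    pep = pd.DataFrame([list(biot_counts) + list(nb_counts)],
                       index=ids, columns=runs)
    return ProteinQuantTable("X", x, pep).validate()


@pytest.mark.parametrize("biot,nb,expected", [
    ((3, 4, 2, 0), (0, 1), True),    # three biot runs >= 2, both nb <= 1
    ((3, 4, 2, 5), (0, 2), False),   # one nb run exceeds the cap
    ((0, 0, 0, 0), (0, 0), False),   # no evidence at all
    ((2, 2, 0, 0), (0, 0), False),   # only two qualifying biot runs
])
def test_peptide_rule_thresholds(biot, nb, expected, call_params):
    assert peptide_rule(_pep_table(biot, nb), call_params).iloc[0] is np.bool_(expected)


# ---------------------------------------------------------------------------
# combined call
# ---------------------------------------------------------------------------

def test_planted_target_detected_background_not(small_cohort, call_params):
    tables, _, _, truth = small_cohort
    calls = call_surface(tables[0], call_params)
    calls = calls.set_index("protein_id")
    planted = truth["is_surface"] & truth["planted_detected_in"].str.contains(
        tables[0].pdx_id)
    strong = calls.loc[planted[planted].index]
    strong = strong[strong["n_biot_quantified"] == 4]
    # the bulk of fully-quantified planted proteins are detected
    assert strong["detected"].mean() > 0.5
    background = calls.loc[truth.index[~truth["is_surface"]]]
    assert background["detected"].mean() < 0.05


def test_peptide_mode_ignores_intensities(call_params):
    t = make_quant_table(missing_frac=0.0, seed=12)
    params = dataclasses.replace(call_params, mode="peptide")
    a = call_surface(t, params)
    zeroed = t.copy()
    zeroed.intensity.loc[:, :] = 0.0
    b = call_surface(zeroed, params)
    pd.testing.assert_series_equal(a["detected"], b["detected"])


def test_detection_monotone_in_effect_size(call_params):
    """Raising the planted enrichment never turns a detection off."""
    base = dict(n_pdx=1, n_proteins=150, n_true_targets=6,
                n_decoys_per_archetype=0, detect_dropout_rate=0.0, seed=13)
    weak_tables, _, _, truth = generate_cohort(
        CohortConfig(enrichment_log2fc=2.0, **base))
    strong_tables, _, _, _ = generate_cohort(
        CohortConfig(enrichment_log2fc=4.0, **base))
    weak = call_surface(weak_tables[0], call_params).set_index("protein_id")
    strong = call_surface(strong_tables[0], call_params).set_index("protein_id")
    targets = truth.index[truth["is_surface"]]
    assert (weak.loc[targets, "detected"]
            <= strong.loc[targets, "detected"]).all()


def test_qvalues_monotone_in_pvalues_within_pdx(small_cohort, call_params):
    tables, _, _, _ = small_cohort
    calls = call_surface(tables[0], call_params)
    s = calls.sort_values("p_value")
    assert (s["q_value"].diff().dropna() >= -1e-12).all()
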