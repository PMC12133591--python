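"""Per-PDX surface-detection calling.

The chain mirrors the Perseus label-free enrichment workflow: run-level
median normalization, downshifted-Gaussian imputation of left-censored
missing values, a moderated two-sample statistic

    t = (mean_biot - mean_nb) / (se_welch + s0)

with ``se_welch = sqrt(v_biot/n_biot + v_nb/n_nb)``, and a permutation
false-discovery estimate. The permutation null pools |t| over all distinct
relabelings of the runs into groups of the original sizes, across **all**
proteins in the table, excluding the observed labeling — the SAM-style
construction Perseus uses. For the 4-vs-2 design this null is enumerated
completely (C(6,4) = 15 labelings, 14 in the null), making p-values exact
and deterministic; larger designs are sampled with a seeded generator.
Benjamini-Hochberg over these pooled p-values is algebraically the SAM
permutation FDR.

Detection combines the intensity rule (q <= q_max, log2fc >= log2fc_min,
enough quantified biot runs) and/or the specific-peptide rule (>= min_pep_biot
peptides in >= min_pep_reps biot runs, <= max_pep_nb in every control run),
according to ``CallParams.mode``.
"""
from __future__ import annotations

import dataclasses
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDesignError, SurfacerError
from .params import CallParams
from .tables import ProteinQuantTable

CALL_COLUMNS = ["pdx_id", "protein_id", "log2fc", "t_stat", "p_value",
                "q_value", "n_biot_quantified", "peptide_rule_pass",
                "detected"]


# ---------------------------------------------------------------------------
# normalization & imputation
# ---------------------------------------------------------------------------

def median_normalize(table: ProteinQuantTable) -> ProteinQuantTable:
    """Shift each run so its observed median equals the grand median.

    The grand median is the median of the runs' pre-normalization medians,
    so a table whose runs already share one median is a fixed point.
    Missing cells stay missing.
    """
    out = table.copy()
    medians = out.intensity.median(axis=0, skipna=True)
    for run in out.runs:
        if out.intensity[run].notna().sum() == 0:
            raise SurfacerError(
                f"{table.pdx_id}: run {run!r} has no observed values")
    grand = float(np.median(medians.to_numpy()))
    out.intensity = out.intensity + (grand - medians)
    return out


def impute_downshift(table: ProteinQuantTable,
                     params: CallParams) -> ProteinQuantTable:
    """Replace missing intensities by downshifted-Gaussian draws.

    Per run r with observed mean mu_r and sd sigma_r, missing cells are drawn
    from Normal(mu_r - d * sigma_r, (w * sigma_r)^2) with d the downshift and
    w the width, both in units of the run's sd. Observed cells are untouched;
    draws are seeded (``params.seed``) and consumed run by run in column
    order, so results are reproducible.
    """
    params.validate()
    out = table.copy()
    rng = np.random.default_rng(params.seed)
    for run in out.runs:
        col = out.intensity[run]
        obs = col.dropna()
        if len(obs) == col.size:
            continue
        if len(obs) < 2:
            raise SurfacerError(
                f"{table.pdx_id}: run {run!r} has fewer than 2 observed "
                "values; imputation sd undefined")
        mu_r = float(obs.mean())
        sd_r = float(obs.std(ddof=1))
        mask = col.isna().to_numpy()
        draws = rng.normal(mu_r - params.impute_downshift * sd_r,
                           params.impute_width * sd_r, int(mask.sum()))
        vals = col.to_numpy(copy=True)
        vals[mask] = draws
        out.intensity[run] = vals
    return out


# ---------------------------------------------------------------------------
# moderated statistic and permutation null
# ---------------------------------------------------------------------------

def welch_t(X: np.ndarray, biot_idx: np.ndarray, nb_idx: np.ndarray,
            s0: float) -> np.ndarray:
    """Moderated Welch statistic per row of ``X`` for one labeling."""
    xb = X[:, biot_idx]
    xn = X[:, nb_idx]
    se = np.sqrt(xb.var(axis=1, ddof=1) / len(biot_idx)
                 + xn.var(axis=1, ddof=1) / len(nb_idx))
    return (xb.mean(axis=1) - xn.mean(axis=1)) / (se + s0)


def _relabelings(n_runs: int, n_biot: int, identity: tuple[int, ...],
                 n_perm: int, seed: int, max_enumerate: int):
    """Yield biot-index tuples of the null labelings.

    Complete enumeration (all distinct labelings except the observed one)
    when their count is at most ``max_enumerate``; otherwise ``n_perm``
    seeded random labelings, the observed one excluded.
    """
    total = comb(n_runs, n_biot)
    if total <= 1:
        raise DegenerateDesignError(
            f"design with {n_runs} runs / {n_biot} biot admits no "
            "non-trivial relabeling")
    if total <= max_enumerate:
        return [c for c in combinations(range(n_runs), n_biot)
                if c != identity], True
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_perm:
        c = tuple(sorted(rng.choice(n_runs, size=n_biot, replace=False)))
        if c != identity:
            out.append(c)
    return out, False


def permutation_pvalues(X: np.ndarray, biot_idx, nb_idx, s0: float,
                        n_perm: int, seed: int,
                        max_enumerate: int = 1000):
    """Two-sided pooled permutation p-values.

    Returns ``(t_obs, p, exact)``. The null pools |t| from every null
    labeling of every protein; ``p_i`` is the fraction of pooled null values
    >= |t_i| (ties count, conservatively), clamped below at one over the
    pool size so p is never 0.
    """
    biot_idx = np.asarray(biot_idx)
    nb_idx = np.asarray(nb_idx)
    n_runs = len(biot_idx) + len(nb_idx)
    identity = tuple(sorted(int(i) for i in biot_idx))
    labelings, exact = _relabelings(n_runs, len(biot_idx), identity,
                                    n_perm, seed, max_enumerate)
    t_obs = welch_t(X, biot_idx, nb_idx, s0)
    all_runs = set(range(n_runs))
    null = np.concatenate([
        np.abs(welch_t(X, np.array(c), np.array(sorted(all_runs - set(c))), s0))
        for c in labelings])
    null.sort()
    count = null.size - np.searchsorted(null, np.abs(t_obs), side="left")
    p = np.maximum(count, 1) / null.size
    return t_obs, p, exact


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def enrichment_test(table: ProteinQuantTable,
                    params: CallParams) -> pd.DataFrame:
    """Moderated permutation test, biot vs nb, on an imputed table.

    Returns a DataFrame with ``protein_id``, ``log2fc``, ``t_stat``,
    ``p_value``, ``q_value`` and ``n_biot_quantified`` (count of biot runs
    quantified in the *input* table — all of them if imputation already
    filled the gaps, the raw count when called on a raw table).
    """
    table.validate()
    params.validate(n_biot_runs=len(table.biot_runs))
    runs = table.runs
    if len(table.biot_runs) < 2 or len(table.nb_runs) < 2:
        raise DegenerateDesignError("need >= 2 runs per condition")
    X = table.intensity[runs].to_numpy()
    biot_idx = np.array([runs.index(r) for r in table.biot_runs])
    nb_idx = np.array([runs.index(r) for r in table.nb_runs])
    t_obs, p, _ = permutation_pvalues(X, biot_idx, nb_idx, params.s0,
                                      params.n_perm, params.seed)
    log2fc = X[:, biot_idx].mean(axis=1) - X[:, nb_idx].mean(axis=1)
    nbq = table.intensity[table.biot_runs].notna().sum(axis=1).to_numpy()
    return pd.DataFrame({
        "protein_id": table.protein_ids,
        "log2fc": log2fc,
        "t_stat": t_obs,
        "p_value": p,
        "q_value": bh_qvalues(p),
        "n_biot_quantified": nbq,
    })


# ---------------------------------------------------------------------------
# peptide rule and the combined call
# ---------------------------------------------------------------------------

def peptide_rule(table: ProteinQuantTable, params: CallParams) -> pd.Series:
    """Specific-peptide detection rule.

    True iff the protein has >= ``min_pep_biot`` peptides in at least
    ``min_pep_reps`` biotinylated runs and at most ``max_pep_nb`` peptides
    in *every* non-biotinylated control run.
    """
    params.validate()
    biot = table.peptides[table.biot_runs]
    nb = table.peptides[table.nb_runs]
    enough_biot = (biot >= params.min_pep_biot).sum(axis=1) >= params.min_pep_reps
    clean_nb = (nb <= params.max_pep_nb).all(axis=1)
    return (enough_biot & clean_nb).rename("peptide_rule_pass")


def call_surface(table: ProteinQuantTable, params: CallParams) -> pd.DataFrame:
    """Full per-PDX call: normalize, impute, test, peptide rule, detect.

    ``detected`` is the intensity rule for ``mode='intensity'``
    (q <= q_max AND log2fc >= log2fc_min AND n_biot_quantified >=
    min_biot_quantified), the peptide rule for ``mode='peptide'``, and
    their disjunction for ``mode='either'``.
    """
    table.validate()
    params.validate(n_biot_runs=len(table.biot_runs))
    normalized = median_normalize(table)
    imputed = impute_downshift(normalized, params)
    stats = enrichment_test(imputed, params)
    # quantification counts come from the raw table, not the imputed one
    nbq = table.intensity[table.biot_runs].notna().sum(axis=1)
    stats["n_biot_quantified"] = nbq.to_numpy()
    pep = peptide_rule(table, params)
    stats["peptide_rule_pass"] = pep.to_numpy()
    intensity_rule = ((stats["q_value"] <= params.q_max)
                      & (stats["log2fc"] >= params.log2fc_min)
                      & (stats["n_biot_quantified"] >= params.min_biot_quantified))
    if params.mode == "intensity":
        detected = intensity_rule
    elif params.mode == "peptide":
        detected = stats["peptide_rule_pass"]
    else:
        detected = intensity_rule | stats["peptide_rule_pass"]
    stats["detected"] = detected
    stats.insert(0, "pdx_id", table.pdx_id)
    return stats[CALL_COLUMNS]


def call_cohort(tables: list[ProteinQuantTable], params: CallParams,
                seed: int | None = None) -> pd.DataFrame:
    """Call every PDX of a cohort; per-PDX imputation seeds are derived
    deterministically from ``seed`` (or ``params.seed``)."""
    base = params.seed if seed is None else seed
    frames = []
    for k, table in enumerate(tables, start=1):
        frames.append(call_surface(
            table, dataclasses.replace(params, seed=base + 50_021 * k)))
    return pd.concat(frames, ignore_index=True)
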