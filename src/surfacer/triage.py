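"""Candidate triage: from per-PDX surface calls to a ranked target list.

The cascade evaluates, in order: surface detection in at least one PDX,
membrane annotation, cross-PDX prevalence, lymphoid tissue-specificity, and
cell-type exclusion (T-cell subsets, granulocytes, HSC by default). Each
stage only sees survivors of the previous one, so the per-protein stage
flags are nested and the waterfall of surviving counts is non-increasing.

Tissue specificity uses the tau index

    tau = sum_i (1 - x_i / max_j x_j) / (T - 1)

over T tissues: 0 for uniform expression, 1 for single-tissue expression,
invariant under rescaling of the expression vector. The lymphoid criterion
additionally requires the top tissue to be lymphoid, a minimum fold ratio
of lymphoid over non-lymphoid maxima, and an absolute cap on non-lymphoid
expression; each conjunct can be toggled in :class:`TriageParams`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedScoreError
from .params import TriageParams
from .tables import AnnotationTable, ExpressionAtlas

WATERFALL_STAGES = ("total", "surface_any", "membrane", "prevalent",
                    "lymphoid_specific", "not_excluded")


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def membrane_filter(calls: pd.DataFrame, annotations: AnnotationTable
                    ) -> tuple[set, set]:
    """Proteins detected in >= 1 PDX that carry a membrane annotation.

    Returns ``(membrane_set, unannotated)``: detected proteins absent from
    the annotation table are excluded but reported, never silently dropped.
    """
    detected_any = set(calls.loc[calls["detected"], "protein_id"])
    annotated = set(annotations.df.index)
    unannotated = detected_any - annotated
    membrane = {p for p in detected_any & annotated
                if bool(annotations.df.at[p, "is_membrane"])}
    return membrane, unannotated


def prevalence_filter(calls: pd.DataFrame, proteins: set,
                      params: TriageParams, n_pdx: int) -> set:
    """Retain proteins detected in at least ``min_pdx`` PDX samples."""
    if params.min_pdx > n_pdx:
        raise ParameterError(
            f"min_pdx: {params.min_pdx} exceeds the number of PDX samples "
            f"({n_pdx})")
    det = calls[calls["detected"]]
    counts = det.groupby("protein_id")["pdx_id"].nunique()
    return {p for p in proteins if counts.get(p, 0) >= params.min_pdx}


def tau_specificity(x) -> float:
    """Tissue-specificity index tau of a non-negative expression vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise UndefinedScoreError("tau needs at least 2 tissues")
    if (x < 0).any():
        raise UndefinedScoreError("tau undefined for negative expression")
    xmax = x.max()
    if xmax == 0:
        raise UndefinedScoreError("tau undefined for an all-zero vector")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def specificity_scores(genes, atlas: ExpressionAtlas,
                       params: TriageParams) -> pd.DataFrame:
    """Per-gene tau and lymphoid/non-lymphoid summaries with the pass flag.

    Genes whose tissue row is all-zero get ``tau = NaN`` and fail; the
    caller is expected to have resolved the genes in the tissue matrix.
    """
    if not params.lymphoid_tissues:
        raise ParameterError("lymphoid_tissues: must not be empty")
    lymph = [t for t in atlas.tissues if t in set(params.lymphoid_tissues)]
    if not lymph:
        raise ParameterError(
            "lymphoid_tissues: none present in the tissue matrix")
    nonlymph = [t for t in atlas.tissues if t not in set(params.lymphoid_tissues)]
    score_cols = ["tau", "lymphoid_max", "nonlymphoid_max", "lymphoid_fold",
                  "passes_specificity"]
    if len(genes) == 0:
        return pd.DataFrame(columns=score_cols).rename_axis("gene_symbol")
    recs = []
    for gene in genes:
        row = atlas.tissue.loc[gene]
        lmax = float(row[lymph].max())
        nmax = float(row[nonlymph].max()) if nonlymph else 0.0
        fold = lmax / (nmax + params.epsilon)
        try:
            tau = tau_specificity(row.to_numpy())
        except UndefinedScoreError:
            tau = float("nan")
        conjuncts = []
        if params.use_tau:
            conjuncts.append(bool(tau >= params.tau_min)
                             if not np.isnan(tau) else False)
        if params.use_lymphoid_argmax:
            conjuncts.append(row.idxmax() in set(params.lymphoid_tissues)
                             and row.max() > 0)
        if params.use_lymphoid_fold:
            conjuncts.append(fold >= params.lymphoid_fold_min)
        if params.use_nonlymphoid_abs:
            conjuncts.append(nmax <= params.nonlymphoid_abs_max)
        recs.append({
            "gene_symbol": gene, "tau": tau, "lymphoid_max": lmax,
            "nonlymphoid_max": nmax, "lymphoid_fold": fold,
            "passes_specificity": all(conjuncts) if conjuncts else True,
        })
    return pd.DataFrame.from_records(recs).set_index("gene_symbol")


def lymphoid_specificity_filter(proteins: set, gene_of: pd.Series,
                                atlas: ExpressionAtlas, params: TriageParams
                                ) -> tuple[set, pd.DataFrame, set]:
    """Apply the tissue-specificity criterion to a protein set.

    Returns ``(passing proteins, per-gene scores, unresolved proteins)``;
    proteins whose gene is absent from the tissue matrix are dropped and
    reported as unresolved.
    """
    resolved = {p for p in proteins
                if p in gene_of.index and gene_of[p] in atlas.tissue.index}
    unresolved = set(proteins) - resolved
    genes = sorted({gene_of[p] for p in resolved})
    scores = specificity_scores(genes, atlas, params)
    passing = {p for p in resolved
               if bool(scores.at[gene_of[p], "passes_specificity"])}
    return passing, scores, unresolved


def celltype_exclusion(proteins: set, gene_of: pd.Series,
                       atlas: ExpressionAtlas, params: TriageParams
                       ) -> tuple[set, pd.Series]:
    """Drop proteins expressed in any excluded cell type.

    A protein is dropped when its gene's ``frac_expressing`` exceeds
    ``exclude_frac_max`` in *any* cell type of ``params.excluded_celltypes``.
    Returns the survivors and the per-protein maximum excluded-cell-type
    fraction (0 for genes absent from the summary).
    """
    excluded = set(params.excluded_celltypes)
    max_frac = {}
    keep = set()
    ct = atlas.celltype
    for p in proteins:
        gene = gene_of.get(p)
        fracs = []
        for c in excluded:
            if gene is not None and (gene, c) in ct.index:
                fracs.append(float(ct.at[(gene, c), "frac_expressing"]))
        m = max(fracs) if fracs else 0.0
        max_frac[p] = m
        if m <= params.exclude_frac_max:
            keep.add(p)
    return keep, pd.Series(max_frac, name="max_excluded_frac")


def dotplot_stats(atlas: ExpressionAtlas, gene: str) -> pd.DataFrame:
    """Per-cell-type (frac_expressing, mean_expr) for one gene."""
    levels = atlas.celltype.index.get_level_values("gene_symbol")
    if gene not in levels:
        raise KeyError(f"gene {gene!r} not in the cell-type summary")
    return atlas.celltype.xs(gene, level="gene_symbol")


def dotplot_from_raw(raw: dict) -> pd.DataFrame:
    """Dot-plot summaries from raw per-cell expression vectors.

    For each cell type: fraction of cells with expression > 0 and the mean
    over expressing cells ((0, 0) when no cell expresses the gene).
    """
    recs = []
    for celltype, values in raw.items():
        v = np.asarray(values, dtype=float)
        expressing = v > 0
        frac = float(expressing.mean()) if v.size else 0.0
        mean = float(v[expressing].mean()) if expressing.any() else 0.0
        recs.append({"celltype": celltype, "frac_expressing": frac,
                     "mean_expr": mean})
    return pd.DataFrame.from_records(recs).set_index("celltype")


# ---------------------------------------------------------------------------
# ranking and the full cascade
# ---------------------------------------------------------------------------

def _zscore(v: pd.Series) -> pd.Series:
    sd = v.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        return pd.Series(0.0, index=v.index)
    return (v - v.mean()) / sd


@dataclass
class TriageResult:
    candidates: pd.DataFrame
    waterfall: list[tuple[str, int]]
    unannotated: set = field(default_factory=set)
    unresolved_genes: set = field(default_factory=set)


def triage(calls: pd.DataFrame, annotations: AnnotationTable,
           atlas: ExpressionAtlas, params: TriageParams) -> TriageResult:
    """Run the full cascade and rank the survivors.

    The candidate table has one row per protein seen in the calls, with the
    nested stage flags, the specificity scores, and
    ``rank_score = z(n_pdx_detected) + z(mean_log2fc) + z(tau)
    - z(max_excluded_frac)`` standardized within the final survivors
    (zero-variance terms contribute 0). Ties break on gene symbol.
    """
    n_pdx = calls["pdx_id"].nunique()
    params.validate(n_pdx=n_pdx)
    gene_of = annotations.gene_of()

    all_proteins = sorted(calls["protein_id"].unique())
    det = calls[calls["detected"]]
    detected_any = set(det["protein_id"])
    membrane, unannotated = membrane_filter(calls, annotations)
    prevalent = prevalence_filter(calls, membrane, params, n_pdx)
    lymphoid, scores, unresolved = lymphoid_specificity_filter(
        prevalent, gene_of, atlas, params)
    survivors, max_frac = celltype_exclusion(lymphoid, gene_of, atlas, params)

    n_detected = det.groupby("protein_id")["pdx_id"].nunique()
    fc_det = det.groupby("protein_id")["log2fc"].mean()
    fc_all = calls.groupby("protein_id")["log2fc"].mean()

    rows = []
    for p in all_proteins:
        gene = gene_of.get(p, "")
        srow = scores.loc[gene] if (gene in scores.index and p in prevalent
                                    and p not in unresolved) else None
        rows.append({
            "protein_id": p,
            "gene_symbol": gene if gene else "",
            "n_pdx_detected": int(n_detected.get(p, 0)),
            "mean_log2fc": float(fc_det.get(p, fc_all.get(p, np.nan))),
            "tau": float(srow["tau"]) if srow is not None else np.nan,
            "lymphoid_max": float(srow["lymphoid_max"]) if srow is not None else np.nan,
            "nonlymphoid_max": float(srow["nonlymphoid_max"]) if srow is not None else np.nan,
            "lymphoid_fold": float(srow["lymphoid_fold"]) if srow is not None else np.nan,
            "max_excluded_frac": float(max_frac.get(p, np.nan)),
            "surface_any": p in detected_any,
            "membrane": p in membrane,
            "prevalent": p in prevalent,
            "lymphoid_specific": p in lymphoid,
            "not_excluded": p in survivors,
            "known_car_target": bool(annotations.df["known_car_target"].get(p, False)),
        })
    cand = pd.DataFrame.from_records(rows).set_index("protein_id")

    surv_mask = cand["not_excluded"]
    cand["rank_score"] = np.nan
    if surv_mask.any():
        sub = cand.loc[surv_mask]
        score = (_zscore(sub["n_pdx_detected"].astype(float))
                 + _zscore(sub["mean_log2fc"])
                 + _zscore(sub["tau"])
                 - _zscore(sub["max_excluded_frac"]))
        cand.loc[surv_mask, "rank_score"] = score
    # survivors first, by decreasing score then gene symbol; rest by gene
    cand = cand.sort_values(
        by=["not_excluded", "rank_score", "gene_symbol"],
        ascending=[False, False, True],
        key=lambda s: s if s.name != "rank_score" else s.fillna(-np.inf))
    cand["rank"] = pd.array(
        [i + 1 if surv else pd.NA
         for i, surv in enumerate(cand["not_excluded"])], dtype="Int64")

    waterfall = [
        ("total", len(all_proteins)),
        ("surface_any", len(detected_any)),
        ("membrane", len(membrane)),
        ("prevalent", len(prevalent)),
        ("lymphoid_specific", len(lymphoid)),
        ("not_excluded", len(survivors)),
    ]
    return TriageResult(cand, waterfall, unannotated, unresolved)
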