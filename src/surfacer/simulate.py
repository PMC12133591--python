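"""Synthetic biotin-enrichment cohorts with known ground truth.

The generator emulates the inputs of a surfaceome screen on patient-derived
xenograft (PDX) leukemia samples: per-PDX label-free quantification tables
(4 biotinylated runs vs 2 non-biotinylated controls), protein annotations,
and tissue / cell-type expression references, together with the truth labels
every downstream test needs.

Statistical structure
---------------------
* log2 intensities = protein baseline Normal(baseline_mu, baseline_sigma)
  + condition effect + run noise Normal(0, noise_sigma). True surface
  proteins gain ``enrichment_log2fc`` in the biotinylated runs of each PDX
  in which they are planted; each target independently drops out of a PDX
  with probability ``detect_dropout_rate``.
* Missingness is left-censored: within each run, proteins whose noise-free
  intensity falls below the run's ``missing_censor_quantile`` quantile are
  missing. Missing cells are absent fields in the serialized table, never
  zeros.
* Specific-peptide counts are Poisson with rate proportional to the
  linear-scale intensity (rate = 2^(x - baseline_mu + 2), capped at 30) and
  0 where the intensity is missing — only the threshold logic of the
  peptide detection rule consumes them.
* Tissue and cell-type profiles follow per-protein archetypes:
  ``lymphoid_restricted`` (the CAR-target profile: bone marrow / spleen /
  blood / lymph node high, elsewhere near zero; expressed in B cells and
  monocytes), ``t_cell`` and ``myeloid`` (lymphoid tissue profile but
  expressed in T-cell subsets resp. granulocytes — the decoys the
  cell-type exclusion stage must catch), ``ubiquitous``,
  ``single_nonlymphoid`` and ``silent``.

One global seed drives a per-PDX seed stream (seed + 1-based PDX index), so
appending a PDX never perturbs the samples already generated.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .params import (CohortConfig, DEFAULT_EXCLUDED_CELLTYPES,
                     DEFAULT_LYMPHOID_TISSUES)
from .tables import AnnotationTable, ExpressionAtlas, ProteinQuantTable, run_label
from . import io as sio

ARCH_LYMPHOID = "lymphoid_restricted"
ARCH_TCELL = "t_cell"
ARCH_MYELOID = "myeloid"
ARCH_UBIQ = "ubiquitous"
ARCH_SINGLE = "single_nonlymphoid"
ARCH_SILENT = "silent"

DECOY_ARCHETYPES = (ARCH_TCELL, ARCH_MYELOID, ARCH_SINGLE, ARCH_UBIQ)

NONLYMPHOID_TISSUES: tuple[str, ...] = (
    "brain", "cerebellum", "heart", "lung", "liver", "kidney", "pancreas",
    "skin", "colon", "stomach", "small intestine", "esophagus", "testis",
    "ovary", "uterus", "prostate", "breast", "thyroid", "adrenal gland",
    "skeletal muscle", "adipose tissue", "bladder", "salivary gland",
    "retina",
)

CELLTYPES: tuple[str, ...] = (
    "B cell", "plasma cell", "monocyte", "macrophage", "dendritic cell",
    "NK cell", "CD4 T cell", "CD8 T cell", "regulatory T cell",
    "neutrophil", "basophil", "eosinophil", "HSC", "erythroid progenitor",
)

_TCELL_TYPES = ("CD4 T cell", "CD8 T cell", "regulatory T cell")
_GRANULO_TYPES = ("neutrophil", "basophil", "eosinophil")
_BCELL_MONO_TYPES = ("B cell", "plasma cell", "monocyte", "macrophage")

# background archetype frequencies for non-planted proteins
_BG_ARCHETYPES = (ARCH_UBIQ, ARCH_SINGLE, ARCH_SILENT, ARCH_MYELOID,
                  ARCH_TCELL, ARCH_LYMPHOID)
_BG_PROBS = (0.50, 0.20, 0.12, 0.08, 0.07, 0.03)

_ATLAS_SEED_OFFSET = 1_000_003


def _protein_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:05d}" for i in range(n)], name="protein_id")


def _gene_symbols(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def _assign_roles(config: CohortConfig, rng: np.random.Generator):
    """Return (is_surface, archetype) arrays over proteins.

    The first ``n_true_targets`` proteins are the planted lymphoid-restricted
    targets; the next 4 * n_decoys_per_archetype are enriched surface decoys
    of the other archetypes (only when targets are planted at all, so a
    zero-target cohort is a genuine null); the rest is background.
    """
    n = config.n_proteins
    is_surface = np.zeros(n, dtype=bool)
    archetype = np.empty(n, dtype=object)
    pos = 0
    is_surface[:config.n_true_targets] = True
    archetype[:config.n_true_targets] = ARCH_LYMPHOID
    pos = config.n_true_targets
    if config.n_true_targets > 0:
        for arch in DECOY_ARCHETYPES:
            k = config.n_decoys_per_archetype
            is_surface[pos:pos + k] = True
            archetype[pos:pos + k] = arch
            pos += k
    n_bg = n - pos
    archetype[pos:] = rng.choice(_BG_ARCHETYPES, size=n_bg, p=_BG_PROBS)
    return is_surface, archetype


def _tissue_profile(arch: str, rng: np.random.Generator,
                    n_lymph: int, n_nonlymph: int) -> np.ndarray:
    """One row of the tissue matrix (lymphoid tissues first)."""
    row = np.zeros(n_lymph + n_nonlymph)
    if arch in (ARCH_LYMPHOID, ARCH_TCELL, ARCH_MYELOID):
        row[:n_lymph] = rng.uniform(40.0, 160.0, n_lymph)
        row[n_lymph:] = rng.uniform(0.0, 0.5, n_nonlymph)
    elif arch == ARCH_UBIQ:
        row[:] = rng.uniform(20.0, 60.0, n_lymph + n_nonlymph)
    elif arch == ARCH_SINGLE:
        row[n_lymph:] = rng.uniform(0.0, 0.5, n_nonlymph)
        j = rng.integers(n_nonlymph)
        row[n_lymph + j] = rng.uniform(80.0, 200.0)
    elif arch == ARCH_SILENT:
        pass
    else:  # pragma: no cover - archetypes are internal
        raise ParameterError(f"unknown archetype {arch!r}")
    return row


def _celltype_profile(arch: str, rng: np.random.Generator) -> np.ndarray:
    """frac_expressing per cell type (order of CELLTYPES)."""
    frac = rng.uniform(0.0, 0.05, len(CELLTYPES))
    by = {c: i for i, c in enumerate(CELLTYPES)}
    if arch == ARCH_LYMPHOID:
        for c in _BCELL_MONO_TYPES:
            frac[by[c]] = rng.uniform(0.5, 0.9)
    elif arch == ARCH_TCELL:
        for c in _TCELL_TYPES:
            frac[by[c]] = rng.uniform(0.5, 0.95)
    elif arch == ARCH_MYELOID:
        for c in _GRANULO_TYPES + ("monocyte",):
            frac[by[c]] = rng.uniform(0.4, 0.9)
    elif arch == ARCH_UBIQ:
        frac = rng.uniform(0.3, 0.7, len(CELLTYPES))
    elif arch == ARCH_SILENT:
        frac = np.zeros(len(CELLTYPES))
    # ARCH_SINGLE keeps the near-zero baseline
    return frac


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns ``(quant_tables, annotations, atlas, truth)`` where ``truth`` is
    a DataFrame indexed by protein_id with columns ``is_surface``,
    ``is_membrane_annotated``, ``tissue_archetype`` and
    ``planted_detected_in`` (``;``-joined PDX ids).
    """
    config.validate()
    n = config.n_proteins
    ids = _protein_ids(n)
    genes = _gene_symbols(n)
    rng_truth = np.random.default_rng(config.seed)

    is_surface, archetype = _assign_roles(config, rng_truth)
    is_membrane = is_surface | (rng_truth.random(n) < 0.3)
    known_car = is_surface & (rng_truth.random(n) < 0.2)
    baseline = rng_truth.normal(config.baseline_mu, config.baseline_sigma, n)

    # --- per-PDX quantification tables -----------------------------------
    pdx_ids = [f"PDX{k}" for k in range(1, config.n_pdx + 1)]
    runs = ([run_label("biot", r + 1) for r in range(config.n_biot_reps)]
            + [run_label("nb", r + 1) for r in range(config.n_nb_reps)])
    n_runs = len(runs)
    planted_in: dict[str, set[str]] = {pid: set() for pid in ids}
    tables: list[ProteinQuantTable] = []
    lam_scale = 2.0 ** (config.baseline_mu - 2.0)
    for k, pdx in enumerate(pdx_ids, start=1):
        rng = np.random.default_rng(config.seed + k)
        keep = rng.random(n) >= config.detect_dropout_rate
        planted = is_surface & keep
        for pid in ids[planted]:
            planted_in[pid].add(pdx)
        effect = np.where(planted, config.enrichment_log2fc, 0.0)
        intensity = np.empty((n, n_runs))
        missing = np.zeros((n, n_runs), dtype=bool)
        peptides = np.zeros((n, n_runs), dtype=int)
        for j, run in enumerate(runs):
            is_biot = j < config.n_biot_reps
            noisefree = baseline + (effect if is_biot else 0.0)
            thr = np.quantile(noisefree, config.missing_censor_quantile)
            intensity[:, j] = noisefree + rng.normal(0.0, config.noise_sigma, n)
            missing[:, j] = noisefree < thr
            lam = np.minimum(2.0 ** intensity[:, j] / lam_scale, 30.0)
            counts = rng.poisson(lam)
            peptides[:, j] = np.where(missing[:, j], 0, counts)
        intensity[missing] = np.nan
        tables.append(ProteinQuantTable(
            pdx,
            pd.DataFrame(intensity, index=ids, columns=runs),
            pd.DataFrame(peptides, index=ids, columns=runs),
        ).validate())

    # --- annotations ------------------------------------------------------
    kw_pool = (["cytoplasm"], ["nucleus"], ["secreted"])
    keywords = []
    bg_kw_choice = rng_truth.integers(0, len(kw_pool), n)
    for i in range(n):
        if is_membrane[i]:
            keywords.append(["membrane", "cell membrane"])
        else:
            keywords.append(list(kw_pool[bg_kw_choice[i]]))
    annotations = AnnotationTable(pd.DataFrame({
        "gene_symbol": genes,
        "is_membrane": is_membrane,
        "subcellular_keywords": keywords,
        "known_car_target": known_car,
    }, index=ids)).validate()

    # --- expression atlas -------------------------------------------------
    rng_atlas = np.random.default_rng(config.seed + _ATLAS_SEED_OFFSET)
    n_lymph = len(DEFAULT_LYMPHOID_TISSUES)
    n_nonlymph = len(NONLYMPHOID_TISSUES)
    tissue_rows = np.vstack([
        _tissue_profile(archetype[i], rng_atlas, n_lymph, n_nonlymph)
        for i in range(n)])
    tissue = pd.DataFrame(
        tissue_rows, index=pd.Index(genes, name="gene_symbol"),
        columns=list(DEFAULT_LYMPHOID_TISSUES) + list(NONLYMPHOID_TISSUES))
    frac_rows = np.vstack([_celltype_profile(archetype[i], rng_atlas)
                           for i in range(n)])
    mean_rows = frac_rows * rng_atlas.uniform(1.0, 5.0, frac_rows.shape)
    ct_index = pd.MultiIndex.from_product(
        [genes, CELLTYPES], names=["gene_symbol", "celltype"])
    celltype = pd.DataFrame({
        "frac_expressing": frac_rows.ravel(),
        "mean_expr": mean_rows.ravel(),
    }, index=ct_index)
    atlas = ExpressionAtlas(
        tissue=tissue, celltype=celltype,
        lymphoid_tissues=frozenset(DEFAULT_LYMPHOID_TISSUES),
        excluded_celltypes=frozenset(DEFAULT_EXCLUDED_CELLTYPES),
    ).validate()

    # --- truth ------------------------------------------------------------
    truth = pd.DataFrame({
        "is_surface": is_surface,
        "is_membrane_annotated": is_membrane,
        "tissue_archetype": archetype.astype(str),
        "planted_detected_in": [";".join(sorted(planted_in[pid]))
                                for pid in ids],
    }, index=ids)
    return tables, annotations, atlas, truth


def planted_pdx_sets(truth: pd.DataFrame) -> pd.Series:
    """Parse ``planted_detected_in`` back into sets of PDX ids."""
    return truth["planted_detected_in"].map(
        lambda s: set(s.split(";")) if s else set())


def write_cohort(config: CohortConfig, outdir) -> list[Path]:
    """Generate a cohort and serialize it into ``outdir``.

    Emits ``pdx_<k>.quant.tsv``, ``annotations.tsv``,
    ``tissue_expression.tsv``, ``celltype_expression.tsv`` and ``truth.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, annotations, atlas, truth = generate_cohort(config)
    written = []
    for k, table in enumerate(tables, start=1):
        p = outdir / f"pdx_{k}.quant.tsv"
        sio.write_quant_table(table, p)
        written.append(p)
    p = outdir / "annotations.tsv"
    sio.write_annotations(annotations, p)
    written.append(p)
    p = outdir / "tissue_expression.tsv"
    sio.write_tissue_matrix(atlas.tissue, p)
    written.append(p)
    p = outdir / "celltype_expression.tsv"
    sio.write_celltype_summary(atlas.celltype, p)
    written.append(p)
    p = outdir / "truth.tsv"
    sio.write_truth(truth, p)
    written.append(p)
    return written
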