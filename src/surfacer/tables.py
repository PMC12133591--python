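"""In-memory containers for the pipeline's tables.

The quantification table keeps intensities and specific-peptide counts as two
aligned DataFrames (proteins x runs). Missing intensities are NaN and are
*never* conflated with zero; peptide counts are always defined (0 when the
run produced no evidence).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, ValidationError

CONDITIONS = ("biot", "nb")


def run_label(condition: str, replicate: int) -> str:
    return f"{condition}.{replicate}"


def parse_run_label(label: str) -> tuple[str, int]:
    cond, _, rep = label.partition(".")
    if cond not in CONDITIONS or not rep.isdigit():
        raise SchemaError(f"malformed run label {label!r}")
    return cond, int(rep)


@dataclass
class ProteinQuantTable:
    """Per-PDX protein x run table of log2 intensities and peptide counts.

    ``intensity`` holds log2 LFQ intensities with NaN for missing values;
    ``peptides`` holds non-negative specific-peptide counts (0 when absent).
    Columns are run labels ``biot.1 .. biot.B, nb.1 .. nb.C``; the index is
    the protein accession.
    """

    pdx_id: str
    intensity: pd.DataFrame
    peptides: pd.DataFrame

    @property
    def runs(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def biot_runs(self) -> list[str]:
        return [r for r in self.runs if parse_run_label(r)[0] == "biot"]

    @property
    def nb_runs(self) -> list[str]:
        return [r for r in self.runs if parse_run_label(r)[0] == "nb"]

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensity.index

    def validate(self) -> "ProteinQuantTable":
        if list(self.intensity.columns) != list(self.peptides.columns):
            raise SchemaError("intensity and peptide run columns differ")
        if not self.intensity.index.equals(self.peptides.index):
            raise SchemaError("intensity and peptide protein indices differ")
        if not self.intensity.index.is_unique:
            dup = self.intensity.index[self.intensity.index.duplicated()][0]
            raise ValidationError(f"duplicate protein_id {dup!r}")
        pairs = [parse_run_label(r) for r in self.runs]
        if len(set(pairs)) != len(pairs):
            raise SchemaError("duplicate (condition, replicate) run")
        if not self.biot_runs:
            raise SchemaError(f"{self.pdx_id}: no biot runs")
        if not self.nb_runs:
            raise SchemaError(f"{self.pdx_id}: no nb runs")
        if (self.peptides.to_numpy() < 0).any():
            raise ValidationError("negative peptide count")
        if self.peptides.isna().to_numpy().any():
            raise ValidationError("peptide counts must not be missing")
        return self

    def copy(self) -> "ProteinQuantTable":
        return ProteinQuantTable(self.pdx_id, self.intensity.copy(),
                                 self.peptides.copy())

    def equals(self, other: "ProteinQuantTable") -> bool:
        return (self.pdx_id == other.pdx_id
                and self.intensity.equals(other.intensity)
                and self.peptides.equals(other.peptides))


@dataclass
class AnnotationTable:
    """Protein annotations: gene symbol, membrane flag, keywords, known-target flag.

    Backed by a DataFrame indexed by protein accession with columns
    ``gene_symbol`` (str), ``is_membrane`` (bool), ``subcellular_keywords``
    (list of str) and ``known_car_target`` (bool).
    """

    df: pd.DataFrame

    REQUIRED = ("gene_symbol", "is_membrane", "subcellular_keywords",
                "known_car_target")

    def validate(self) -> "AnnotationTable":
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise SchemaError(f"annotation table missing column {col!r}")
        if not self.df.index.is_unique:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValidationError(f"duplicate protein_id {dup!r}")
        for pid, row in self.df.iterrows():
            if "membrane" in row["subcellular_keywords"] and not row["is_membrane"]:
                raise ValidationError(
                    f"{pid}: keyword 'membrane' present but is_membrane is false")
        return self

    def gene_of(self) -> pd.Series:
        return self.df["gene_symbol"]


@dataclass
class ExpressionAtlas:
    """Tissue- and cell-type-level expression references.

    ``tissue`` is a gene x tissue matrix in nTPM-like units (>= 0).
    ``celltype`` is a long table indexed by (gene_symbol, celltype) with
    ``frac_expressing`` in [0, 1] and ``mean_expr`` >= 0, the two quantities
    a dot plot encodes.
    """

    tissue: pd.DataFrame
    celltype: pd.DataFrame
    lymphoid_tissues: frozenset = field(default_factory=frozenset)
    excluded_celltypes: frozenset = field(default_factory=frozenset)

    def validate(self) -> "ExpressionAtlas":
        if (self.tissue.to_numpy() < 0).any():
            raise ValidationError("negative tissue expression value")
        for col in ("frac_expressing", "mean_expr"):
            if col not in self.celltype.columns:
                raise SchemaError(f"celltype summary missing column {col!r}")
        frac = self.celltype["frac_expressing"].to_numpy()
        if ((frac < 0) | (frac > 1)).any():
            raise ValidationError("frac_expressing outside [0, 1]")
        if (self.celltype["mean_expr"].to_numpy() < 0).any():
            raise ValidationError("negative mean_expr")
        missing = set(self.lymphoid_tissues) - set(self.tissue.columns)
        if missing:
            raise SchemaError(
                f"lymphoid_tissues not in tissue matrix: {sorted(missing)}")
        celltypes = set(self.celltype.index.get_level_values("celltype"))
        missing = set(self.excluded_celltypes) - celltypes
        if missing:
            raise SchemaError(
                f"excluded_celltypes not in celltype summary: {sorted(missing)}")
        return self

    @property
    def tissues(self) -> list[str]:
        return list(self.tissue.columns)

    @property
    def celltypes(self) -> list[str]:
        return sorted(set(self.celltype.index.get_level_values("celltype")))
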