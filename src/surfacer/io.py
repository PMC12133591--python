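"""Readers and writers for every table the pipeline touches.

All dialects are UTF-8, tab-separated, one header row, ``#``-prefixed lines
ignored. Missing intensities are written as ``NA`` and parsed back to NaN —
never to zero, and zeros are never silently promoted to missing. Floats are
written with Python's shortest round-trip representation, so read(write(x))
is field-for-field identical.

Dialects
--------
``pdx_<k>.quant.tsv``
    ``protein_id`` then ``intensity.<cond>.<rep>`` and ``peptides.<cond>.<rep>``
    columns, conditions ``biot``/``nb``.
``annotations.tsv``
    ``protein_id, gene_symbol, is_membrane, subcellular_keywords, known_car_target``
    with ``;``-separated keywords.
``tissue_expression.tsv``
    ``gene_symbol`` plus one numeric column per tissue.
``celltype_expression.tsv``
    long form ``gene_symbol, celltype, frac_expressing, mean_expr``.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, SchemaError
from .tables import (AnnotationTable, ExpressionAtlas, ProteinQuantTable,
                     parse_run_label)

MISSING = "NA"


# ---------------------------------------------------------------------------
# low-level cell codecs
# ---------------------------------------------------------------------------

def _fmt_float(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return MISSING
    return repr(float(x))


def _fmt_bool(x) -> str:
    return "true" if x else "false"


def _parse_float(cell: str, where: str) -> float:
    if cell == "" or cell == MISSING:
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"{where}: cannot parse {cell!r} as a number") from None


def _parse_int(cell: str, where: str) -> int:
    if cell == "" or cell == MISSING:
        return 0
    try:
        return int(cell)
    except ValueError:
        raise FormatError(f"{where}: cannot parse {cell!r} as an integer") from None


def _parse_bool(cell: str, where: str) -> bool:
    low = cell.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise FormatError(f"{where}: cannot parse {cell!r} as a boolean")


def _read_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(line_number, cells), ...]) skipping # comments."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if line == "" and header is not None:
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                rows.append((lineno, cells))
    if header is None:
        raise SchemaError(f"{path}: empty file, no header row")
    return header, rows


def _write_rows(path, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

def read_quant_table(path, pdx_id: str, linear: bool = False) -> ProteinQuantTable:
    """Read a per-PDX quantification table.

    With ``linear=True`` the intensity columns are interpreted as raw
    (linear-scale) values and log2-transformed on read; missing cells stay
    missing and non-positive values are a format error rather than being
    coerced.
    """
    header, rows = _read_rows(path)
    if not header or header[0] != "protein_id":
        raise SchemaError(f"{path}: first column must be 'protein_id'")
    int_cols: list[str] = []
    pep_cols: list[str] = []
    for col in header[1:]:
        kind, _, run = col.partition(".")
        if kind not in ("intensity", "peptides"):
            raise SchemaError(f"{path}: unexpected column {col!r}")
        try:
            parse_run_label(run)
        except SchemaError:
            raise FormatError(
                f"{path}: unknown condition token in column {col!r}") from None
        (int_cols if kind == "intensity" else pep_cols).append(run)
    if sorted(int_cols) != sorted(pep_cols):
        raise SchemaError(f"{path}: intensity and peptide run columns differ")

    ids: list[str] = []
    seen: set[str] = set()
    ivals: list[list[float]] = []
    pvals: list[list[int]] = []
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} cells, "
                              f"got {len(cells)}")
        pid = cells[0]
        if pid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
        seen.add(pid)
        ids.append(pid)
        rec = dict(zip(header[1:], cells[1:]))
        irow, prow = [], []
        for run in int_cols:
            x = _parse_float(rec[f"intensity.{run}"], f"{path}:{lineno}")
            if linear and not math.isnan(x):
                if x <= 0:
                    raise FormatError(
                        f"{path}:{lineno}: non-positive linear intensity {x}")
                x = math.log2(x)
            irow.append(x)
        for run in int_cols:
            prow.append(_parse_int(rec[f"peptides.{run}"], f"{path}:{lineno}"))
        ivals.append(irow)
        pvals.append(prow)

    index = pd.Index(ids, name="protein_id")
    intensity = pd.DataFrame(ivals, index=index, columns=int_cols, dtype=float)
    peptides = pd.DataFrame(pvals, index=index, columns=int_cols, dtype=int)
    return ProteinQuantTable(pdx_id, intensity, peptides).validate()


def write_quant_table(table: ProteinQuantTable, path) -> None:
    runs = table.runs
    header = (["protein_id"]
              + [f"intensity.{r}" for r in runs]
              + [f"peptides.{r}" for r in runs])
    rows = []
    pep = table.peptides
    for pid in table.protein_ids:
        irow = [_fmt_float(v) for v in table.intensity.loc[pid, runs]]
        prow = [str(int(v)) for v in pep.loc[pid, runs]]
        rows.append([str(pid)] + irow + prow)
    _write_rows(path, header, rows)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANNOT_COLS = ("protein_id", "gene_symbol", "is_membrane",
               "subcellular_keywords", "known_car_target")


def read_annotations(path) -> AnnotationTable:
    header, rows = _read_rows(path)
    for col in _ANNOT_COLS:
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    idx = {c: header.index(c) for c in _ANNOT_COLS}
    recs = []
    for lineno, cells in rows:
        where = f"{path}:{lineno}"
        kw = cells[idx["subcellular_keywords"]]
        recs.append({
            "protein_id": cells[idx["protein_id"]],
            "gene_symbol": cells[idx["gene_symbol"]],
            "is_membrane": _parse_bool(cells[idx["is_membrane"]], where),
            "subcellular_keywords": [k for k in kw.split(";") if k],
            "known_car_target": _parse_bool(cells[idx["known_car_target"]], where),
        })
    df = pd.DataFrame.from_records(recs).set_index("protein_id") if recs else \
        pd.DataFrame(columns=list(_ANNOT_COLS[1:])).rename_axis("protein_id")
    return AnnotationTable(df).validate()


def write_annotations(annotations: AnnotationTable, path) -> None:
    rows = []
    for pid, row in annotations.df.iterrows():
        rows.append([str(pid), row["gene_symbol"], _fmt_bool(row["is_membrane"]),
                     ";".join(row["subcellular_keywords"]),
                     _fmt_bool(row["known_car_target"])])
    _write_rows(path, list(_ANNOT_COLS), rows)


# ---------------------------------------------------------------------------
# expression atlases
# ---------------------------------------------------------------------------

def read_tissue_matrix(path) -> pd.DataFrame:
    header, rows = _read_rows(path)
    if not header or header[0] != "gene_symbol":
        raise SchemaError(f"{path}: first column must be 'gene_symbol'")
    tissues = header[1:]
    genes, vals = [], []
    for lineno, cells in rows:
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row")
        genes.append(cells[0])
        vals.append([_parse_float(c, f"{path}:{lineno}") for c in cells[1:]])
    return pd.DataFrame(vals, index=pd.Index(genes, name="gene_symbol"),
                        columns=tissues, dtype=float)


def write_tissue_matrix(tissue: pd.DataFrame, path) -> None:
    header = ["gene_symbol"] + list(tissue.columns)
    rows = [[str(g)] + [_fmt_float(v) for v in tissue.loc[g]]
            for g in tissue.index]
    _write_rows(path, header, rows)


_CT_COLS = ("gene_symbol", "celltype", "frac_expressing", "mean_expr")


def read_celltype_summary(path) -> pd.DataFrame:
    header, rows = _read_rows(path)
    for col in _CT_COLS:
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    idx = {c: header.index(c) for c in _CT_COLS}
    recs = []
    for lineno, cells in rows:
        where = f"{path}:{lineno}"
        recs.append((cells[idx["gene_symbol"]], cells[idx["celltype"]],
                     _parse_float(cells[idx["frac_expressing"]], where),
                     _parse_float(cells[idx["mean_expr"]], where)))
    df = pd.DataFrame(recs, columns=list(_CT_COLS))
    return df.set_index(["gene_symbol", "celltype"])


def write_celltype_summary(celltype: pd.DataFrame, path) -> None:
    rows = [[str(g), str(c), _fmt_float(r["frac_expressing"]),
             _fmt_float(r["mean_expr"])]
            for (g, c), r in celltype.iterrows()]
    _write_rows(path, list(_CT_COLS), rows)


def read_atlas(tissue_path, celltype_path,
               lymphoid_tissues: Iterable[str],
               excluded_celltypes: Iterable[str]) -> ExpressionAtlas:
    atlas = ExpressionAtlas(
        tissue=read_tissue_matrix(tissue_path),
        celltype=read_celltype_summary(celltype_path),
        lymphoid_tissues=frozenset(lymphoid_tissues),
        excluded_celltypes=frozenset(excluded_celltypes),
    )
    return atlas.validate()


# ---------------------------------------------------------------------------
# surface calls, candidates, waterfall, truth
# ---------------------------------------------------------------------------

CALL_SCHEMA = {
    "pdx_id": str, "protein_id": str, "log2fc": float, "t_stat": float,
    "p_value": float, "q_value": float, "n_biot_quantified": int,
    "peptide_rule_pass": bool, "detected": bool,
}

CANDIDATE_SCHEMA = {
    "protein_id": str, "gene_symbol": str, "n_pdx_detected": int,
    "mean_log2fc": float, "tau": float, "lymphoid_max": float,
    "nonlymphoid_max": float, "lymphoid_fold": float,
    "max_excluded_frac": float, "surface_any": bool, "membrane": bool,
    "prevalent": bool, "lymphoid_specific": bool, "not_excluded": bool,
    "known_car_target": bool, "rank_score": float, "rank": int,
}

TRUTH_SCHEMA = {
    "protein_id": str, "is_surface": bool, "is_membrane_annotated": bool,
    "tissue_archetype": str, "planted_detected_in": str,
}


def _write_schema_frame(df: pd.DataFrame, schema: dict, path,
                        index_col: str | None) -> None:
    frame = df.reset_index() if index_col else df
    header = list(schema)
    rows = []
    for _, row in frame.iterrows():
        cells = []
        for col, typ in schema.items():
            v = row[col]
            if typ is float:
                cells.append(_fmt_float(v))
            elif typ is bool:
                cells.append(_fmt_bool(v))
            elif typ is int:
                cells.append(MISSING if pd.isna(v) else str(int(v)))
            else:
                cells.append(str(v))
        rows.append(cells)
    _write_rows(path, header, rows)


def _read_schema_frame(path, schema: dict, index_col: str | None) -> pd.DataFrame:
    header, rows = _read_rows(path)
    for col in schema:
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    idx = {c: header.index(c) for c in schema}
    recs = []
    for lineno, cells in rows:
        where = f"{path}:{lineno}"
        rec = {}
        for col, typ in schema.items():
            cell = cells[idx[col]]
            if typ is float:
                rec[col] = _parse_float(cell, where)
            elif typ is bool:
                rec[col] = _parse_bool(cell, where)
            elif typ is int:
                rec[col] = (pd.NA if cell in ("", MISSING)
                            else _parse_int(cell, where))
            else:
                rec[col] = cell
        recs.append(rec)
    df = pd.DataFrame.from_records(recs) if recs else \
        pd.DataFrame(columns=list(schema))
    for col, typ in schema.items():
        if typ is int:
            df[col] = df[col].astype("Int64")
        elif typ is bool and not df.empty:
            df[col] = df[col].astype(bool)
    if index_col:
        df = df.set_index(index_col)
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    _write_schema_frame(calls, CALL_SCHEMA, path, index_col=None)


def read_calls(path) -> pd.DataFrame:
    df = _read_schema_frame(path, CALL_SCHEMA, index_col=None)
    df["n_biot_quantified"] = df["n_biot_quantified"].astype(int)
    return df


def write_candidates(candidates: pd.DataFrame, path) -> None:
    _write_schema_frame(candidates, CANDIDATE_SCHEMA, path,
                        index_col="protein_id")


def read_candidates(path) -> pd.DataFrame:
    return _read_schema_frame(path, CANDIDATE_SCHEMA, index_col="protein_id")


def write_waterfall(waterfall: list[tuple[str, int]], path) -> None:
    _write_rows(path, ["stage", "count"],
                [[stage, str(int(count))] for stage, count in waterfall])


def read_waterfall(path) -> list[tuple[str, int]]:
    header, rows = _read_rows(path)
    if header[:2] != ["stage", "count"]:
        raise SchemaError(f"{path}: expected columns stage, count")
    return [(cells[0], int(cells[1])) for _, cells in rows]


def write_truth(truth: pd.DataFrame, path) -> None:
    _write_schema_frame(truth, TRUTH_SCHEMA, path, index_col="protein_id")


def read_truth(path) -> pd.DataFrame:
    return _read_schema_frame(path, TRUTH_SCHEMA, index_col="protein_id")
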