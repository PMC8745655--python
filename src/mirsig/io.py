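"""Readers and writers for the pipeline's interchange formats.

All formats are plain text: TSV/CSV matrices and tables, plus the packaged
46-row fold/adjusted-p fixture used throughout the tests. Scientific
notation in the fixture was normalized to standard ``e``-exponent form at
transcription time; the shipped file is integrity-checked by SHA-256.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "load_table1_fixture",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_contrast_table",
    "write_contrast_table",
    "read_wide_fold_table",
    "write_wide_fold_table",
    "read_target_table",
    "read_go_annotations",
    "read_long_de_table",
    "write_long_de_table",
    "TABLE1_SHA256",
]

TABLE1_SHA256 = "671043e49ce20e59e18ea8ae7927c31872cea206ffe07d32b959cbf98563a7c9"


def _fixture_path() -> Path:
    return Path(resources.files("mirsig").joinpath("data/table1.csv"))


def load_table1_fixture(verify: bool = True) -> pd.DataFrame:
    """The packaged 46-miRNA fold / adjusted-p table.

    Returns a DataFrame indexed by miRNA name with an ``accession`` column
    plus ``fold_<line>`` and ``padj_<line>`` columns for the four resistant
    lines. Raises if the shipped file fails its checksum.
    """
    path = _fixture_path()
    if verify:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != TABLE1_SHA256:
            raise ValueError(
                f"packaged fixture checksum mismatch: expected {TABLE1_SHA256}, got {digest}"
            )
    table = pd.read_csv(path)
    return table.set_index("mirna")


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    # round_trip parsing so write . read is the identity on float64 values
    return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)


def read_expression_matrix(path, groups: pd.Series | None = None) -> ExpressionMatrix:
    """Read a feature x sample TSV/CSV matrix.

    The first column holds feature identifiers, the header row sample
    identifiers. Group labels come from ``groups`` when given, otherwise
    from the sample names by stripping a trailing ``_<replicate>`` suffix.
    """
    table = _read_delimited(path, index_col=0)
    non_numeric = [c for c in table.columns if not pd.api.types.is_numeric_dtype(table[c])]
    if non_numeric:
        raise ValueError(f"non-numeric sample columns: {non_numeric}")
    if table.isna().any().any():
        raise ValueError("matrix contains missing values (ragged rows or empty cells)")
    if groups is None:
        groups = pd.Series({s: str(s).rsplit("_", 1)[0] for s in table.columns})
    return ExpressionMatrix(table, groups)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> Path:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    out = matrix.values.copy()
    out.index.name = out.index.name or "feature"
    # repr-format floats so read . write is the identity on values
    out.to_csv(path, sep=sep, float_format=None)
    return path


def read_contrast_table(path) -> pd.DataFrame:
    table = _read_delimited(path)
    required = {"feature", "log2_diff", "signed_fold", "t_mod", "p_raw", "p_adj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"contrast table missing columns: {sorted(missing)}")
    return table.set_index("feature")


def write_contrast_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = ["log2_diff", "signed_fold", "t_mod", "p_raw", "p_adj"]
    out = table[cols].copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")
    return path


def read_wide_fold_table(path) -> pd.DataFrame:
    """Wide selection input: index miRNA, fold_<line> / padj_<line> columns."""
    table = _read_delimited(path, index_col=0)
    if not any(c.startswith("fold_") for c in table.columns):
        raise ValueError("expected fold_<line> columns in wide fold table")
    return table


def write_wide_fold_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = table.copy()
    out.index.name = out.index.name or "mirna"
    out.to_csv(path, sep="\t")
    return path


def read_target_table(path) -> pd.DataFrame:
    """One miRNA->gene edge table: columns mirna, gene (and optional source)."""
    table = _read_delimited(path)
    missing = {"mirna", "gene"} - set(table.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    return table


def read_go_annotations(path) -> pd.DataFrame:
    table = _read_delimited(path)
    missing = {"gene", "term"} - set(table.columns)
    if missing:
        raise ValueError(f"GO annotation table missing columns: {sorted(missing)}")
    return table


def read_long_de_table(path) -> pd.DataFrame:
    table = _read_delimited(path)
    missing = {"cell_line", "feature", "signed_fold", "p_adj"} - set(table.columns)
    if missing:
        raise ValueError(f"long DE table missing columns: {sorted(missing)}")
    return table


def write_long_de_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path
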