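"""Plain-text readers and writers: GMT gene sets, TSV matrices, CSV reports.

All interchange is tab- or comma-separated text with explicit headers —
desk-scale data that stays diffable.  Rank matrices are validated as
permutations on load; score matrices are rank-transformed column-wise.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .connectivity import GeneSet, rank_transform
from .errors import GMTFormatError, MatrixFormatError
from .signature import ExpressionMatrix, SignaturePair
from .simulate import CTPLibrary, GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_matrix",
    "write_library",
    "write_deg_table",
    "write_screen_report",
    "write_scatter",
    "write_ground_truth",
    "read_id_list",
]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members per line).

    Duplicate members within a set are collapsed with a warning (inside
    :class:`GeneSet`); a line with fewer than three fields is an error
    reported with its line number.  Sets with an empty member list are
    permitted (a third, empty field is still required).
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTFormatError(
                    f"expected >= 3 tab-separated fields, got {len(fields)}",
                    line_number=lineno,
                )
            name, _description, *members = fields
            members = [m.strip() for m in members if m.strip()]
            sets.append(GeneSet(name=name, members=tuple(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            # an empty set still gets a third (empty) member field
            members = gs.members if gs.members else ("",)
            fh.write("\t".join([gs.name, description, *members]) + "\n")


def signature_from_gmt(path: str | Path) -> SignaturePair:
    """Load a two-set GMT as a signature; set names must be 'up' and 'down'."""
    sets = {gs.name: gs for gs in read_gmt(path)}
    if not {"up", "down"} <= set(sets):
        raise GMTFormatError(
            f"signature GMT must contain sets named 'up' and 'down'; got {sorted(sets)}"
        )
    return SignaturePair(up=sets["up"], down=sets["down"], provenance=str(path))


def _read_rectangular_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.isna().any().any():
        raise MatrixFormatError(f"{path}: missing values (ragged rows?)")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"{path}: duplicate row identifiers {dups[:5]}")
    df.index.name = None
    df.columns.name = None
    return df


def read_expression(
    matrix_path: str | Path, condition_path: str | Path, reference: str = "A"
) -> ExpressionMatrix:
    """Read an expression TSV plus its two-column (sample, group) sidecar."""
    values = _read_rectangular_tsv(matrix_path)
    cond = pd.read_csv(condition_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values=values, condition=cond, reference=reference)


def write_expression(
    expr: ExpressionMatrix, matrix_path: str | Path, condition_path: str | Path
) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    expr.condition.rename("group").to_csv(
        condition_path, sep="\t", index_label="sample"
    )


def read_matrix(
    path: str | Path, kind: Literal["expression", "ranks", "scores"]
) -> ExpressionMatrix | CTPLibrary:
    """Read a genes x columns TSV as expression values, ranks or scores.

    ``kind='ranks'`` validates every column as a permutation of ``1..n``;
    ``kind='scores'`` rank-transforms each column (largest score -> rank 1);
    ``kind='expression'`` requires non-negative values and a separate
    condition file, so use :func:`read_expression` instead for that case.
    """
    df = _read_rectangular_tsv(path)
    if kind == "expression":
        raise MatrixFormatError(
            "expression matrices need a condition sidecar; use read_expression()"
        )
    if kind == "ranks":
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.all(arr == arr.astype(int)):
            raise MatrixFormatError(f"{path}: rank matrix must contain integers")
        try:
            return CTPLibrary(df.astype(np.int64))
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: {exc}") from exc
    if kind == "scores":
        genes = list(df.index)
        cols = {}
        for comp in df.columns:
            profile = rank_transform(genes, df[comp].to_numpy(float), compound_id=comp)
            cols[comp] = profile.ranks
        return CTPLibrary(pd.DataFrame(cols, index=genes))
    raise MatrixFormatError(f"unknown matrix kind {kind!r}")


def write_library(library: CTPLibrary, path: str | Path) -> None:
    library.ranks.to_csv(path, sep="\t", index_label="gene")


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    deg.to_csv(path, index_label="gene")


def write_screen_report(report, path: str | Path) -> None:
    report.to_frame().to_csv(path, index=False)


def write_scatter(report, path: str | Path) -> None:
    """ES pairs as scatter coordinates (x = up-set ES, y = down-set ES)."""
    frame = report.to_frame()[["compound_id", "es_up", "es_down", "selected"]]
    frame = frame.rename(columns={"es_up": "x", "es_down": "y"})
    frame.to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    """One plain-text identifier list per ground-truth category."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("deg_up_ids", "deg_down_ids", "reverser_ids", "mimicker_ids"):
        with open(directory / f"{name}.txt", "w") as fh:
            for ident in getattr(truth, name):
                fh.write(ident + "\n")


def read_id_list(path: str | Path) -> tuple[str, ...]:
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())
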