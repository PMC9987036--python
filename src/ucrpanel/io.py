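"""Reading and writing expression matrices and sample annotations.

An expression matrix is a :class:`pandas.DataFrame` of log2 intensities with
probe identifiers as the index (convention ``uc.<n>+`` for sense probes and
``uc.<n>+A`` for antisense probes) and sample identifiers as columns.  Sample
annotations are a DataFrame indexed by sample id with columns ``group``
(one of ``NBE``, ``LG``, ``HG``), ``survival_months`` and ``event``.

Values are assumed already log2-normalized upstream; no normalization is
performed here.  Missing values are allowed only in spot-level (replicate)
matrices and are removed by :func:`collapse_replicates`.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens recognized as missing values (case-insensitive).  Anything else
#: non-numeric in a matrix cell is an error, never silently missing.
MISSING_TOKENS = frozenset({"", "na", "null"})

#: Sample groups: normal bladder epithelium controls, low-grade and
#: high-grade bladder cancer.
GROUPS = ("NBE", "LG", "HG")

_PROBE_NAME_RE = re.compile(r"^uc\.\d+\+(A)?$")


class ExpressionIOError(ValueError):
    """Raised for malformed expression matrices or annotation tables."""


def _coerce_numeric(raw: pd.DataFrame, path: str) -> pd.DataFrame:
    """Convert string cells to floats, mapping missing tokens to NaN.

    Raises :class:`ExpressionIOError` naming the offending row/column for any
    cell that is neither numeric nor a recognized missing token.
    """
    def parse_cell(value: object, probe: str, sample: str) -> float:
        if isinstance(value, (int, float, np.integer, np.floating)):
            return float(value)
        text = str(value).strip()
        if text.lower() in MISSING_TOKENS:
            return np.nan
        try:
            return float(text)
        except ValueError:
            raise ExpressionIOError(
                f"{path}: non-numeric value {value!r} at probe {probe!r}, "
                f"sample {sample!r}"
            ) from None

    out = pd.DataFrame(
        [
            [parse_cell(raw.iat[i, j], str(raw.index[i]), str(raw.columns[j]))
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )
    return out


def validate_expression_matrix(matrix: pd.DataFrame, *, allow_missing: bool = False,
                               source: str = "expression matrix") -> None:
    """Check the expression-matrix invariants, raising on violation.

    Probe and sample identifiers must be unique and the matrix non-empty;
    unless ``allow_missing`` (spot-level data awaiting replicate collapsing),
    every value must be finite.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ExpressionIOError(f"{source}: empty matrix")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ExpressionIOError(f"{source}: duplicate probe id(s): {dupes}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ExpressionIOError(f"{source}: duplicate sample id(s): {dupes}")
    values = matrix.to_numpy(dtype=float)
    if not allow_missing and not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise ExpressionIOError(
            f"{source}: {n_bad} non-finite value(s); missing values are only "
            "allowed in spot-level matrices before replicate collapsing"
        )


def lint_probe_names(probe_ids: Sequence[str]) -> list[str]:
    """Return probe ids not matching the ``uc.<n>+`` / ``uc.<n>+A`` convention.

    Advisory only: probe ids are treated as opaque strings everywhere else.
    """
    offenders = [p for p in probe_ids if not _PROBE_NAME_RE.match(str(p))]
    if offenders:
        logger.warning(
            "%d probe id(s) do not follow the uc.<n>+ / uc.<n>+A naming "
            "convention (first: %r)", len(offenders), offenders[0],
        )
    return offenders


def read_expression_matrix(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a probes x samples log2 expression matrix.

    Parameters
    ----------
    path:
        Tab-separated file with a header row of sample ids and probe ids in
        the first column.
    format:
        ``"tsv"`` for plain TSV, or ``"geo_series_matrix"`` for the GEO
        series-matrix text dialect (``!``-prefixed metadata lines, the table
        fenced by ``!series_matrix_table_begin`` / ``!series_matrix_table_end``,
        identifiers possibly double-quoted).
    """
    path = Path(path)
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False)
    elif format == "geo_series_matrix":
        lines = path.read_text().splitlines()
        begin = [i for i, ln in enumerate(lines)
                 if ln.startswith("!series_matrix_table_begin")]
        end = [i for i, ln in enumerate(lines)
               if ln.startswith("!series_matrix_table_end")]
        if begin and end:
            table = lines[begin[0] + 1:end[0]]
        else:
            # tolerate a fence-less file: drop metadata lines
            table = [ln for ln in lines if not ln.startswith("!")]
        table = [ln for ln in table if ln.strip()]
        if not table:
            raise ExpressionIOError(f"{path}: empty series-matrix table")
        rows = [[cell.strip().strip('"') for cell in ln.split("\t")]
                for ln in table]
        header = rows[0]
        raw = pd.DataFrame([r[1:] for r in rows[1:]],
                           index=pd.Index([r[0] for r in rows[1:]],
                                          name=header[0]),
                           columns=header[1:])
    else:
        raise ValueError(f"unknown expression matrix format: {format!r}")

    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    matrix = _coerce_numeric(raw, str(path))
    validate_expression_matrix(matrix, allow_missing=True, source=str(path))
    return matrix


def collapse_replicates(matrix: pd.DataFrame,
                        replicate_map: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Collapse spot-level replicate rows to one row per probe.

    The collapsed value is the median of the non-missing replicate values
    (each probe is spotted multiple times on the array, so several numerical
    values exist per probe and sample).  A probe whose replicates are all
    missing for every sample is dropped with a log message; cells where all
    replicates are missing but others are not would violate the collapsed
    invariants and raise.

    Parameters
    ----------
    matrix:
        Spot-level matrix whose index contains every spot row id named in
        ``replicate_map``; missing values (NaN) are permitted.
    replicate_map:
        Maps each probe id to its spot row ids.  Each spot id must belong to
        exactly one probe.
    """
    claimed: dict[str, str] = {}
    for probe, spots in replicate_map.items():
        for spot in spots:
            if spot in claimed:
                raise ExpressionIOError(
                    f"spot id {spot!r} claimed by both probe "
                    f"{claimed[spot]!r} and probe {probe!r}"
                )
            claimed[spot] = probe
            if spot not in matrix.index:
                raise ExpressionIOError(
                    f"spot id {spot!r} (probe {probe!r}) not present in matrix"
                )

    collapsed_rows = {}
    dropped = []
    for probe, spots in replicate_map.items():
        block = matrix.loc[list(spots)].to_numpy(dtype=float)
        if np.isnan(block).all():
            dropped.append(probe)
            continue
        with np.errstate(all="ignore"):
            med = np.nanmedian(block, axis=0)
        if np.isnan(med).any():
            bad = matrix.columns[np.isnan(med)].tolist()
            raise ExpressionIOError(
                f"probe {probe!r}: all replicates missing for sample(s) {bad}"
            )
        collapsed_rows[probe] = med
    if dropped:
        logger.info("collapse_replicates: dropped %d probe(s) with all "
                    "replicates missing: %s", len(dropped), dropped)
    collapsed = pd.DataFrame.from_dict(collapsed_rows, orient="index",
                                       columns=matrix.columns)
    collapsed.index.name = matrix.index.name or "probe_id"
    validate_expression_matrix(collapsed, source="collapsed matrix")
    return collapsed


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation TSV (sample_id, group, survival_months, event).

    ``survival_months`` and ``event`` may be missing (typically for NBE
    controls).  Group labels must be one of NBE/LG/HG; survival months must
    be non-negative; sample ids must be unique.
    """
    ann = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str})
    if "sample_id" not in ann.columns or "group" not in ann.columns:
        raise ExpressionIOError(f"{path}: annotation needs 'sample_id' and "
                                "'group' columns")
    ann = ann.set_index("sample_id")
    validate_annotation(ann, source=str(path))
    return ann


def validate_annotation(ann: pd.DataFrame, source: str = "annotation") -> None:
    if ann.index.has_duplicates:
        dupes = ann.index[ann.index.duplicated()].unique().tolist()
        raise ExpressionIOError(f"{source}: duplicate sample id(s): {dupes}")
    bad_groups = sorted(set(ann["group"]) - set(GROUPS))
    if bad_groups:
        raise ExpressionIOError(f"{source}: unknown group label(s) "
                                f"{bad_groups}; expected one of {GROUPS}")
    if "survival_months" in ann.columns:
        surv = pd.to_numeric(ann["survival_months"], errors="coerce")
        if (surv.dropna() < 0).any():
            raise ExpressionIOError(f"{source}: negative survival_months")
    if "event" in ann.columns:
        ev = pd.to_numeric(ann["event"], errors="coerce").dropna()
        if not ev.isin([0, 1]).all():
            raise ExpressionIOError(f"{source}: event indicator must be 0/1")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular result as TSV with a header and deterministic columns.

    Round-trips through ``pandas.read_csv(..., sep="\\t")`` at full printed
    precision (pandas writes ``repr``-exact floats).
    """
    if records is None or len(records) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    records.to_csv(Path(path), sep="\t",
                   index=records.index.name is not None)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix as TSV (probes in rows, samples in columns)."""
    if matrix is None or matrix.shape[0] == 0:
        raise ValueError(f"refusing to write empty matrix to {path}")
    out = matrix.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(Path(path), sep="\t")
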