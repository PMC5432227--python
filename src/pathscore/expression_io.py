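"""Gene-by-sample expression matrices and sample annotation tables.

Matrices are plain TSV: header row of sample ids, first column gene
symbols. Annotations are TSV with at least ``sample_id`` and ``group``
columns; survival and pairing fields are optional.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORM_COUNTS = "counts"
PLATFORM_CONTINUOUS = "continuous"

BENIGN = "benign"
TUMOUR = "tumour"

_GROUP_ALIASES = {
    "b": BENIGN, "benign": BENIGN, "normal": BENIGN, "control": BENIGN,
    "t": TUMOUR, "tumour": TUMOUR, "tumor": TUMOUR, "cancer": TUMOUR,
}

_TRUE = {"1", "y", "yes", "true", "event"}
_FALSE = {"0", "n", "no", "false", "censored"}


@dataclass
class ExpressionMatrix:
    """Numeric genes x samples matrix with a platform tag.

    ``values`` index = gene symbols, columns = sample ids, both unique.
    ``platform`` is ``counts`` (raw, non-negative integers) or
    ``continuous``; ``normalized`` marks depth- or quantile-normalized data.
    """

    values: pd.DataFrame
    platform: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.platform not in (PLATFORM_COUNTS, PLATFORM_CONTINUOUS):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("matrix values must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ValueError("missing values are not supported")
        if self.platform == PLATFORM_COUNTS and not self.normalized:
            if (arr < 0).any():
                raise ValueError("counts platform requires non-negative values")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts platform requires integer values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: group, cohort, pairing, survival, stage."""

    sample_id: str
    group: str
    cohort: Optional[str] = None
    pair_id: Optional[str] = None
    time_to_event: Optional[float] = None
    event: Optional[bool] = None
    stage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in (BENIGN, TUMOUR):
            raise ValueError(f"sample {self.sample_id!r}: unknown group {self.group!r}")
        if self.time_to_event is not None and self.time_to_event < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative time_to_event")
        if self.event is not None and self.time_to_event is None:
            raise ValueError(f"sample {self.sample_id!r}: event flag without time_to_event")


def read_expression(path: str | Path, platform: str) -> ExpressionMatrix:
    """Read a TSV matrix; collapse duplicate gene rows to the highest-mean row.

    Non-numeric cells raise with their coordinates; negative values under
    the counts platform are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy()][0]
            raise ValueError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        num[col] = converted
    if num.index.has_duplicates:
        n_dup = int(num.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows (keeping highest-mean row)", path, n_dup)
        num = (
            num.assign(_mean=num.mean(axis=1))
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        num = num.loc[~num.index.duplicated()]
    return ExpressionMatrix(values=num, platform=platform)


def write_expression(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format=float_format)


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().casefold()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"{where}: cannot interpret event flag {value!r}")


def _get(row: pd.Series, *names: str) -> Optional[str]:
    for n in names:
        if n in row.index:
            v = row[n]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            s = str(v).strip()
            if s and s.casefold() not in {"na", "nan", "", "-", "—"}:
                return s
    return None


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV.

    Required columns: ``sample_id``, ``group`` (aliases like T/B accepted).
    Optional: ``cohort``, ``pair_id``, ``time`` (or ``time_to_event``),
    ``event``, ``stage``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().casefold() for c in df.columns]
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: annotation table requires sample_id and group columns")
    out: list[SampleAnnotation] = []
    for i, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        raw_group = str(row["group"]).strip().casefold()
        if raw_group not in _GROUP_ALIASES:
            raise ValueError(f"{path} row {i + 2}: unknown group label {row['group']!r}")
        time_s = _get(row, "time", "time_to_event", "months")
        event_s = _get(row, "event")
        stage_s = _get(row, "stage")
        out.append(
            SampleAnnotation(
                sample_id=sid,
                group=_GROUP_ALIASES[raw_group],
                cohort=_get(row, "cohort"),
                pair_id=_get(row, "pair_id"),
                time_to_event=float(time_s) if time_s is not None else None,
                event=_parse_bool(event_s, f"{path} row {i + 2}") if event_s is not None else None,
                stage=int(stage_s) if stage_s is not None else None,
            )
        )
    ids = [a.sample_id for a in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids in annotations")
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append({
            "sample_id": a.sample_id,
            "group": a.group,
            "cohort": a.cohort or "",
            "pair_id": a.pair_id or "",
            "time": "" if a.time_to_event is None else f"{a.time_to_event:.10g}",
            "event": "" if a.event is None else int(a.event),
            "stage": "" if a.stage is None else a.stage,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotations_by_id(annotations: Iterable[SampleAnnotation]) -> dict[str, SampleAnnotation]:
    return {a.sample_id: a for a in annotations}


def align(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Restrict both inputs to their shared sample ids, in matrix order."""
    ann = annotations_by_id(annotations)
    shared = [s for s in matrix.samples if s in ann]
    if not shared:
        raise ValueError("no shared sample ids between matrix and annotations")
    dropped_m = sorted(set(matrix.samples) - set(shared))
    dropped_a = sorted(set(ann) - set(shared))
    if dropped_m:
        logger.warning("align: dropping %d matrix samples without annotations: %s", len(dropped_m), dropped_m)
    if dropped_a:
        logger.warning("align: dropping %d annotated samples absent from matrix: %s", len(dropped_a), dropped_a)
    aligned = replace(matrix, values=matrix.values[shared])
    return aligned, [ann[s] for s in shared]
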