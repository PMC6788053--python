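"""CSV/JSON input-output for matrices, masks and benchmark results.

Matrix files are plain CSV: first column sample id, header row feature ids,
numeric body, samples as rows.  Missing cells in masked matrices use a
configurable sentinel (default ``"NA"``).  Each simulated mask can carry a
JSON sidecar recording the mechanism spec, the seed and full per-event
provenance, sufficient to audit the mask after the fact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import IntensityMatrix
from .missingness import MaskedMatrix, MaskingEvent, MissingnessSpec

__all__ = [
    "FormatError",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_mask_sidecar",
    "read_mask_sidecar",
]

DEFAULT_SENTINEL = "NA"


class FormatError(ValueError):
    """Malformed matrix file (ragged rows, bad cells, duplicate ids)."""


def read_matrix_csv(
    path: str | Path, missing_sentinel: str = DEFAULT_SENTINEL
) -> IntensityMatrix | MaskedMatrix:
    """Parse a matrix CSV; sentinel (or empty) cells become missing entries.

    Returns an :class:`IntensityMatrix` when the file is complete, otherwise
    a :class:`MaskedMatrix` (with no ground-truth ``source``).
    """
    path = Path(path)
    # pandas silently renames duplicate header columns; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate feature ids {sorted(dupes)}")
    try:
        frame = pd.read_csv(
            path,
            index_col=0,
            keep_default_na=False,
            na_values=[missing_sentinel, ""],
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids {dupes}")
    try:
        values = frame.astype(float).to_numpy()
    except ValueError:
        str_frame = frame.astype(str)
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & (str_frame != "nan") & frame.notna()
        rows, cols = np.nonzero(bad.to_numpy())
        if rows.size:
            i, j = int(rows[0]), int(cols[0])
            raise FormatError(
                f"{path}: non-numeric cell {frame.iat[i, j]!r} at sample "
                f"{frame.index[i]!r}, feature {frame.columns[j]!r}"
            ) from None
        raise
    sample_ids = [str(s) for s in frame.index]
    feature_ids = [str(f) for f in frame.columns]
    mask = np.isnan(values)
    if not mask.any():
        return IntensityMatrix(values, sample_ids, feature_ids)
    return MaskedMatrix(
        values=values,
        mask=mask,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
    )


def write_matrix_csv(
    matrix: IntensityMatrix | MaskedMatrix | pd.DataFrame,
    path: str | Path,
    missing_sentinel: str = DEFAULT_SENTINEL,
) -> None:
    if isinstance(matrix, pd.DataFrame):
        frame = matrix
    elif isinstance(matrix, IntensityMatrix):
        frame = matrix.to_frame()
    else:
        frame = pd.DataFrame(
            matrix.values, index=matrix.sample_ids, columns=matrix.feature_ids
        )
    frame.to_csv(path, na_rep=missing_sentinel)


def _event_to_dict(event: MaskingEvent) -> dict:
    d = dataclasses.asdict(event)
    d["masked_cells"] = [[int(i), int(j)] for i, j in event.masked_cells]
    return d


def write_mask_sidecar(
    masked: MaskedMatrix, path: str | Path, seed: int | None = None
) -> None:
    """JSON provenance: spec, seed, per-event cells and per-step counts."""
    payload = {
        "spec": dataclasses.asdict(masked.spec) if masked.spec else None,
        "seed": seed,
        "shape": list(masked.shape),
        "n_missing": masked.n_missing,
        "step_counts": masked.step_counts(),
        "events": [_event_to_dict(ev) for ev in masked.events],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_mask_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("spec"):
        payload["spec"] = MissingnessSpec(**payload["spec"])
    payload["events"] = [
        MaskingEvent(
            step_mechanism=e["step_mechanism"],
            driver_feature=e["driver_feature"],
            target_feature=e["target_feature"],
            cutoff_fraction=e["cutoff_fraction"],
            masked_cells=[(int(i), int(j)) for i, j in e["masked_cells"]],
        )
        for e in payload["events"]
    ]
    return payload
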