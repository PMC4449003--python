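"""Readers and writers for the pipeline's file formats.

All tabular formats are UTF-8 comma-separated CSV with a header row;
trial indices are 0-based. Reports are JSON. A loader for externally
deposited trial data in MATLAB format is provided; since such files carry
no self-describing schema, the caller must supply a field map naming the
MAT variables that hold each canonical column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .gamble_engine import GamblePairSpec, OutcomeDistribution
from .inference import FitResult, TrialRecord
from .synthetic_cohort import DATASET_COLUMNS

__all__ = [
    "write_gamble_set",
    "read_gamble_set",
    "write_dataset",
    "read_dataset",
    "load_dataset",
    "write_fits",
    "read_fits",
    "write_json_report",
    "dataset_summary",
]

logger = logging.getLogger(__name__)

GAMBLE_COLUMNS = ["pair_id", "x0", "n", "gA", "pA", "gB", "pB"]


def write_gamble_set(pairs: list[GamblePairSpec], path: str | Path) -> None:
    rows = [
        {"pair_id": p.pair_id, "x0": p.x0, "n": p.n,
         "gA": p.gA, "pA": p.pA, "gB": p.gB, "pB": p.pB}
        for p in pairs
    ]
    pd.DataFrame(rows, columns=GAMBLE_COLUMNS).to_csv(path, index=False)


def read_gamble_set(path: str | Path) -> list[GamblePairSpec]:
    df = pd.read_csv(path)
    missing = set(GAMBLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gamble CSV missing columns {sorted(missing)}")
    return [
        GamblePairSpec(
            x0=int(r.x0), n=int(r.n), gA=int(r.gA), pA=float(r.pA),
            gB=int(r.gB), pB=float(r.pB), pair_id=int(r.pair_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_dataset(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns {sorted(missing)}")
    return df


def dataset_summary(records: list[TrialRecord]) -> dict:
    """Load summary: participants, trial counts, missed counts."""
    pids = sorted({r.participant_id for r in records})
    return {
        "n_participants": len(pids),
        "participant_ids": pids,
        "n_trials": len(records),
        "n_missed": sum(r.choice == "missed" for r in records),
    }


def _validate_rows(df: pd.DataFrame, source: str) -> list[TrialRecord]:
    records: list[TrialRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        # header is line 1, so data row i sits on line i + 2 of the file
        line = i + 2
        try:
            rt = float(row.rt_ms)
            if row.choice != "missed" and not np.isnan(rt) and rt <= 0:
                raise ValueError(f"rt_ms={rt} not positive on a non-missed trial")
            pair = GamblePairSpec(
                x0=int(row.x0), n=int(row.n),
                gA=int(row.gA), pA=float(row.pA),
                gB=int(row.gB), pB=float(row.pB),
                pair_id=int(row.pair_id),
            )
            records.append(
                TrialRecord(
                    participant_id=str(row.participant_id),
                    frame=str(row.frame),
                    block=int(row.block),
                    trial_index=int(row.trial_index),
                    pair=pair,
                    choice=str(row.choice),
                    rt_ms=rt,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"{source} line {line}: {exc}")
    if errors:
        shown = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise ValueError(f"malformed trial rows:\n{shown}{more}")
    return records


def load_dataset(
    path: str | Path,
    format: str = "csv",
    field_map: dict[str, str] | None = None,
    frame_codes: dict | None = None,
    choice_codes: dict | None = None,
) -> list[TrialRecord]:
    """Load trial-level data as validated TrialRecords.

    For ``format="csv"`` the canonical dataset schema is expected. For
    ``format="mat"`` a ``field_map`` is required, mapping every canonical
    column name (participant_id, frame, block, trial_index, pair_id, x0, n,
    gA, pA, gB, pB, choice, rt_ms) to the corresponding variable name inside
    the MAT file; each variable must flatten to one value per trial.
    ``frame_codes`` / ``choice_codes`` optionally translate numeric codes to
    the canonical labels (e.g. ``{1: "foraging", 0: "casino"}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = read_dataset(path)
    elif format == "mat":
        if field_map is None:
            raise ValueError(
                "MAT files carry no canonical schema; supply field_map "
                "naming the MAT variable for each dataset column"
            )
        from scipy.io import loadmat

        raw = loadmat(path, squeeze_me=True)
        missing = set(DATASET_COLUMNS) - set(field_map)
        if missing:
            raise ValueError(f"field_map missing entries for {sorted(missing)}")
        cols = {}
        for col in DATASET_COLUMNS:
            var = field_map[col]
            if var not in raw:
                raise ValueError(f"MAT file has no variable {var!r} (for {col})")
            cols[col] = np.asarray(raw[var]).reshape(-1)
        lengths = {len(v) for v in cols.values()}
        if len(lengths) != 1:
            raise ValueError(f"MAT variables have unequal lengths: {lengths}")
        df = pd.DataFrame(cols)
        if frame_codes:
            df["frame"] = df["frame"].map(lambda v: frame_codes.get(v, v))
        if choice_codes:
            df["choice"] = df["choice"].map(lambda v: choice_codes.get(v, v))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'mat'")

    records = _validate_rows(df, str(path))
    summary = dataset_summary(records)
    logger.info(
        "loaded %s: %d participants, %d trials (%d missed)",
        path, summary["n_participants"], summary["n_trials"], summary["n_missed"],
    )
    return records


def write_fits(results: list[FitResult], path: str | Path) -> None:
    from .inference import fits_to_frame

    fits_to_frame(results).to_csv(path, index=False)


def read_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, OutcomeDistribution):
        return obj.to_dict()
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")
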