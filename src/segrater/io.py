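"""Reading and writing the on-disk study artifacts.

Label sequences are stored as one single-channel PNG per frame plus a JSON
manifest (``sequence_manifest.json``) recording video id, fps, class names
and the ordered frame file list. PNG is lossless, so write → read is
bit-exact. Ratings and result tables travel as plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import EvalConfig, LabelMapSequence, RatingRecord, SampleKey

__all__ = [
    "read_label_sequence",
    "write_label_sequence",
    "read_ratings",
    "write_ratings",
    "write_table",
    "read_config",
]

MANIFEST_NAME = "sequence_manifest.json"

RATINGS_COLUMNS = [
    "participant_id",
    "cases_performed",
    "cases_assisted",
    "video_id",
    "structure",
    "accuracy_rating",
    "identification_rating",
]


def write_label_sequence(seq: LabelMapSequence, directory: str | Path) -> Path:
    """Write one PNG per frame plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(seq.class_names) > 256:
        raise ValueError("more than 256 classes cannot be stored as 8-bit PNG")
    frame_files = []
    for t in range(seq.T):
        name = f"frame_{t:05d}.png"
        Image.fromarray(seq.frames[t].astype(np.uint8), mode="L").save(directory / name)
        frame_files.append(name)
    manifest = {
        "video_id": seq.video_id,
        "fps": seq.fps,
        "class_names": list(seq.class_names),
        "frame_files": frame_files,
    }
    manifest_path = directory / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_label_sequence(manifest_path: str | Path) -> LabelMapSequence:
    """Load a frame-sequence directory back into a LabelMapSequence."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    manifest = json.loads(manifest_path.read_text())
    directory = manifest_path.parent
    class_names = list(manifest["class_names"])
    frames = []
    for name in manifest["frame_files"]:
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"frame file missing: {path}")
        frame = np.asarray(Image.open(path), dtype=np.int64)
        if frame.ndim != 2:
            raise ValueError(f"{path} is not a single-channel image")
        frames.append(frame)
    stack = np.stack(frames)
    if stack.max(initial=0) >= len(class_names):
        raise ValueError(
            f"label {int(stack.max())} exceeds the {len(class_names)} declared classes"
        )
    return LabelMapSequence(
        frames=stack,
        class_names=class_names,
        fps=float(manifest.get("fps", 25.0)),
        video_id=str(manifest["video_id"]),
    )


def write_ratings(records: Iterable[RatingRecord], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "cases_performed": r.cases_performed,
            "cases_assisted": r.cases_assisted,
            "video_id": r.sample.video_id,
            "structure": r.sample.structure,
            "accuracy_rating": r.accuracy_rating,
            "identification_rating": r.identification_rating,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RATINGS_COLUMNS).to_csv(path, index=False)


def read_ratings(csv_path: str | Path, config: EvalConfig) -> list[RatingRecord]:
    """Parse a ratings CSV, validating every row against the Likert bounds."""
    df = pd.read_csv(csv_path, dtype={"participant_id": str, "video_id": str, "structure": str})
    unknown = set(df.columns) - set(RATINGS_COLUMNS)
    if unknown:
        raise ValueError(f"unknown ratings columns: {sorted(unknown)}")
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing ratings columns: {sorted(missing)}")
    for col in ("cases_performed", "cases_assisted", "accuracy_rating", "identification_rating"):
        if df[col].isna().any() or not np.issubdtype(df[col].dtype, np.integer):
            raise ValueError(f"column {col!r} must hold integers with no gaps")
    records = []
    for row in df.itertuples(index=False):
        rec = RatingRecord(
            participant_id=row.participant_id,
            cases_performed=int(row.cases_performed),
            cases_assisted=int(row.cases_assisted),
            sample=SampleKey(video_id=row.video_id, structure=row.structure),
            accuracy_rating=int(row.accuracy_rating),
            identification_rating=int(row.identification_rating),
        )
        rec.validate_scale(config.likert_min, config.likert_max)
        records.append(rec)
    return records


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                columns: Sequence[str] | None = None,
                float_precision: int = 6) -> None:
    """Write keyed rows as CSV with deterministic column order.

    All rows must share one key set; floats are rendered at a fixed
    precision so reruns produce byte-identical files.
    """
    if rows:
        keys = list(rows[0].keys())
        for i, row in enumerate(rows):
            if list(row.keys()) != keys:
                raise ValueError(f"row {i} keys differ from row 0")
        if columns is None:
            columns = keys
    elif columns is None:
        raise ValueError("columns must be given for an empty table")
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, index=False, float_format=f"%.{float_precision}f")


def read_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — a YAML subset) config file into a dict."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data
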