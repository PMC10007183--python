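"""Readers and writers for recordings, feature tables and reports.

Delimited text is the canonical interchange format (one sample per row,
channel columns, metadata in a ``#``-comment header or JSON sidecar); EDF
files are read through MNE's packaged reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "read_recording",
    "read_recording_text",
    "read_recording_edf",
    "write_recording_text",
    "read_dataset_manifest",
    "checksum",
]


def write_recording_text(rec: Recording, path, delimiter: str = "\t") -> None:
    """Samples x channels delimited text with a metadata comment header."""
    meta = {"fs": rec.fs, "subject_id": rec.subject_id, "condition": rec.condition}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta)}\n")
        fh.write("# " + delimiter.join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=delimiter, fmt="%.8g")


def read_recording_text(path, fs: "float | None" = None) -> Recording:
    """Read a delimited recording; metadata from the comment header if present."""
    meta: dict = {}
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("{"):
                meta = json.loads(body)
            elif body:
                names = body.replace(",", "\t").split("\t") if "\t" in body or "," in body else body.split()
    data = np.loadtxt(path, comments="#")  # tab/whitespace delimited
    data = np.atleast_2d(data).T
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError(f"{path}: sampling frequency not in header; pass fs=")
    return Recording(
        data=data, fs=float(fs),
        channel_names=names if len(names) == data.shape[0] else [],
        subject_id=str(meta.get("subject_id", "unknown")),
        condition=str(meta.get("condition", "unknown")),
    )


def read_recording_edf(path, subject_id: str = "unknown",
                       condition: str = "unknown") -> Recording:
    """Read an EDF file (microvolt scaling) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names), subject_id=subject_id,
        condition=condition,
    )


def read_recording(path, **kwargs) -> Recording:
    """Dispatch on extension: ``.edf`` via MNE, anything else as text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, **kwargs)
    return read_recording_text(path, **kwargs)


def read_dataset_manifest(manifest_path) -> list[Recording]:
    """Load every recording listed in a dataset manifest (JSON)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    recordings = []
    for entry in manifest["recordings"]:
        p = manifest_path.parent / entry["file"]
        rec = read_recording(p, fs=entry.get("fs")) if p.suffix != ".edf" else read_recording(p)
        rec.subject_id = entry["subject_id"]
        rec.condition = entry["condition"]
        recordings.append(rec)
    return recordings


def checksum(arr: np.ndarray) -> str:
    """Short sha256 of an array's bytes, for run manifests."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def features_to_frame(vectors, subject_ids, conditions) -> pd.DataFrame:
    """Stack per-recording FeatureVectors into a tidy labelled frame."""
    rows = [fv.values for fv in vectors]
    labels = vectors[0].labels
    df = pd.DataFrame(rows, columns=labels)
    df.insert(0, "subject_id", list(subject_ids))
    df.insert(1, "condition", list(conditions))
    return df
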