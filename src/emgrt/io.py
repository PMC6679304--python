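"""Plain-text recording and session I/O.

One delimited text file per repetition: a single comment header line

    # fs=200 subject=s01 gesture=1 rep=0 onset=45 offset=185

followed by one row per sample with one integer column per channel
(tab-separated).  ``onset``/``offset`` are omitted for pure-rest
recordings.  A session manifest is a tab-separated table listing
file, subject, gesture and repetition.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .synth import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_session",
    "read_session",
]

_HEADER_RE = re.compile(r"(\w+)=([^\s]+)")


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    fields = [f"fs={rec.fs:g}", f"subject={rec.subject_id}",
              f"gesture={rec.gesture_label}", f"rep={rec.repetition_index}"]
    if rec.true_onset is not None:
        fields += [f"onset={rec.true_onset}", f"offset={rec.true_offset}"]
    header = "# " + " ".join(fields)
    np.savetxt(path, rec.samples, fmt="%d", delimiter="\t",
               header=header.lstrip("# "), comments="# ")


def read_recording(path) -> Recording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    meta: dict[str, str] = {}
    if first.startswith("#"):
        meta = dict(_HEADER_RE.findall(first))
    samples = np.loadtxt(path, comments="#", delimiter="\t", dtype=np.int64,
                         ndmin=2)
    onset = int(meta["onset"]) if "onset" in meta else None
    offset = int(meta["offset"]) if "offset" in meta else None
    return Recording(
        samples=samples,
        fs=float(meta.get("fs", 200.0)),
        subject_id=meta.get("subject", "unknown"),
        gesture_label=int(meta.get("gesture", 0)),
        repetition_index=int(meta.get("rep", 0)),
        true_onset=onset, true_offset=offset,
    )


def write_session(recordings: Sequence[Recording], out_dir,
                  prefix: str = "rep") -> Path:
    """Write one file per recording plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["file", "subject", "gesture", "repetition"])
        for i, rec in enumerate(recordings):
            name = (f"{prefix}_g{rec.gesture_label}"
                    f"_r{rec.repetition_index}_{i:04d}.tsv")
            write_recording(rec, out_dir / name)
            writer.writerow([name, rec.subject_id, rec.gesture_label,
                             rec.repetition_index])
    return manifest


def read_session(manifest_path) -> list[Recording]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    recordings = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            recordings.append(read_recording(base / row["file"]))
    return recordings
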