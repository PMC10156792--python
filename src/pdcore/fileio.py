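"""Readers and writers for the formats the pipeline touches.

STAR particle tables use the single-particle metadata dialect: a
``data_`` block with a ``loop_`` of ``_rln``-prefixed columns.  Only the
loop form used by particle tables is supported (no multi-block or
key-value STAR features); recognized columns are mapped to the internal
schema and unrecognized ones are carried through untouched so round
trips are lossless.  Alignments are aligned FASTA (read via Biopython);
detection tables are CSV, with automatic sniffing of raw-count versus
already-binned layouts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .occupancy import MAX_DETECTIONS
from .seqdiscrim import AlignedSeqSet

__all__ = [
    "read_star",
    "write_star",
    "read_alignment",
    "write_alignment",
    "DetectionFile",
    "read_detections",
    "write_detections",
    "write_json_report",
    "write_provenance",
]

# STAR column <-> internal schema
_STAR_TO_INTERNAL = {
    "rlnAngleRot": "rot",
    "rlnAngleTilt": "tilt",
    "rlnAnglePsi": "psi",
    "rlnOriginXAngst": "origin_x",
    "rlnOriginYAngst": "origin_y",
    "pdcParticleId": "particle_id",
    "pdcCoreId": "core_id",
    "pdcSubparticleId": "subparticle_id",
    "pdcParentParticleId": "parent_particle_id",
    "pdcOperatorIndex": "operator_index",
    "pdcSiteIndex": "site_index",
}
_INTERNAL_TO_STAR = {v: k for k, v in _STAR_TO_INTERNAL.items()}
_MANDATORY_STAR = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
_NUMERIC_INTERNAL = {"rot", "tilt", "psi", "origin_x", "origin_y"}
_INT_INTERNAL = {"particle_id", "subparticle_id", "parent_particle_id", "operator_index", "site_index"}


def _parse_loop(lines: list[str], start: int) -> tuple[list[str], list[list[str]], int]:
    """Parse one loop_ block starting after the ``loop_`` line."""
    headers: list[str] = []
    i = start
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.startswith("_"):
            headers.append(stripped.split()[0].lstrip("_"))
            i += 1
        else:
            break
    if not headers:
        raise ValueError(f"malformed loop_ block at line {start}: no column headers")
    rows: list[list[str]] = []
    while i < len(lines):
        stripped = lines[i].strip()
        if not stripped or stripped.startswith(("data_", "loop_", "#")):
            break
        fields = stripped.split()
        if len(fields) != len(headers):
            raise ValueError(
                f"malformed loop_ row at line {i + 1}: {len(fields)} fields, "
                f"expected {len(headers)}"
            )
        rows.append(fields)
        i += 1
    return headers, rows, i


def read_star(path: str | Path) -> pd.DataFrame:
    """Read a STAR particle table into the internal schema.

    Recognized ``_rln``/``pdc`` columns are renamed; everything else is
    kept verbatim (string dtype).  When no explicit particle/core id
    column is present, ``rlnImageName`` supplies the core id and
    particles are numbered by row order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    headers = rows = None
    for i, line in enumerate(lines):
        if line.strip() == "loop_":
            headers, rows, _ = _parse_loop(lines, i + 1)
            break
    if headers is None:
        raise ValueError(f"{path}: no loop_ block found")
    missing = [c for c in _MANDATORY_STAR if c not in headers]
    if missing:
        raise ValueError(f"{path}: missing mandatory STAR columns: {missing}")
    df = pd.DataFrame(rows, columns=headers)
    df = df.rename(columns=_STAR_TO_INTERNAL)
    for col in df.columns:
        if col in _NUMERIC_INTERNAL:
            df[col] = df[col].astype(float)
        elif col in _INT_INTERNAL:
            df[col] = df[col].astype(int)
    if "core_id" not in df.columns:
        if "rlnImageName" in df.columns:
            df["core_id"] = df["rlnImageName"]
        else:
            df["core_id"] = np.arange(len(df))
    if "particle_id" not in df.columns:
        df["particle_id"] = np.arange(len(df))
    for col in ("origin_x", "origin_y"):
        if col not in df.columns:
            df[col] = 0.0
    return df


def write_star(table: pd.DataFrame, path: str | Path, block_name: str = "particles") -> None:
    """Write a table in STAR loop format, restoring dialect column names."""
    path = Path(path)
    out = table.rename(columns=_INTERNAL_TO_STAR)
    cols = list(out.columns)
    formatted = {}
    for col in cols:
        series = out[col]
        if pd.api.types.is_float_dtype(series):
            formatted[col] = series.map(lambda v: f"{v:.6f}")
        else:
            formatted[col] = series.astype(str)
    with path.open("w") as fh:
        fh.write(f"\ndata_{block_name}\n\nloop_\n")
        for i, col in enumerate(cols, start=1):
            fh.write(f"_{col} #{i}\n")
        for fields in zip(*(formatted[col] for col in cols)):
            fh.write(" ".join(fields) + "\n")


def read_alignment(path: str | Path, default_group: str = "unknown") -> AlignedSeqSet:
    """Read an aligned FASTA file.

    The taxon group is taken from a ``group|name`` id prefix or a
    ``group=X`` token in the description; otherwise *default_group*.
    Ragged alignments are rejected naming the first offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    length = len(records[0].seq)
    ids, groups, seqs = [], [], []
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"{path}: ragged alignment — record {rec.id!r} has length "
                f"{len(rec.seq)}, expected {length}"
            )
        group = default_group
        if "|" in rec.id:
            group = rec.id.split("|", 1)[0]
        else:
            for token in rec.description.split():
                if token.startswith("group="):
                    group = token[len("group="):]
        ids.append(rec.id)
        groups.append(group)
        seqs.append(str(rec.seq).upper())
    return AlignedSeqSet(ids=tuple(ids), groups=tuple(groups), seqs=tuple(seqs))


def write_alignment(msa: AlignedSeqSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, seq in zip(msa.ids, msa.seqs):
            fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class DetectionFile:
    """A loaded detection table plus which layout was found on disk."""

    table: pd.DataFrame   # core_id, detection_count  (raw layout only)
    layout: str           # "raw" (detection counts 0..60) | "binned" (trimer counts)


def read_detections(path: str | Path) -> DetectionFile:
    """Read a per-core counts CSV, sniffing raw versus binned layout.

    Raw files carry ``core_id, detection_count``; already-binned files
    carry ``core_id, trimer_count``.  The layout actually found is
    recorded on the returned object.  Non-integer or out-of-range counts
    are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "detection_count" in df.columns:
        layout, col = "raw", "detection_count"
    elif "trimer_count" in df.columns:
        layout, col = "binned", "trimer_count"
    else:
        raise ValueError(
            f"{path}: expected a 'detection_count' or 'trimer_count' column, "
            f"found {list(df.columns)}"
        )
    if "core_id" not in df.columns:
        raise ValueError(f"{path}: missing 'core_id' column")
    values = df[col]
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise ValueError(f"{path}: column {col!r} contains non-integer counts")
    df[col] = values.astype(int)
    upper = MAX_DETECTIONS if layout == "raw" else MAX_DETECTIONS // 3
    if (df[col] < 0).any() or (df[col] > upper).any():
        raise ValueError(
            f"{path}: column {col!r} must lie in 0..{upper} "
            f"({'detections per core' if layout == 'raw' else 'trimers per core'})"
        )
    return DetectionFile(table=df[["core_id", col]], layout=layout)


def write_detections(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_json_report(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_provenance(
    out_path: str | Path,
    command: str,
    config: dict,
    inputs: list[str | Path] = (),
) -> Path:
    """Write a machine-readable provenance record next to an output file.

    Records the full effective configuration (defaults included), the
    seed if any, package and interpreter versions, and SHA-256 digests
    of every input, so a run can be reproduced exactly from the record.
    """
    from . import __version__

    out_path = Path(out_path)
    record = {
        "command": command,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()},
        "inputs": {
            str(p): _digest(Path(p)) for p in inputs if Path(p).exists()
        },
        "versions": {
            "pdcore": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    prov_path = out_path.with_name(out_path.name + ".provenance.json")
    prov_path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return prov_path
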