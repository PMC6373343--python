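"""Stream file formats and checkpoint persistence.

JSON-lines is the canonical stream format: the first line is a header
object declaring p, r, the column roles and any simulation metadata;
every following line is one record ``{"id": ..., "y": ..., "x": [...],
"z": [...]}``.  CSV is supported for fixtures: a header row
``id,y,x0..x{p-1},z0..z{r-1}`` plus an optional ``<path>.meta.json``
sidecar carrying the same header object.

Records with non-finite fields are skipped with a warning; the iterator
exposes the skip count.  Checkpoints are versioned JSON snapshots of the
streaming state; loading a mismatched version is an error.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .model import DataPoint
from .sema import GlobalState

__all__ = [
    "StreamHeader",
    "read_stream",
    "write_stream",
    "save_checkpoint",
    "load_checkpoint",
]

_HEADER_KEY = "semastream_header"


@dataclass
class StreamHeader:
    """Schema of a stream file: dimensions, column roles, provenance."""

    p: int
    r: int
    x_columns: list = field(default_factory=list)
    z_columns: list = field(default_factory=list)
    condition: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if not self.x_columns:
            self.x_columns = [f"x{k}" for k in range(self.p)]
        if not self.z_columns:
            self.z_columns = [f"z{k}" for k in range(self.r)]
        if len(self.x_columns) != self.p or len(self.z_columns) != self.r:
            raise ValueError("column roles do not match declared p and r")

    def to_dict(self) -> dict:
        d = asdict(self)
        d[_HEADER_KEY] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StreamHeader":
        return cls(
            p=int(d["p"]),
            r=int(d["r"]),
            x_columns=list(d.get("x_columns") or []),
            z_columns=list(d.get("z_columns") or []),
            condition=d.get("condition"),
            seed=d.get("seed"),
        )


class _PointIterator:
    """Lazy record iterator that counts skipped (non-finite) records."""

    def __init__(self, gen: Iterator[DataPoint]):
        self._gen = gen
        self.skipped = 0

    def __iter__(self):
        return self

    def __next__(self) -> DataPoint:
        return next(self._gen)


def write_stream(path, header: StreamHeader, points: Iterable[DataPoint]) -> None:
    """Write a stream to ``path``; format chosen by suffix (.jsonl / .csv)."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            fh.write(json.dumps(header.to_dict()) + "\n")
            for pt in points:
                fh.write(
                    json.dumps(
                        {
                            "id": _plain(pt.individual_id),
                            "y": pt.y,
                            "x": pt.x.tolist(),
                            "z": pt.z.tolist(),
                        }
                    )
                    + "\n"
                )
    elif path.suffix == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "y"]
                + [f"x{k}" for k in range(header.p)]
                + [f"z{k}" for k in range(header.r)]
            )
            for pt in points:
                writer.writerow(
                    [_plain(pt.individual_id), pt.y]
                    + list(pt.x)
                    + list(pt.z)
                )
        with open(path.with_name(path.name + ".meta.json"), "w") as fh:
            json.dump(header.to_dict(), fh)
    else:
        raise ValueError(f"unsupported stream format {path.suffix!r}")


def _plain(value):
    if isinstance(value, np.generic):
        return value.item()
    return value


def read_stream(path):
    """Open a stream file; returns ``(StreamHeader, iterator of DataPoint)``.

    Reading is lazy (constant memory).  Malformed records raise with the
    line number; non-finite records are skipped with a warning and
    counted on the iterator's ``skipped`` attribute.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        with open(path) as fh:
            first = fh.readline()
        try:
            head = json.loads(first)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}:1: malformed header line") from exc
        if _HEADER_KEY not in head:
            raise ValueError(f"{path}:1: missing stream header object")
        header = StreamHeader.from_dict(head)
        it = _PointIterator(iter(()))
        it._gen = _iter_jsonl(path, header, it)
        return header, it
    if path.suffix == ".csv":
        meta = path.with_name(path.name + ".meta.json")
        with open(path, newline="") as fh:
            cols = next(csv.reader(fh))
        if meta.exists():
            with open(meta) as fh:
                header = StreamHeader.from_dict(json.load(fh))
        else:
            p = sum(c.startswith("x") for c in cols)
            r = sum(c.startswith("z") for c in cols)
            header = StreamHeader(p=p, r=r)
        if cols[:2] != ["id", "y"] or len(cols) != 2 + header.p + header.r:
            raise ValueError(f"{path}:1: header row does not match schema")
        it = _PointIterator(iter(()))
        it._gen = _iter_csv(path, header, it)
        return header, it
    raise ValueError(f"unsupported stream format {path.suffix!r}")


def _iter_jsonl(path, header: StreamHeader, counter=None):
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                pt = DataPoint(rec["id"], float(rec["y"]),
                               np.array(rec["x"], float),
                               np.array(rec["z"], float))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if pt.x.shape[0] != header.p or pt.z.shape[0] != header.r:
                raise ValueError(
                    f"{path}:{lineno}: record dimensions do not match header"
                )
            if not pt.is_finite():
                warnings.warn(f"{path}:{lineno}: non-finite record skipped")
                if counter is not None:
                    counter.skipped += 1
                continue
            yield pt


def _iter_csv(path, header: StreamHeader, counter=None):
    p, r = header.p, header.r
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header row
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2 + p + r:
                raise ValueError(f"{path}:{lineno}: wrong number of fields")
            try:
                pt = DataPoint(
                    _maybe_int(row[0]),
                    float(row[1]),
                    np.array(row[2 : 2 + p], float),
                    np.array(row[2 + p :], float),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if not pt.is_finite():
                warnings.warn(f"{path}:{lineno}: non-finite record skipped")
                if counter is not None:
                    counter.skipped += 1
                continue
            yield pt


def _maybe_int(token: str):
    try:
        return int(token)
    except ValueError:
        return token


def save_checkpoint(state: GlobalState, path) -> None:
    """Serialize a streaming state to versioned JSON."""
    with open(path, "w") as fh:
        json.dump(state.to_checkpoint(), fh)


def load_checkpoint(path) -> GlobalState:
    """Restore a streaming state; refuses mismatched checkpoint versions."""
    with open(path) as fh:
        snap = json.load(fh)
    return GlobalState.from_checkpoint(snap)
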