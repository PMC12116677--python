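"""Embedding tables, dataset manifests and the feature-extractor contract.

The on-disk embedding dialect is deliberately minimal: tab-separated
text, one row per image, first column the item id, remaining columns the
embedding vector, no header, floats written at full (round-trip)
precision. Manifests are CSV with header ``id,uri,label``; the label
column is optional and, when present, carries ground truth used only for
evaluation — the selection pipeline itself never reads it.
"""

from __future__ import annotations

import abc
import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "ManifestRecord",
    "DatasetManifest",
    "ExtractorAdapter",
    "read_embeddings",
    "write_embeddings",
    "read_manifest",
    "write_manifest",
    "l2_normalize",
    "write_adapter_metadata",
]


@dataclass
class EmbeddingMatrix:
    """N items × d dimensions of real-valued features with unique string ids.

    Invariants (checked on construction): N ≥ 1, d ≥ 1, all values
    finite, ids unique and aligned with rows.
    """

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array (N items × d dims)")
        n, d = self.vectors.shape
        if n < 1 or d < 1:
            raise ValueError(f"embedding matrix must have N ≥ 1 and d ≥ 1, got {n}×{d}")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite values")
        dupes = _duplicates(self.ids)
        if dupes:
            raise ValueError(f"duplicate item ids: {sorted(dupes)}")

    @property
    def n_items(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def subset(self, indices: Sequence[int]) -> "EmbeddingMatrix":
        """Row-subset preserving the given order."""
        idx = list(indices)
        return EmbeddingMatrix([self.ids[i] for i in idx], self.vectors[idx])

    def index_of(self) -> dict[str, int]:
        return {item_id: i for i, item_id in enumerate(self.ids)}


@dataclass(frozen=True)
class ManifestRecord:
    id: str
    uri: str
    label: str | None = None


@dataclass
class DatasetManifest:
    """Per-item records: id, source URI, and (optionally) a class label.

    Labels are all-or-none: either every record carries one or none does.
    """

    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("manifest must contain at least one record")
        dupes = _duplicates([r.id for r in self.records])
        if dupes:
            raise ValueError(f"duplicate manifest ids: {sorted(dupes)}")
        n_labeled = sum(r.label is not None for r in self.records)
        if n_labeled not in (0, len(self.records)):
            raise ValueError("class labels must be present for all records or none")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ManifestRecord]:
        return iter(self.records)

    @property
    def is_labeled(self) -> bool:
        return self.records[0].label is not None

    def labels_by_id(self) -> dict[str, str]:
        if not self.is_labeled:
            raise ValueError("manifest carries no class labels")
        return {r.id: r.label for r in self.records}  # type: ignore[misc]

    def class_set(self) -> list[str]:
        """Distinct class labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.label is not None and r.label not in seen:
                seen[r.label] = None
        return list(seen)


class ExtractorAdapter(abc.ABC):
    """Contract for pluggable image feature extractors.

    Implementations wrap a pre-trained backbone (e.g. a self-supervised
    vision transformer such as DINOv2) and turn a list of image URIs into
    an :class:`EmbeddingMatrix`. The core pipeline never loads images
    itself; it only consumes the embedding table an adapter produces.

    Required guarantees: output row order matches input URI order, and
    the embedding dimension is fixed across calls. ``metadata`` must
    record at least the token-pooling mode, the input resolution and a
    checkpoint identifier, because those choices silently change the
    embedding geometry and must travel with the table.
    """

    @property
    @abc.abstractmethod
    def name(self) -> str: ...

    @abc.abstractmethod
    def embed(self, uris: Sequence[str]) -> EmbeddingMatrix: ...

    @property
    @abc.abstractmethod
    def metadata(self) -> dict: ...


def write_adapter_metadata(adapter: ExtractorAdapter, path: str | Path) -> Path:
    """Serialize an adapter's provenance metadata to JSON next to its table."""
    path = Path(path)
    payload = {"name": adapter.name, **adapter.metadata}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    """Read an embedding table (TSV: id then d float columns, no header).

    Rejects ragged rows (reporting the 1-based row number), non-numeric
    or non-finite cells, and duplicate ids (reporting the offending id).
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    width: int | None = None
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: row {lineno} has no embedding values")
            item_id, cells = parts[0], parts[1:]
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}: ragged row {lineno}: expected {width} values, got {len(cells)}"
                )
            if item_id in seen:
                raise ValueError(f"{path}: duplicate id {item_id!r} at row {lineno}")
            seen.add(item_id)
            values: list[float] = []
            for col, cell in enumerate(cells, start=2):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, column {col}"
                    ) from None
                if not math.isfinite(v):
                    raise ValueError(
                        f"{path}: non-finite value {cell!r} at row {lineno}, column {col}"
                    )
                values.append(v)
            ids.append(item_id)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty embedding file")
    return EmbeddingMatrix(ids, np.array(rows, dtype=np.float64))


def write_embeddings(embeddings: EmbeddingMatrix, path: str | Path) -> Path:
    """Write an embedding table in the TSV dialect; round-trips exactly.

    Floats are written with :func:`repr`, which is the shortest decimal
    string that parses back to the identical IEEE-754 double.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for item_id, row in zip(embeddings.ids, embeddings.vectors):
            if "\t" in item_id or "\n" in item_id:
                raise ValueError(f"id {item_id!r} contains a tab or newline")
            fh.write(item_id + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest (CSV, header ``id,uri[,label]``)."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "uri" not in reader.fieldnames:
            raise ValueError(f"{path}: manifest header must contain 'id' and 'uri'")
        has_label = "label" in reader.fieldnames
        records = [
            ManifestRecord(
                id=row["id"],
                uri=row["uri"],
                label=(row["label"] if has_label and row["label"] != "" else None),
            )
            for row in reader
        ]
    return DatasetManifest(records)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        if manifest.is_labeled:
            writer.writerow(["id", "uri", "label"])
            for r in manifest:
                writer.writerow([r.id, r.uri, r.label])
        else:
            writer.writerow(["id", "uri"])
            for r in manifest:
                writer.writerow([r.id, r.uri])
    return path


def l2_normalize(embeddings: EmbeddingMatrix) -> EmbeddingMatrix:
    """Scale every row to unit Euclidean norm.

    Offered as an optional preprocessing step; the pipeline default is to
    cluster raw embeddings. Zero rows cannot be normalized and are
    reported by id.
    """
    norms = np.linalg.norm(embeddings.vectors, axis=1)
    zero = norms == 0.0
    if np.any(zero):
        bad = [embeddings.ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"cannot normalize all-zero rows for ids: {bad}")
    return EmbeddingMatrix(list(embeddings.ids), embeddings.vectors / norms[:, None])
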