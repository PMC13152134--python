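"""Dataset manifests, image I/O, and split construction.

A :class:`Manifest` is the ledger binding image files to binary labels
(0 = normal, 1 = abnormal), optional subtype/patient metadata, and a
train / internal-validation split tag. Every audit in this package
consumes manifests plus 8-bit RGB rasters (``numpy`` arrays of shape
``(H, W, 3)``, dtype ``uint8``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageRecord",
    "Manifest",
    "ManifestSchemaError",
    "ManifestIntegrityError",
    "StratificationError",
    "read_manifest",
    "write_manifest",
    "stratified_split",
    "load_image",
    "save_image",
    "as_raster",
]

REQUIRED_COLUMNS = ("image_id", "path", "label")
CANONICAL_COLUMNS = (
    "image_id",
    "path",
    "label",
    "subtype",
    "patient_id",
    "split",
    "dataset_id",
)
SPLITS = ("train", "internal_val", "unassigned")


class ManifestSchemaError(ValueError):
    """A manifest file is missing a required column."""


class ManifestIntegrityError(ValueError):
    """A manifest violates an integrity invariant (e.g. duplicate ids)."""


class StratificationError(ValueError):
    """A split cannot be stratified (a class is empty or too small)."""


@dataclass(frozen=True)
class ImageRecord:
    """One image-level row: the unit of every audit table."""

    image_id: str
    path: str
    label: int
    subtype: str | None = None
    patient_id: str | None = None
    split: str = "unassigned"
    dataset_id: str = ""
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ManifestIntegrityError(
                f"label must be 0 (normal) or 1 (abnormal), got {self.label!r} "
                f"for image_id={self.image_id!r}"
            )
        if self.split not in SPLITS:
            raise ManifestIntegrityError(
                f"split must be one of {SPLITS}, got {self.split!r}"
            )


@dataclass(frozen=True)
class Manifest:
    records: tuple[ImageRecord, ...]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: dict[str, int] = {}
        dupes = []
        for r in self.records:
            if r.image_id in seen:
                dupes.append(r.image_id)
            seen[r.image_id] = 1
        if dupes:
            raise ManifestIntegrityError(
                "duplicate image_id(s): " + ", ".join(sorted(set(dupes)))
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, split: str) -> tuple[ImageRecord, ...]:
        return tuple(r for r in self.records if r.split == split)

    def by_id(self, image_id: str) -> ImageRecord:
        for r in self.records:
            if r.image_id == image_id:
                return r
        raise KeyError(image_id)


_LABEL_MAP = {"normal": 0, "abnormal": 1, "0": 0, "1": 1}


def _parse_label(raw: str, image_id: str) -> int:
    key = str(raw).strip().lower()
    if key not in _LABEL_MAP:
        raise ManifestIntegrityError(
            f"unparseable label {raw!r} for image_id={image_id!r}; "
            "expected normal/abnormal or 0/1"
        )
    return _LABEL_MAP[key]


def read_manifest(path: str | Path) -> Manifest:
    """Read a manifest CSV.

    Requires at least ``image_id,path,label`` columns; ``normal``/``abnormal``
    label strings are mapped to 0/1. Unknown columns are preserved verbatim in
    ``ImageRecord.extra``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(
            f"manifest {path} is missing required column(s): {', '.join(missing)}"
        )
    extra_cols = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        image_id = d["image_id"]
        records.append(
            ImageRecord(
                image_id=image_id,
                path=d["path"],
                label=_parse_label(d["label"], image_id),
                subtype=d.get("subtype") or None,
                patient_id=d.get("patient_id") or None,
                split=d.get("split") or "unassigned",
                dataset_id=d.get("dataset_id", ""),
                extra={c: d[c] for c in extra_cols},
            )
        )
    dataset_ids = {r.dataset_id for r in records if r.dataset_id}
    dataset_id = dataset_ids.pop() if len(dataset_ids) == 1 else ""
    return Manifest(records=tuple(records), dataset_id=dataset_id)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest CSV in canonical column order; round-trips losslessly."""
    extra_cols: list[str] = []
    for r in manifest.records:
        for c in r.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for r in manifest.records:
        row = {
            "image_id": r.image_id,
            "path": r.path,
            "label": r.label,
            "subtype": r.subtype or "",
            "patient_id": r.patient_id or "",
            "split": r.split,
            "dataset_id": r.dataset_id,
        }
        for c in extra_cols:
            row[c] = r.extra.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + extra_cols)
    df.to_csv(path, index=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    manifest: Manifest,
    val_fraction: float,
    seed: int,
    by_patient: bool = False,
) -> Manifest:
    """Assign train / internal_val splits by stratified random sampling.

    Per class, ``max(1, round(val_fraction * class_size))`` records become
    ``internal_val`` and the rest ``train``. Shuffling precedes sampling and
    the assignment is a pure function of (record order, val_fraction, seed).

    With ``by_patient=True``, whole patient groups are assigned together
    (shuffled patients move to validation until every class quota is met, so
    per-class fractions are approximate) — the partitioning recommended for
    leakage-free evaluation; the default mirrors the common image-level
    protocol.
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    labels = manifest.labels
    for cls in (0, 1):
        if not np.any(labels == cls):
            raise StratificationError(f"class {cls} has no records; cannot stratify")
    rng = np.random.default_rng(seed)
    assignment = np.full(len(manifest), "train", dtype=object)
    if by_patient:
        groups: dict[str, list[int]] = {}
        for i, record in enumerate(manifest.records):
            key = record.patient_id or record.image_id
            groups.setdefault(key, []).append(i)
        keys = list(groups)
        rng.shuffle(keys)
        quota = {
            cls: max(1, _round_half_up(val_fraction * int((labels == cls).sum())))
            for cls in (0, 1)
        }
        taken = {0: 0, 1: 0}
        for key in keys:
            if taken[0] >= quota[0] and taken[1] >= quota[1]:
                break
            # whole patients move together, so per-class counts are
            # approximate: a patient fills the quota of every class it has
            # images in
            for i in groups[key]:
                assignment[i] = "internal_val"
                taken[labels[i]] += 1
    else:
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            perm = idx.copy()
            rng.shuffle(perm)
            n_val = max(1, _round_half_up(val_fraction * len(idx)))
            assignment[perm[:n_val]] = "internal_val"
    records = tuple(
        replace(r, split=str(assignment[i])) for i, r in enumerate(manifest.records)
    )
    return Manifest(records=records, dataset_id=manifest.dataset_id)


def as_raster(image: np.ndarray) -> np.ndarray:
    """Validate an 8-bit RGB raster and return it as a C-contiguous array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError("images must be at least 8x8 pixels")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected dtype uint8, got {arr.dtype}")
    return np.ascontiguousarray(arr)


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an 8-bit RGB raster.

    Grayscale sources are replicated to three channels; alpha is dropped.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return as_raster(arr)


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(as_raster(image), mode="RGB").save(path)


def load_images(records: Iterable[ImageRecord]) -> list[np.ndarray]:
    """Load the rasters for a sequence of records, erroring with the record id."""
    out = []
    for r in records:
        try:
            out.append(load_image(r.path))
        except OSError as exc:
            raise OSError(f"record {r.image_id!r}: {exc}") from exc
    return out
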