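"""Dataset index types and file IO: PNG rasters and CSV manifests.

Masks are stored as 8-bit PNGs with values {0, 255} (255 = LAA foreground);
images as 8-bit grayscale PNGs of intensities scaled from [0, 1].  The
manifest is a CSV with header ``image_path,mask_path,patient_id,thrombus,split``
whose paths are relative to the manifest's directory.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

MANIFEST_HEADER = ["image_path", "mask_path", "patient_id", "thrombus", "split"]
SPLITS = ("train", "val", "test", "unassigned")


@dataclass(frozen=True)
class SampleRecord:
    """One image/mask pair with patient identity and thrombus status."""

    image_path: str
    mask_path: str
    patient_id: str
    thrombus: bool
    split: str = "unassigned"

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


@dataclass
class DatasetManifest:
    """Ordered dataset index; ``root`` resolves the records' relative paths."""

    records: list[SampleRecord]
    image_size: tuple[int, int]
    seed: int
    root: Path = field(default_factory=Path)

    def __post_init__(self):
        self.root = Path(self.root)
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image_path entries in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def subset(self, split: str) -> list[SampleRecord]:
        return [r for r in self.records if r.split == split]

    def with_splits(self, assignment: dict[str, str]) -> "DatasetManifest":
        """New manifest with each record's split set by its patient's label."""
        recs = [replace(r, split=assignment[r.patient_id]) for r in self.records]
        return DatasetManifest(recs, self.image_size, self.seed, self.root)

    def resolve(self, rel_path: str) -> Path:
        return self.root / rel_path


# ---------------------------------------------------------------------------
# PNG IO


def save_image_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG."""
    arr = np.asarray(image, dtype=float)
    if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
        raise ValueError("image values must lie in [0, 1]")
    byte = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(byte, mode="L").save(path)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit PNG with values {0, 255}."""
    arr = np.asarray(mask)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    Image.fromarray((arr.astype(np.uint8) * 255), mode="L").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float image in [0, 1]."""
    with Image.open(path) as im:
        if im.mode != "L":
            raise ValueError(f"{path}: expected 8-bit grayscale PNG, got mode {im.mode!r}")
        arr = np.asarray(im, dtype=np.float64)
    return arr / 255.0


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a {0, 255} PNG as a {0, 1} integer mask; other values are errors."""
    with Image.open(path) as im:
        if im.mode != "L":
            raise ValueError(f"{path}: expected 8-bit grayscale PNG, got mode {im.mode!r}")
        arr = np.asarray(im)
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(f"{path}: illegal mask values {bad[:10].tolist()} (expected only 0/255)")
    return (arr == 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Manifest IO


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write the manifest CSV; record paths stay relative to the manifest
    file, so saving into a different directory rebases them against the
    manifest's data root."""
    path = Path(path)
    rel = os.path.relpath(manifest.root, path.parent)
    prefix = "" if rel == "." else rel + "/"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for r in manifest.records:
            writer.writerow([prefix + r.image_path, prefix + r.mask_path,
                             r.patient_id, str(bool(r.thrombus)), r.split])


_BOOLS = {"true": True, "false": False, "1": True, "0": False}


def load_manifest(path: str | Path, check_files: bool = False,
                  image_size: tuple[int, int] | None = None,
                  seed: int = 0) -> DatasetManifest:
    """Load and validate a manifest CSV; malformed rows are reported with
    their line numbers."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise ValueError(f"{path}: empty manifest file")
    if rows[0] != MANIFEST_HEADER:
        raise ValueError(f"{path}: bad header {rows[0]!r}, expected {MANIFEST_HEADER!r}")
    records: list[SampleRecord] = []
    errors: list[str] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != 5:
            errors.append(f"line {lineno}: expected 5 fields, got {len(row)}")
            continue
        img, msk, pid, thr, split = row
        if thr.strip().lower() not in _BOOLS:
            errors.append(f"line {lineno}: bad thrombus flag {thr!r}")
            continue
        if split not in SPLITS:
            errors.append(f"line {lineno}: bad split {split!r}")
            continue
        try:
            records.append(SampleRecord(img, msk, pid, _BOOLS[thr.strip().lower()], split))
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError(f"{path}: malformed manifest rows:\n  " + "\n  ".join(errors))
    if not records:
        raise ValueError(f"{path}: manifest contains no records")
    root = path.parent
    if check_files:
        for r in records:
            for rel in (r.image_path, r.mask_path):
                if not (root / rel).exists():
                    raise FileNotFoundError(f"{path}: referenced file missing: {rel}")
    if image_size is None:
        first = read_image_png(root / records[0].image_path)
        image_size = first.shape
    return DatasetManifest(records, tuple(image_size), seed, root)
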