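"""Dataset loading and report serialization."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["DatasetRecord", "LoadedDataset", "load_dataset", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class DatasetRecord:
    path: Path
    class_label: str
    severity: str | None = None
    counts: dict = field(default_factory=dict)
    seed: int | None = None
    _image: np.ndarray | None = field(default=None, repr=False)

    def image(self) -> np.ndarray:
        """Decode lazily; cached after the first read."""
        if self._image is None:
            self._image = np.asarray(iio.imread(self.path))
        return self._image


@dataclass
class LoadedDataset:
    records: list[DatasetRecord]
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list[str]:
        return [r.class_label for r in self.records]


def load_dataset(root: str | Path, manifest: str | Path | None = None) -> LoadedDataset:
    """Load a dataset from a CSV manifest or a folder-per-class layout.

    Manifest columns: filename, class_label and optionally severity,
    ma_count, he_count, ex_count, seed (the schema written by the
    synthetic generator).  Unreadable images are skipped with a warning
    and counted, never fatal; a missing manifest is an error.
    """
    root = Path(root)
    records: list[DatasetRecord] = []
    skipped = 0
    if manifest is not None or (root / "manifest.csv").exists():
        mpath = Path(manifest) if manifest is not None else root / "manifest.csv"
        if not mpath.exists():
            raise FileNotFoundError(f"manifest not found: {mpath}")
        table = pd.read_csv(mpath)
        for _, row in table.iterrows():
            path = root / str(row["filename"])
            rec = DatasetRecord(
                path=path,
                class_label=str(row["class_label"]),
                severity=None if str(row.get("severity", "none")) == "none" else str(row["severity"]),
                counts={
                    k: int(row[k]) for k in ("ma_count", "he_count", "ex_count") if k in row
                },
                seed=int(row["seed"]) if "seed" in row else None,
            )
            try:
                rec.image()
            except (FileNotFoundError, OSError, ValueError) as exc:
                logger.warning("skipping unreadable image %s: %s", path, exc)
                skipped += 1
                continue
            records.append(rec)
    else:
        # folder-per-class layout: <root>/<class>/<image>
        for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            for img_path in sorted(cls_dir.glob("*")):
                if img_path.suffix.lower() not in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}:
                    continue
                rec = DatasetRecord(path=img_path, class_label=cls_dir.name)
                try:
                    rec.image()
                except (OSError, ValueError) as exc:
                    logger.warning("skipping unreadable image %s: %s", img_path, exc)
                    skipped += 1
                    continue
                records.append(rec)
        if not records and not any(root.iterdir()):
            raise FileNotFoundError(f"no manifest.csv and no class folders under {root}")
    return LoadedDataset(records=records, skipped=skipped)


def write_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
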