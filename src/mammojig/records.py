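"""Per-image metadata records and the manifest container.

A manifest is the study's unit of bookkeeping: one row per mammographic
image, carrying the patient identifier (the grouping key for all
cross-validation splits), the binary cancer label, the radiological
finding, the breast-density category and file references for the image
and, for lesion images, its ground-truth mask.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

#: Radiological finding categories.
FINDINGS = ("mass", "calcification", "distortion", "normal")

#: Breast-density categories: dense breast / not-dense breast.
DENSITIES = ("DB", "Not-DB")

#: Image-level exclusion flags applied before analysis. ``none`` means the
#: image is kept; the remaining seven mirror radiological exclusion causes.
EXCLUSION_FLAGS = (
    "none",
    "phyllodes",
    "neurofibromatosis",
    "lymphedema",
    "venous_port",
    "foreign_body",
    "artifact",
    "lesion_unidentifiable",
)

#: Exact manifest CSV column order.
MANIFEST_COLUMNS = (
    "patient_id",
    "image_id",
    "view",
    "cancer",
    "finding",
    "density",
    "image_path",
    "mask_path",
    "exclusion_flag",
)


@dataclass(frozen=True)
class ImageRecord:
    """Metadata for a single mammographic image."""

    patient_id: str
    image_id: str
    view: str = "MLO"
    cancer: int = 0
    finding: str = "normal"
    density: str = "Not-DB"
    image_path: str = ""
    mask_path: str = ""
    exclusion_flag: str = "none"

    def __post_init__(self) -> None:
        if self.finding not in FINDINGS:
            raise ValueError(f"unknown finding {self.finding!r}")
        if self.density not in DENSITIES:
            raise ValueError(f"unknown density {self.density!r}")
        if self.exclusion_flag not in EXCLUSION_FLAGS:
            raise ValueError(f"unknown exclusion flag {self.exclusion_flag!r}")
        if self.cancer not in (0, 1):
            raise ValueError("cancer label must be 0 or 1")
        if self.finding == "normal":
            if self.cancer != 0:
                raise ValueError("normal finding implies cancer = 0")
            if self.mask_path:
                raise ValueError("normal finding implies empty mask_path")
        if not self.patient_id:
            raise ValueError("record must carry a patient_id")


@dataclass
class Manifest:
    """Ordered collection of :class:`ImageRecord` with a provenance note."""

    records: list[ImageRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("image_id values must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        return df.reindex(columns=list(MANIFEST_COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: Iterable[ImageRecord], provenance: str = "") -> "Manifest":
        return cls(records=list(records), provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        records = [
            ImageRecord(
                patient_id=row.patient_id,
                image_id=row.image_id,
                view=row.view,
                cancer=int(row.cancer),
                finding=row.finding,
                density=row.density,
                image_path=row.image_path,
                mask_path=row.mask_path,
                exclusion_flag=row.exclusion_flag,
            )
            for row in df.itertuples()
        ]
        return cls(records=records, provenance=str(path))
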