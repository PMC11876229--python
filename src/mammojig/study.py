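"""Convenience assembly of an in-memory synthetic study dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocessing import apply_exclusions
from .records import Manifest
from .synthetic import SyntheticConfig, generate_record, total_images
from .training import StudyData

__all__ = ["make_study_data"]


def make_study_data(patients: int = 60, seed: int = 0,
                    config: SyntheticConfig | None = None,
                    exclusions: bool = True) -> StudyData:
    """Generate phantom crops in memory and package them for the arm
    runner: images keyed by image id plus the metadata table. With
    ``exclusions=True`` flagged records are dropped first, mirroring the
    study's curation step."""
    cfg = config or SyntheticConfig(n_patients=patients, seed=seed)
    n = total_images(cfg)
    images: dict[str, np.ndarray] = {}
    records = []
    for i in range(n):
        img, _, rec = generate_record(cfg, i)
        images[rec.image_id] = img
        records.append(rec)
    manifest = Manifest.from_records(records, provenance="synthetic in-memory")
    if exclusions:
        manifest, _ = apply_exclusions(manifest)
        images = {r.image_id: images[r.image_id] for r in manifest}
    table = pd.DataFrame([
        {"image_id": r.image_id, "patient_id": r.patient_id, "cancer": r.cancer,
         "finding": r.finding, "density": r.density}
        for r in manifest
    ])
    return StudyData(images=images, table=table)
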