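"""Serialization helpers: NPZ archives, TSV tables, optional GIFTI export."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import CohortRecord, PriorTemplate, SurfaceModel

__all__ = [
    "save_template",
    "load_template",
    "cohort_table",
    "save_cohort_table",
    "export_map_gifti",
]


def save_template(path: str | Path, template: PriorTemplate) -> None:
    np.savez_compressed(
        path,
        mu0=template.mu0,
        sigma0_sq=template.sigma0_sq,
        sigma_tot_sq=template.sigma_tot_sq,
        sigma_noise_sq=template.sigma_noise_sq,
        n_subjects_used=template.n_subjects_used,
        ic_labels=np.array(template.ic_labels),
    )


def load_template(path: str | Path) -> PriorTemplate:
    with np.load(path, allow_pickle=False) as z:
        return PriorTemplate(
            mu0=z["mu0"],
            sigma0_sq=z["sigma0_sq"],
            sigma_tot_sq=z["sigma_tot_sq"],
            sigma_noise_sq=z["sigma_noise_sq"],
            n_subjects_used=int(z["n_subjects_used"]),
            ic_labels=[str(x) for x in z["ic_labels"]],
        )


def cohort_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Cohort covariates and strengths as a tidy table (one row/subject)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age_pma_weeks": r.age_pma_weeks,
            "sex": r.sex,
            "motion": r.motion,
        }
        row.update(
            {f"strength_IC{q + 1}": s for q, s in enumerate(r.strength)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort_table(path: str | Path, records: list[CohortRecord]) -> None:
    cohort_table(records).to_csv(path, sep="\t", index=False)


def export_map_gifti(path: str | Path, mesh: SurfaceModel, values: np.ndarray) -> None:
    """Write a per-vertex map as a GIFTI functional file (needs nibabel)."""
    import nibabel as nib

    darr = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[darr]), str(path))
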