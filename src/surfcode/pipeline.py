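"""End-to-end glue: cohort grids -> MMS -> patches -> sparse codes ->
pooled subject representations -> cross-validated classification."""

from __future__ import annotations

import numpy as np

from .aggregate_classify import (
    CvResult,
    SubjectRepresentation,
    build_representations,
    cross_validate,
    pool_subjects,
)
from .io_formats import RunLogger
from .morphometry import PatchSpec, compute_mms, concat_patch_sets, sample_subject_patches
from .pascs_core import PascsHyper, PascsModel, encode, fit
from .synthetic import Cohort


def cohort_patches(cohort: Cohort, patch_size: int, count_per_hemisphere: int,
                   seed: int = 0):
    """MMS + patch extraction for every subject; one pooled PatchSet."""
    sets = []
    for i, (sid, per_hemi) in enumerate(sorted(cohort.grids.items())):
        fields = {
            hemi: compute_mms(cohort.template[hemi], grid)
            for hemi, grid in per_hemi.items()
        }
        spec = PatchSpec(size=patch_size, count_per_hemisphere=count_per_hemisphere,
                         seed=seed + i)
        sets.append(sample_subject_patches(fields, spec))
    return concat_patch_sets(sets)


def run_pipeline_cv(cohort: Cohort, params: dict, seed: int = 0, folds: int = 10,
                    repeats: int = 5, logger: RunLogger | None = None) -> CvResult:
    """Full pipeline on one cohort, ending in repeated k-fold CV.

    `params` keys (all optional): patch_size, count_per_hemisphere, m, lam,
    sigma, epochs, encode_passes, pool_mode.
    """
    patch_size = int(params.get("patch_size", 10))
    count = int(params.get("count_per_hemisphere", 20))
    patches = cohort_patches(cohort, patch_size, count, seed=seed)
    hyper = PascsHyper(
        m=int(params.get("m", 100)),
        lam=float(params.get("lam", 0.22)),
        sigma=float(params.get("sigma", 3.6)),
        epochs=int(params.get("epochs", 5)),
        seed=seed,
    )
    model = fit(patches, hyper, logger=logger)
    Z = encode(patches, model, passes=int(params.get("encode_passes", 10)))
    pooled = pool_subjects(Z, patches.subject_ids, mode=params.get("pool_mode", "max"))
    reps = build_representations(pooled, cohort.metadata)
    return cross_validate(reps, folds=folds, repeats=repeats, seed=seed, logger=logger)


def representations_for(cohort: Cohort, model: PascsModel, patch_size: int,
                        count_per_hemisphere: int, seed: int = 0,
                        encode_passes: int = 10,
                        pool_mode: str = "max") -> list[SubjectRepresentation]:
    """Encode + pool a cohort under an already-fitted model."""
    patches = cohort_patches(cohort, patch_size, count_per_hemisphere, seed=seed)
    Z = encode(patches, model, passes=encode_passes)
    pooled = pool_subjects(Z, patches.subject_ids, mode=pool_mode)
    return build_representations(pooled, cohort.metadata)
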