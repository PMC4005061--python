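"""Shared setup for the numbered analysis drivers."""

import os

from alffpipe import CohortSpec, EffectSpec, GmSpec, VoxelGrid, box_roi

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, "..", "results")
SCRATCH = os.path.join(HERE, "..", "scratch")
os.makedirs(RESULTS, exist_ok=True)
os.makedirs(SCRATCH, exist_ok=True)

STUDY_GRID = VoxelGrid.isotropic((24, 24, 16), 3.0)

#: the planted functional effect: 30 voxels, amplitude ratio 1.5 (A stronger)
EFFECT_ROI = box_roi(STUDY_GRID, (12, 12, 8), (5, 3, 2))

#: a separate region with 15% gray-matter loss in group A
ATROPHY_ROI = box_roi(STUDY_GRID, (6, 16, 10), (4, 4, 3))


def study_cohort_spec(seed: int = 1, amplitude_ratio: float = 1.5) -> CohortSpec:
    """The cohort every driver analyzes: 20 vs 18 subjects, planted effects."""
    return CohortSpec(
        seed=seed,
        effects=(EffectSpec(roi=EFFECT_ROI, amplitude_ratio=amplitude_ratio),),
        gm_confound=GmSpec(baseline=0.6, atrophy_roi=ATROPHY_ROI,
                           group_a_deficit=0.15, subject_sd=0.05),
    )
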