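"""Seeded simulation studies: calibration, power, and recovery.

These drive the package's own validation: type-I error of the permutation
machinery on null cohorts, detection of the designed meditation-state
effect, and recovery of the generator's cross-network anticorrelation
through the full denoise -> seed-FC chain.  Problem sizes are arguments so
callers choose the scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import fc_map, seed_timecourse
from .falff import (
    FrequencyBand,
    add_zscores,
    compute_falff,
    extract_roi_mean,
    falff_series,
)
from .inference import PermutationConfig, permutation_test
from .pda import pda_table
from .preprocess import (
    OutlierConfig,
    build_confounds,
    denoise,
    detect_outliers,
    erode_mask,
    global_signal,
)
from .synth import Acquisition, CohortDesign, generate_node_timecourses, generate_run


def null_design(n_em: int = 16, n_volumes: int | None = None) -> CohortDesign:
    """Design with every effect multiplier at 1 (no group or condition
    effect); used for calibration studies."""
    mult = {
        "HC": {"rsBase": {"DMN": 1.0, "CEN": 1.0}},
        "EM": {c: {"DMN": 1.0, "CEN": 1.0} for c in ("rsBase", "Med", "rsPost")},
    }
    design = CohortDesign(n_em=n_em, multipliers=mult)
    if n_volumes is not None:
        design.conditions = {
            "rsBase": Acquisition(2.0, n_volumes),
            "Med": Acquisition(1.5, n_volumes),
            "rsPost": Acquisition(2.0, n_volumes),
        }
    return design


def state_design(
    n_em: int = 16, n_volumes: int = 200, med_cen_multiplier: float = 1.5
) -> CohortDesign:
    """Design with a pure meditation-state effect: the CEN in-band
    amplitude is multiplied during Med, nothing else differs."""
    design = null_design(n_em=n_em, n_volumes=n_volumes)
    design.multipliers["EM"]["Med"]["CEN"] = med_cen_multiplier
    return design


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def scalar_pda_sessions(
    design: CohortDesign,
    seed,
    group: str = "EM",
    conditions=("rsBase", "Med"),
) -> pd.DataFrame:
    """Per-session scalar PDA computed from node time courses alone.

    The fast route for calibration studies: fALFF of each gray node's
    generated series stands in for the ROI-mean fALFF of its sphere (the
    sphere carries exactly that series plus exchangeable voxel noise).
    """
    ss = _as_seedseq(seed)
    gray = design.gray_nodes()
    dmn = [n.name for n in gray if n.network == "DMN"]
    cen = [n.name for n in gray if n.network == "CEN"]
    subjects = [f"{group}{i + 1:02d}" for i in range(design.n_em)]
    children = iter(ss.spawn(len(subjects) * len(conditions)))
    rows = []
    for subject in subjects:
        for cond in conditions:
            tc, nodes = generate_node_timecourses(
                design, cond, next(children), group
            )
            acq = design.conditions[cond]
            for j, node in enumerate(nodes):
                if node.network in ("DMN", "CEN"):
                    rows.append(
                        {
                            "subject": subject,
                            "condition": cond,
                            "roi": node.name,
                            "mean_falff": float(
                                falff_series(tc[:, j], acq.tr_seconds, design.band)
                            ),
                        }
                    )
    table = add_zscores(pd.DataFrame(rows))
    return pda_table(table, dmn, cen)


def null_calibration(
    n_cohorts: int = 1000,
    seed: int = 0,
    n_subjects: int = 16,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the paired permutation test on scalar PDA
    over null cohorts.

    Calibrated on the TR-matched paired contrast (rsBase vs rsPost, both
    2 s / 151 volumes): with mixed repetition times the broadband noise
    share shifts mean fALFF between conditions, and pooled z-scoring then
    couples paired differences across subjects, which makes the paired
    test conservative rather than miscalibrated (see the methods note).
    """
    design = null_design(n_em=n_subjects)
    ss = _as_seedseq(seed)
    rejections = 0
    for child in ss.spawn(n_cohorts):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pda = scalar_pda_sessions(design, child, conditions=("rsBase", "rsPost"))
        base = pda[pda.condition == "rsBase"].sort_values("subject")["pda"].values
        med = pda[pda.condition == "rsPost"].sort_values("subject")["pda"].values
        res = permutation_test(
            base,
            med,
            paired=True,
            config=PermutationConfig(n_permutations=n_permutations, seed=sub_seed),
            alternative="greater",
        )
        rejections += res.p < alpha
    return rejections / n_cohorts


def _cohort_pda_from_volumes(design, seed, conditions):
    """fALFF -> ROI mean -> z -> PDA for every EM session of a design,
    generating full 4D runs (no smoothing: ROI means are unaffected by it
    in this isotropic-node design)."""
    ss = _as_seedseq(seed)
    masks = design.network_masks()
    subjects = [f"EM{i + 1:02d}" for i in range(design.n_em)]
    children = iter(ss.spawn(len(subjects) * len(conditions)))
    rows = []
    for subject in subjects:
        for cond in conditions:
            art = generate_run(design, subject, "EM", cond, next(children))
            fmap = compute_falff(art.run, design.band)
            for net in ("DMN", "CEN"):
                rows.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "roi": net,
                        "mean_falff": extract_roi_mean(fmap, masks[net]),
                    }
                )
    table = add_zscores(pd.DataFrame(rows))
    return pda_table(table, ["DMN"], ["CEN"])


def state_recovery(
    n_cohorts: int = 50,
    seed: int = 0,
    med_cen_multiplier: float = 1.5,
    n_volumes: int = 200,
    n_subjects: int = 16,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> float:
    """Fraction of cohorts in which the pipeline detects PDA(Med) >
    PDA(rsBase) at p < alpha.  With multiplier 1 this estimates the null
    rejection rate."""
    design = state_design(
        n_em=n_subjects, n_volumes=n_volumes, med_cen_multiplier=med_cen_multiplier
    )
    ss = _as_seedseq(seed)
    hits = 0
    for child in ss.spawn(n_cohorts):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pda = _cohort_pda_from_volumes(design, child, ("rsBase", "Med"))
        base = pda[pda.condition == "rsBase"].sort_values("subject")["pda"].values
        med = pda[pda.condition == "Med"].sort_values("subject")["pda"].values
        res = permutation_test(
            base,
            med,
            paired=True,
            config=PermutationConfig(n_permutations=n_permutations, seed=sub_seed),
            alternative="greater",
        )
        hits += res.p < alpha
    return hits / n_cohorts


def denoise_run(art, design, band: FrequencyBand | None = None, n_compcor: int = 5):
    """Standard denoising chain for one generated run: outliers from motion
    and global intensity, aCompCor from eroded WM/CSF, confound regression
    with simultaneous band-pass."""
    if band is None:
        band = design.band
    masks = design.network_masks()
    flags = detect_outliers(
        art.motion.values, global_signal(art.run), OutlierConfig()
    )
    wm = erode_mask(masks["WM"])
    csf = erode_mask(masks["CSF"])
    confounds = build_confounds(
        art.run, wm, csf, art.motion.values, flags, n_compcor
    )
    return denoise(art.run, confounds, band)


def anticorrelation_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    target_r: float = -0.6,
    n_volumes: int = 800,
) -> list[float]:
    """Mean cross-network Fisher z (CEN seed -> DMN voxels) for runs whose
    generator truth sets r(DMN, CEN) = target_r; returns one value per
    simulated run."""
    design = null_design(n_em=1, n_volumes=n_volumes)
    design.cross_network_r = {c: target_r for c in design.cross_network_r}
    masks = design.network_masks()
    ss = _as_seedseq(seed)
    out = []
    for child in ss.spawn(n_seeds):
        art = generate_run(design, "EM01", "EM", "rsBase", child)
        clean = denoise_run(art, design)
        tc = seed_timecourse(clean, masks["CEN"])
        cmap = fc_map(clean, tc, seed_label="CEN")
        out.append(float(np.nanmean(cmap.values[masks["DMN"].voxels])))
    return out
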