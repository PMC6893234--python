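"""Positive diametric activity (PDA) and the trait/state contrast assembly.

PDA summarizes the diametric relation between the two anticorrelated
networks in a single per-session scalar:

    PDA = mean CEN fALFF - mean DMN fALFF

computed on z-scored ROI extraction values.  PDA is positive whenever mean
CEN activity exceeds mean DMN activity; the formula itself does not force
positivity, so negative values are representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import CohortTable


def compute_pda(cen_mean: float, dmn_mean: float) -> float:
    """PDA = mean CEN activity minus mean DMN activity."""
    if not (np.isfinite(cen_mean) and np.isfinite(dmn_mean)):
        raise ValidationError("PDA inputs must be finite")
    return float(cen_mean - dmn_mean)


def pda_table(
    roi_z_table: pd.DataFrame,
    dmn_rois: list[str],
    cen_rois: list[str],
    weight_by_voxels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One PdaScore row per session from a long ROI z-score table.

    Network means weight ROIs equally by default; pass per-ROI voxel counts
    in ``weight_by_voxels`` to weight by size instead.  Every session must
    carry a z value for every ROI of both networks.
    """
    required = list(dmn_rois) + list(cen_rois)
    missing_sessions = []
    rows = []
    for (subject, condition), sub in roi_z_table.groupby(
        ["subject", "condition"], sort=True
    ):
        z = dict(zip(sub["roi"], sub["z"]))
        if any(r not in z for r in required):
            missing_sessions.append((subject, condition))
            continue

        def net_mean(names):
            vals = np.array([z[r] for r in names], dtype=float)
            if weight_by_voxels is not None:
                w = np.array([weight_by_voxels[r] for r in names], dtype=float)
                return float(np.average(vals, weights=w))
            return float(vals.mean())

        cen = net_mean(cen_rois)
        dmn = net_mean(dmn_rois)
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "cen_mean": cen,
                "dmn_mean": dmn,
                "pda": compute_pda(cen, dmn),
            }
        )
    if missing_sessions:
        raise ValidationError(
            f"sessions missing ROI values: {missing_sessions}"
        )
    return pd.DataFrame(rows).sort_values(["subject", "condition"]).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class ContrastSpec:
    """A left-vs-right (group, condition) comparison; effect = right - left."""

    name: str
    left: tuple[str, str]
    right: tuple[str, str]
    paired: bool


TRAIT = ContrastSpec("trait", ("HC", "rsBase"), ("EM", "rsBase"), paired=False)
STATE = ContrastSpec("state", ("EM", "rsBase"), ("EM", "Med"), paired=True)
STATE_TO_TRAIT = ContrastSpec(
    "state_to_trait", ("EM", "rsBase"), ("EM", "rsPost"), paired=True
)

CONTRASTS = {c.name: c for c in (TRAIT, STATE, STATE_TO_TRAIT)}


def assemble_contrast(
    values: pd.DataFrame,
    spec: ContrastSpec,
    cohort: CohortTable,
    value_col: str = "pda",
) -> tuple[np.ndarray, np.ndarray]:
    """Two aligned samples (left, right) of per-session scalars.

    For paired specs both samples are ordered by subject and every left
    subject must have the right session.  ``values`` needs columns
    subject, condition, and ``value_col``.
    """

    def side(group, condition):
        subjects = cohort.sessions(group=group, condition=condition)["subject"]
        sub = values[values["condition"] == condition]
        sub = sub[sub["subject"].isin(subjects)]
        return dict(zip(sub["subject"], sub[value_col]))

    left = side(*spec.left)
    right = side(*spec.right)
    if spec.paired:
        subjects = sorted(left)
        missing = [s for s in subjects if s not in right]
        if missing:
            raise ValidationError(
                f"paired contrast '{spec.name}': subject(s) {missing} missing "
                f"the {spec.right[1]} session"
            )
        lv = np.array([left[s] for s in subjects], dtype=float)
        rv = np.array([right[s] for s in subjects], dtype=float)
        return lv, rv
    return (
        np.array([left[s] for s in sorted(left)], dtype=float),
        np.array([right[s] for s in sorted(right)], dtype=float),
    )
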