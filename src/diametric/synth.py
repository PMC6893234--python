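"""Synthetic 4D BOLD cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
anticorrelated gray-matter networks (DMN, CEN) whose in-band (0.008-0.09 Hz)
amplitude depends on group and condition, white-matter and CSF confound
compartments that leak into gray matter, a low-order drift, voxel noise, and
motion with injected spike artifacts.  Every ground-truth parameter is
recorded in a flat truth ledger so recovery tests never rely on hard-coded
constants.

Cross-node correlation is produced by applying one shared band filter to
independent Gaussian noise and then mixing by the Cholesky factor of the
target correlation matrix; filtering before mixing preserves the target
correlation in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._filters import bandpass_ideal
from .exceptions import DesignError, ValidationError
from .falff import FrequencyBand
from .io import (
    BoldRun,
    CohortTable,
    MOTION_COLUMNS,
    SpatialGrid,
    VolumeMask,
    default_grid,
    write_bold,
    write_cohort,
    write_mask,
    write_motion,
)

GRAY_NETWORKS = ("DMN", "CEN")
NOISE_NETWORKS = ("WM", "CSF")


@dataclass(frozen=True)
class NodeSpec:
    """A spherical signal or confound node."""

    name: str
    network: str  # DMN | CEN | WM | CSF
    center: tuple[int, int, int]
    radius: int = 2
    in_band_amplitude: float = 1.0
    broadband_amplitude: float = 0.25

    def __post_init__(self):
        if self.network not in GRAY_NETWORKS + NOISE_NETWORKS:
            raise ValidationError(f"unknown network '{self.network}'")
        if self.radius < 1:
            raise ValidationError("node radius must be >= 1")
        if self.in_band_amplitude < 0 or self.broadband_amplitude < 0:
            raise ValidationError("amplitudes must be nonnegative")


def default_nodes() -> tuple[NodeSpec, ...]:
    """Four gray nodes (2 DMN + 2 CEN) and one WM + one CSF compartment on
    the default 24^3 grid; placements are schematic, not anatomical."""
    return (
        NodeSpec("DMN_mpfc", "DMN", (11, 18, 12)),
        NodeSpec("DMN_pcc", "DMN", (11, 5, 12)),
        NodeSpec("CEN_dlpfc_l", "CEN", (4, 12, 14)),
        NodeSpec("CEN_dlpfc_r", "CEN", (18, 12, 14)),
        NodeSpec("WM_core", "WM", (11, 11, 5), 2, 1.0, 0.5),
        NodeSpec("CSF_vent", "CSF", (11, 11, 19), 2, 1.0, 0.5),
    )


@dataclass(frozen=True)
class Acquisition:
    tr_seconds: float
    n_volumes: int

    def __post_init__(self):
        if self.tr_seconds <= 0 or self.n_volumes < 8:
            raise ValidationError("invalid acquisition")


def _default_conditions():
    # Mirrors the study design: 5-min rest at TR 2 s (151 volumes) before and
    # after a 20-min meditation block at TR 1.5 s (804 volumes).
    return {
        "rsBase": Acquisition(2.0, 151),
        "Med": Acquisition(1.5, 804),
        "rsPost": Acquisition(2.0, 151),
    }


def _default_multipliers():
    # Trait: meditators show reduced in-band amplitude in both networks at
    # baseline.  State: the CEN amplitude rises during meditation (x1.5 over
    # the meditator baseline) and partially persists afterwards (x1.25).
    return {
        "HC": {"rsBase": {"DMN": 1.0, "CEN": 1.0}},
        "EM": {
            "rsBase": {"DMN": 0.8, "CEN": 0.8},
            "Med": {"DMN": 0.8, "CEN": 1.2},
            "rsPost": {"DMN": 0.8, "CEN": 1.0},
        },
    }


@dataclass
class CohortDesign:
    """All ground-truth parameters of a synthetic cohort."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_mm: float = 4.0
    nodes: tuple[NodeSpec, ...] = field(default_factory=default_nodes)
    n_hc: int = 17
    n_em: int = 16
    conditions: dict = field(default_factory=_default_conditions)
    group_conditions: dict = field(
        default_factory=lambda: {"HC": ("rsBase",), "EM": ("rsBase", "Med", "rsPost")}
    )
    band: FrequencyBand = field(default_factory=FrequencyBand)
    multipliers: dict = field(default_factory=_default_multipliers)
    within_network_r: float = 0.7
    cross_network_r: dict = field(
        default_factory=lambda: {"rsBase": -0.5, "Med": -0.5, "rsPost": -0.5}
    )
    hours_modulate_cross_r: float = 0.0
    confound_leak: float = 0.15
    drift_amplitude: float = 1.0
    noise_sd: float = 1.0
    spike_rate: float = 0.02
    spike_magnitude_mm: float = 0.8
    spike_intensity: float = 4.0
    walk_step_mm: float = 0.02
    hours_mean: float = 1677.0
    hours_sd: float = 367.0

    def __post_init__(self):
        if self.n_hc < 1 or self.n_em < 1:
            raise DesignError("need at least one subject per group")
        if not (0 <= self.spike_rate <= 1):
            raise DesignError("spike_rate must be a probability")
        for grp, conds in self.group_conditions.items():
            for c in conds:
                if c not in self.conditions:
                    raise DesignError(f"condition '{c}' has no acquisition spec")
                m = self.multipliers[grp][c]
                if any(v <= 0 for v in m.values()):
                    raise DesignError("effect multipliers must be > 0")

    # -- derived geometry -------------------------------------------------
    def grid(self) -> SpatialGrid:
        return default_grid(self.grid_shape, self.voxel_mm)

    def gray_nodes(self) -> list[NodeSpec]:
        return [n for n in self.nodes if n.network in GRAY_NETWORKS]

    def node_masks(self) -> dict[str, np.ndarray]:
        """Boolean sphere per node; overlapping or out-of-grid spheres are
        design errors."""
        shape = self.grid_shape
        idx = np.indices(shape)
        masks: dict[str, np.ndarray] = {}
        occupied = np.zeros(shape, dtype=bool)
        for node in self.nodes:
            c = np.asarray(node.center)
            if (c - node.radius < 0).any() or (
                c + node.radius >= np.asarray(shape)
            ).any():
                raise DesignError(f"node {node.name} sphere does not fit in grid")
            d2 = sum((idx[k] - c[k]) ** 2 for k in range(3))
            sphere = d2 <= node.radius**2
            if (occupied & sphere).any():
                raise DesignError(f"node {node.name} overlaps another node")
            occupied |= sphere
            masks[node.name] = sphere
        return masks

    def network_masks(self) -> dict[str, VolumeMask]:
        grid = self.grid()
        node_masks = self.node_masks()
        out = {}
        for net in GRAY_NETWORKS + NOISE_NETWORKS:
            vox = np.zeros(self.grid_shape, dtype=bool)
            for node in self.nodes:
                if node.network == net:
                    vox |= node_masks[node.name]
            if vox.any():
                out[net] = VolumeMask(grid, vox)
        return out

    def multiplier(self, group: str, condition: str, network: str) -> float:
        return float(self.multipliers[group][condition].get(network, 1.0))

    def target_correlation(
        self, condition: str, cross_r: float | None = None
    ) -> np.ndarray:
        """Target correlation matrix across gray nodes for one condition."""
        gray = self.gray_nodes()
        g = len(gray)
        if cross_r is None:
            cross_r = float(self.cross_network_r[condition])
        R = np.eye(g)
        for i in range(g):
            for j in range(i + 1, g):
                same = gray[i].network == gray[j].network
                R[i, j] = R[j, i] = self.within_network_r if same else cross_r
        return R


@dataclass
class RunArtifacts:
    """One generated run plus its motion table and ground truth record."""

    run: BoldRun
    motion: pd.DataFrame
    truth: dict


def _unit_band_noise(rng, n, tr, band, n_series):
    """Independent band-limited columns with unit sample variance."""
    z = rng.standard_normal((n, n_series))
    f = bandpass_ideal(z, tr, band.low_hz, band.high_hz, axis=0)
    sd = f.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return f / sd


def generate_node_timecourses(
    design: CohortDesign,
    condition: str,
    rng,
    group: str = "EM",
    cross_r: float | None = None,
) -> tuple[np.ndarray, list[NodeSpec]]:
    """(time x node) matrix for all nodes of the design.

    Gray nodes share band-limited latent signals mixed by the Cholesky
    factor of the target correlation matrix and scaled by
    in_band_amplitude x condition multiplier; WM/CSF compartments get
    independent band-limited confound signals.  Every node also receives
    independent broadband noise scaled by its broadband_amplitude.
    """
    rng = np.random.default_rng(rng)
    acq = design.conditions[condition]
    n, tr = acq.n_volumes, acq.tr_seconds
    nodes = list(design.nodes)
    gray = design.gray_nodes()
    R = design.target_correlation(condition, cross_r)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as err:
        raise DesignError(
            "target correlation matrix is not positive semidefinite"
        ) from err
    latent = _unit_band_noise(rng, n, tr, design.band, len(gray))
    mixed = latent @ L.T
    # re-standardize after mixing: sample correlations are unchanged and
    # every node gets exactly unit sample variance (no node is privileged
    # by its position in the Cholesky factor)
    sd = mixed.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    mixed = mixed / sd
    out = np.zeros((n, len(nodes)))
    gi = 0
    for j, node in enumerate(nodes):
        if node.network in GRAY_NETWORKS:
            mult = design.multiplier(group, condition, node.network)
            sig = node.in_band_amplitude * mult * mixed[:, gi]
            gi += 1
        else:
            sig = node.in_band_amplitude * _unit_band_noise(rng, n, tr, design.band, 1)[
                :, 0
            ]
        if node.broadband_amplitude > 0:
            sig = sig + node.broadband_amplitude * rng.standard_normal(n)
        out[:, j] = sig
    return out, nodes


def generate_run(
    design: CohortDesign,
    subject: str,
    group: str,
    condition: str,
    rng_seed,
    cross_r: float | None = None,
) -> RunArtifacts:
    """One 4D run + motion table + truth record; deterministic given seed."""
    rng = np.random.default_rng(rng_seed)
    acq = design.conditions[condition]
    n, tr = acq.n_volumes, acq.tr_seconds
    tc, nodes = generate_node_timecourses(design, condition, rng, group, cross_r)
    node_masks = design.node_masks()

    data = design.noise_sd * rng.standard_normal(design.grid_shape + (n,))

    # WM/CSF confound signals leak (scaled) into every gray node.
    leak = np.zeros(n)
    for j, node in enumerate(nodes):
        if node.network in NOISE_NETWORKS:
            leak = leak + tc[:, j]
    leak = design.confound_leak * leak

    for j, node in enumerate(nodes):
        series = tc[:, j]
        if node.network in GRAY_NETWORKS:
            series = series + leak
        data[node_masks[node.name]] += series

    drift = design.drift_amplitude * (np.arange(n) / max(n - 1, 1) - 0.5)
    data += drift

    # Motion: slow random walk; spikes are persistent position steps > the
    # outlier threshold, matched by a one-volume global intensity jump.
    steps = rng.normal(0.0, design.walk_step_mm, size=(n, 6))
    steps[0] = 0.0
    spike_draws = rng.random(n - 1)
    spike_times = [int(t) for t in np.nonzero(spike_draws < design.spike_rate)[0] + 1]
    for t in spike_times:
        axis = int(rng.integers(0, 3))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        steps[t, axis] += sign * design.spike_magnitude_mm
        data[..., t] += design.spike_intensity
    motion = pd.DataFrame(np.cumsum(steps, axis=0), columns=list(MOTION_COLUMNS))

    run = BoldRun(design.grid(), data, tr, subject=subject, condition=condition)
    truth = {
        "subject": subject,
        "group": group,
        "condition": condition,
        "tr_seconds": tr,
        "n_volumes": n,
        "multipliers": {
            net: design.multiplier(group, condition, net) for net in GRAY_NETWORKS
        },
        "cross_network_r": float(
            design.cross_network_r[condition] if cross_r is None else cross_r
        ),
        "within_network_r": design.within_network_r,
        "confound_leak": design.confound_leak,
        "drift_amplitude": design.drift_amplitude,
        "spike_rate": design.spike_rate,
        "spike_times": spike_times,
        "nodes": [asdict(nd) for nd in nodes],
    }
    return RunArtifacts(run, motion, truth)


@dataclass
class Cohort:
    """A generated cohort: session table, masks, truth ledger, and either
    in-memory runs or on-disk paths."""

    design: CohortDesign
    table: CohortTable
    masks: dict
    truth: dict
    runs: dict | None = None  # (subject, condition) -> RunArtifacts
    out_dir: Path | None = None


def _cohort_rows(design: CohortDesign, rng) -> pd.DataFrame:
    rows = []
    for i in range(design.n_hc):
        rows.append({"subject": f"HC{i + 1:02d}", "group": "HC"})
    for i in range(design.n_em):
        rows.append({"subject": f"EM{i + 1:02d}", "group": "EM"})
    recs = []
    for row in rows:
        if row["group"] == "EM":
            hours = float(
                np.clip(rng.normal(design.hours_mean, design.hours_sd), 100.0, None)
            )
        else:
            hours = np.nan
        for cond in design.group_conditions[row["group"]]:
            recs.append({**row, "condition": cond, "meditation_hours": hours})
    return pd.DataFrame(recs)


def generate_cohort(design: CohortDesign, seed, out_dir=None, compress=True) -> Cohort:
    """Generate every session of the design.

    With ``out_dir`` set, runs are written to disk (NIfTI + motion TSV) and
    dropped from memory; otherwise all runs are kept in ``Cohort.runs``
    (only sensible for desk-scale designs).
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    frame = _cohort_rows(design, rng)

    hours = frame["meditation_hours"]
    if design.hours_modulate_cross_r and hours.notna().any():
        h = hours[hours.notna()]
        h_std = (h - h.mean()) / (h.std(ddof=1) or 1.0)
        hours_z = dict(zip(frame.loc[h.index, "subject"], h_std))
    else:
        hours_z = {}

    child_seeds = ss.spawn(len(frame))
    masks = design.network_masks()
    runs = {} if out_dir is None else None
    truth_runs = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "runs").mkdir(parents=True, exist_ok=True)

    paths = []
    for (idx, row), child in zip(frame.iterrows(), child_seeds):
        cross_r = None
        if row["subject"] in hours_z:
            base = float(design.cross_network_r[row["condition"]])
            # keep the per-subject target inside the PSD region of the
            # block correlation matrix: |cross| < (1 + within) / 2
            bound = (1.0 + design.within_network_r) / 2.0 - 0.05
            cross_r = float(
                np.clip(
                    base + design.hours_modulate_cross_r * hours_z[row["subject"]],
                    -bound,
                    bound,
                )
            )
        art = generate_run(
            design, row["subject"], row["group"], row["condition"], child, cross_r
        )
        truth_runs.append(art.truth)
        if out_dir is None:
            runs[(row["subject"], row["condition"])] = art
            paths.append({"run_path": "", "motion_path": ""})
        else:
            stem = f"{row['subject']}_{row['condition']}"
            ext = ".nii.gz" if compress else ".nii"
            run_path = out_dir / "runs" / f"{stem}{ext}"
            motion_path = out_dir / "runs" / f"{stem}_motion.tsv"
            write_bold(art.run, run_path)
            write_motion(art.motion, motion_path)
            paths.append(
                {"run_path": str(run_path), "motion_path": str(motion_path)}
            )

    frame = pd.concat([frame, pd.DataFrame(paths, index=frame.index)], axis=1)
    table = CohortTable(frame)
    truth = {
        "seed": int(seed) if np.isscalar(seed) else None,
        "design": {
            "grid_shape": list(design.grid_shape),
            "n_hc": design.n_hc,
            "n_em": design.n_em,
            "multipliers": design.multipliers,
            "cross_network_r": design.cross_network_r,
            "within_network_r": design.within_network_r,
            "hours_modulate_cross_r": design.hours_modulate_cross_r,
            "confound_leak": design.confound_leak,
            "spike_rate": design.spike_rate,
        },
        "runs": truth_runs,
    }
    cohort = Cohort(design, table, masks, truth, runs, out_dir)
    if out_dir is not None:
        write_cohort(table, out_dir / "cohort.tsv")
        for name, mask in masks.items():
            write_mask(mask, out_dir / f"mask_{name}.nii.gz")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return cohort
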