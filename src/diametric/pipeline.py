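"""End-to-end orchestration: simulate -> preprocess -> fALFF -> trait-ROI
derivation -> connectivity -> PDA -> group inference, from one config and
one seed, with a manifest that makes every output table reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .connectivity import fc_map, seed_timecourse
from .exceptions import DiametricError, ValidationError
from .falff import FrequencyBand, add_zscores, compute_falff, extract_roi_mean
from .inference import (
    PermutationConfig,
    TfceParams,
    covariate_correlation,
    median_split_compare,
    paired_ttest,
    permutation_test,
    rm_anova,
)
from .io import VolumeMask, read_bold, read_motion, write_map, write_mask
from .pda import CONTRASTS, assemble_contrast, pda_table
from .preprocess import (
    OutlierConfig,
    build_confounds,
    denoise,
    detect_outliers,
    erode_mask,
    global_signal,
    smooth,
)
from .synth import Acquisition, CohortDesign, generate_cohort

_STRUCTURE6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class PipelineConfig:
    """Everything run_all needs; the demo default is a desk-scale mirror of
    the full study design (8+8 subjects, 200 volumes, 500 permutations)."""

    design: CohortDesign = field(default_factory=CohortDesign)
    band: FrequencyBand = field(default_factory=FrequencyBand)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    tfce: TfceParams = field(default_factory=TfceParams)
    n_compcor: int = 5
    smooth_fwhm_mm: float = 8.0
    n_permutations_activity: int = 5000
    n_permutations_fc: int = 1000
    height_p: float = 0.05
    cluster_fdr_q: float = 0.05
    compress_volumes: bool = True


def demo_config() -> PipelineConfig:
    """Scaled-down default design: complete on one CPU in minutes."""
    design = CohortDesign(
        n_hc=8,
        n_em=8,
        conditions={
            "rsBase": Acquisition(2.0, 200),
            "Med": Acquisition(1.5, 200),
            "rsPost": Acquisition(2.0, 200),
        },
    )
    return PipelineConfig(
        design=design,
        n_permutations_activity=500,
        n_permutations_fc=500,
        compress_volumes=False,
    )


def config_from_dict(d: dict) -> PipelineConfig:
    cfg = demo_config() if d.get("demo", True) else PipelineConfig()
    design = cfg.design
    for key in ("n_hc", "n_em"):
        if key in d:
            setattr(design, key, int(d[key]))
    if "n_volumes" in d:
        n = int(d["n_volumes"])
        design.conditions = {
            "rsBase": Acquisition(2.0, n),
            "Med": Acquisition(1.5, n),
            "rsPost": Acquisition(2.0, n),
        }
    if "grid_shape" in d:
        design.grid_shape = tuple(int(x) for x in d["grid_shape"])
    if "band" in d:
        cfg.band = FrequencyBand(*[float(x) for x in d["band"]])
    for key in (
        "n_compcor",
        "smooth_fwhm_mm",
        "n_permutations_activity",
        "n_permutations_fc",
        "height_p",
        "cluster_fdr_q",
    ):
        if key in d:
            setattr(cfg, key, type(getattr(cfg, key))(d[key]))
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _config_fingerprint(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_trait_rois(
    hc_maps: list[np.ndarray],
    em_maps: list[np.ndarray],
    templates: dict[str, VolumeMask],
    config: PipelineConfig,
    seed: int = 0,
    return_details: bool = False,
):
    """Data-driven ROI masks from the trait contrast on fALFF maps.

    Within each network template, an unpaired TFCE permutation test
    compares meditators against controls at baseline; voxels significant
    under max-TFCE FWE correction are binarized and split into 6-connected
    components.  If nothing survives in a network, its template is
    returned as a single ROI with a warning.
    """
    out: dict[str, VolumeMask] = {}
    details: dict[str, pd.DataFrame] = {}
    for net, template in templates.items():
        bbox = ndimage.find_objects(template.voxels.astype(int))[0]
        hc = np.stack([m[bbox] for m in hc_maps])
        em = np.stack([m[bbox] for m in em_maps])
        res = permutation_test(
            hc,
            em,
            paired=False,
            config=PermutationConfig(
                n_permutations=config.n_permutations_activity,
                seed=seed,
                height_p=config.height_p,
                cluster_fdr_q=config.cluster_fdr_q,
            ),
            tfce=config.tfce,
            mask=template.voxels[bbox],
            alternative="two-sided",
        )
        clusters = res.clusters.copy()
        if len(clusters):
            offset = np.array([s.start for s in bbox])
            peaks = np.stack(
                [offset + np.array(p) for p in clusters["peak_voxel"]]
            )
            clusters["peak_voxel"] = [tuple(int(v) for v in p) for p in peaks]
            mm = template.grid.voxel_to_world(peaks.astype(float))
            mm = np.atleast_2d(mm)
            for ax, name in enumerate(("peak_x_mm", "peak_y_mm", "peak_z_mm")):
                clusters[name] = np.round(mm[:, ax], 3)
        details[net] = clusters
        sig = res.p_fwe < config.cluster_fdr_q
        if not sig.any():
            warnings.warn(
                f"no significant trait voxels in {net}; falling back to the "
                "template mask as a single ROI"
            )
            out[f"{net}_roi1"] = template
            continue
        lab, n_lab = ndimage.label(sig, structure=_STRUCTURE6)
        for k in range(1, n_lab + 1):
            vox = np.zeros(template.grid.shape, dtype=bool)
            vox[bbox] = lab == k
            out[f"{net}_roi{k}"] = VolumeMask(template.grid, vox)
    if return_details:
        return out, details
    return out


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _json_ready(obj.to_dict(orient="records"))
    return obj


def run_all(config: PipelineConfig, seed: int, out_dir) -> dict:
    """Execute every stage in dependency order; returns the run manifest.

    Outputs: per-session fALFF/PDA tables (activity box-plot analogs), FC
    summary tables, derived trait ROIs, an inference report (trait, state,
    state-to-trait contrasts; repeated-measures tests; practice-hours
    analyses), a truth-vs-estimate recovery table, and manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "maps").mkdir(exist_ok=True)
    manifest = {
        "config_hash": _config_fingerprint(config),
        "seed": int(seed),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": [],
    }
    design = config.design
    stage = "simulate"
    try:
        cohort = generate_cohort(
            design, seed, out_dir=out_dir / "sim", compress=config.compress_volumes
        )
        manifest["stages"][stage] = str(out_dir / "sim")

        # -- per-session fALFF maps (smoothed, unfiltered data) ----------
        stage = "falff"
        masks = cohort.masks
        frame = cohort.table.frame
        falff_maps: dict[tuple[str, str], np.ndarray] = {}
        for _, row in frame.iterrows():
            run = read_bold(row.run_path)
            run = smooth(run, config.smooth_fwhm_mm)
            fmap = compute_falff(run, config.band)
            falff_maps[(row.subject, row.condition)] = fmap.values
            write_map(
                cohort.design.grid(),
                fmap.values,
                out_dir / "maps" / f"falff_{row.subject}_{row.condition}.nii.gz",
            )
        grid = design.grid()
        band = config.band

        rows = []
        for (subject, condition), values in falff_maps.items():
            from .falff import FalffMap

            fmap = FalffMap(grid, values, band, design.conditions[condition].tr_seconds)
            for net in ("DMN", "CEN"):
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "roi": net,
                        "mean_falff": extract_roi_mean(fmap, masks[net]),
                    }
                )
        roi_long = pd.DataFrame(rows).sort_values(
            ["subject", "condition", "roi"]
        ).reset_index(drop=True)
        roi_long.to_csv(out_dir / "falff_roi.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "falff_roi.tsv"

        # -- PDA tables: trait reference set and EM state reference set --
        stage = "pda"
        groups = dict(zip(frame.subject, frame.group))
        is_base = roi_long.condition == "rsBase"
        trait_tbl = add_zscores(roi_long[is_base].copy())
        pda_trait = pda_table(trait_tbl, ["DMN"], ["CEN"])
        pda_trait["group"] = pda_trait.subject.map(groups)
        pda_trait.to_csv(out_dir / "pda_trait.tsv", sep="\t", index=False)

        em_subjects = set(frame.loc[frame.group == "EM", "subject"])
        state_tbl = add_zscores(
            roi_long[roi_long.subject.isin(em_subjects)].copy()
        )
        pda_state = pda_table(state_tbl, ["DMN"], ["CEN"])
        pda_state.to_csv(out_dir / "pda_state.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "pda_trait.tsv, pda_state.tsv"

        # -- trait ROI derivation (seeds for connectivity) ---------------
        stage = "derive_trait_rois"
        hc_base = [
            falff_maps[(s, "rsBase")]
            for s in sorted(frame.loc[frame.group == "HC", "subject"].unique())
        ]
        em_base = [
            falff_maps[(s, "rsBase")] for s in sorted(em_subjects)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seeds_masks, cluster_tables = derive_trait_rois(
                hc_base,
                em_base,
                {"DMN": masks["DMN"], "CEN": masks["CEN"]},
                config,
                seed=seed + 1,
                return_details=True,
            )
        for name, m in seeds_masks.items():
            write_mask(m, out_dir / "maps" / f"seed_{name}.nii.gz")
        for net, tbl in cluster_tables.items():
            tbl.to_csv(
                out_dir / f"trait_clusters_{net}.tsv", sep="\t", index=False
            )
        manifest["stages"][stage] = sorted(seeds_masks)

        # -- connectivity: denoise each run, seed maps, network means ----
        stage = "connectivity"
        wm = erode_mask(masks["WM"])
        csf = erode_mask(masks["CSF"])
        fc_rows = []
        for _, row in frame.iterrows():
            raw = read_bold(row.run_path)
            motion = read_motion(row.motion_path)
            flags = detect_outliers(
                motion.values, global_signal(raw), config.outliers
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                confounds = build_confounds(
                    raw, wm, csf, motion.values, flags, config.n_compcor
                )
                clean = denoise(
                    smooth(raw, config.smooth_fwhm_mm), confounds, config.band
                )
            for seed_name, seed_mask in sorted(seeds_masks.items()):
                tc = seed_timecourse(clean, seed_mask)
                cmap = fc_map(clean, tc, seed_label=seed_name)
                for net in ("DMN", "CEN"):
                    fc_rows.append(
                        {
                            "subject": row.subject,
                            "condition": row.condition,
                            "seed": seed_name,
                            "target_network": net,
                            "mean_z": float(
                                np.nanmean(cmap.values[masks[net].voxels])
                            ),
                        }
                    )
        fc_summary = pd.DataFrame(fc_rows).sort_values(
            ["subject", "condition", "seed", "target_network"]
        ).reset_index(drop=True)
        fc_summary.to_csv(out_dir / "fc_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "fc_summary.tsv"

        # -- group inference ---------------------------------------------
        stage = "inference"
        report = {
            "seed": int(seed),
            "n_permutations": {
                "activity": config.n_permutations_activity,
                "fc": config.n_permutations_fc,
            },
        }
        perm_cfg = PermutationConfig(
            n_permutations=config.n_permutations_activity, seed=seed + 2
        )
        for name, spec in CONTRASTS.items():
            values = pda_trait if name == "trait" else pda_state
            left, right = assemble_contrast(values, spec, cohort.table)
            res = permutation_test(
                left, right, paired=spec.paired, config=perm_cfg
            )
            entry = {
                "method": res.method,
                "statistic": round(float(res.stat), 8),
                "p_permutation": round(float(res.p), 8),
                "n_left": len(left),
                "n_right": len(right),
            }
            if spec.paired:
                tt = paired_ttest(left, right)
                entry["paired_t"] = round(tt.t, 8)
                entry["paired_df"] = tt.df
            report[f"pda_{name}"] = entry

        anova = rm_anova(pda_state.rename(columns={"pda": "value"}))
        report["pda_rm_anova"] = {
            "chi2": round(anova.chi2, 8),
            "df": anova.df,
            "p": round(anova.p, 8),
            "condition_means": _json_ready(anova.condition_means),
            "tukey": _json_ready(anova.tukey),
        }
        cen_tbl = state_tbl[state_tbl.roi == "CEN"].rename(columns={"z": "value"})
        anova_cen = rm_anova(cen_tbl)
        report["cen_falff_rm_anova"] = {
            "chi2": round(anova_cen.chi2, 8),
            "df": anova_cen.df,
            "p": round(anova_cen.p, 8),
        }

        # FC state contrast: CEN-seed connectivity with the DMN
        cen_seeds = [s for s in seeds_masks if s.startswith("CEN")]
        fc_val = (
            fc_summary[
                (fc_summary.seed.isin(cen_seeds))
                & (fc_summary.target_network == "DMN")
            ]
            .groupby(["subject", "condition"], as_index=False)["mean_z"]
            .mean()
        )
        fc_cfg = PermutationConfig(
            n_permutations=config.n_permutations_fc, seed=seed + 3
        )
        for name in ("state", "state_to_trait"):
            left, right = assemble_contrast(
                fc_val, CONTRASTS[name], cohort.table, value_col="mean_z"
            )
            res = permutation_test(left, right, paired=True, config=fc_cfg)
            report[f"fc_cen_dmn_{name}"] = {
                "statistic": round(float(res.stat), 8),
                "p_permutation": round(float(res.p), 8),
            }

        # practice hours: correlation with baseline CEN->DMN connectivity
        hours = (
            frame[frame.group == "EM"]
            .drop_duplicates("subject")
            .set_index("subject")["meditation_hours"]
        )
        em_base_fc = fc_val[
            (fc_val.condition == "rsBase") & (fc_val.subject.isin(em_subjects))
        ].set_index("subject")["mean_z"]
        common = sorted(set(hours.index) & set(em_base_fc.index))
        try:
            corr = covariate_correlation(
                em_base_fc[common].values,
                hours[common].values,
                n_permutations=config.n_permutations_fc,
                seed=seed + 4,
            )
            report["hours_vs_fc_rsBase"] = {
                "r": round(float(corr.r), 8),
                "p_permutation": round(float(corr.p), 8),
                "n": corr.n,
            }
        except ValidationError as err:
            report["hours_vs_fc_rsBase"] = {"skipped": str(err)}
        hc_base_fc = fc_val[
            (fc_val.condition == "rsBase") & (~fc_val.subject.isin(em_subjects))
        ]["mean_z"].values
        try:
            split = median_split_compare(
                em_base_fc[common].values, hours[common].values, hc_base_fc
            )
            report["hours_median_split"] = {
                "median_hours": round(split.median, 4),
                "n_ties": split.n_ties,
                "group_means": _json_ready(split.group_means),
                "chi2": round(split.chi2, 8),
                "p": round(split.p, 8),
                "tukey": _json_ready(split.tukey),
            }
        except ValidationError as err:
            report["hours_median_split"] = {"skipped": str(err)}
        with open(out_dir / "inference_report.json", "w") as fh:
            json.dump(_json_ready(report), fh, indent=1, sort_keys=True)
        manifest["stages"][stage] = "inference_report.json"

        # -- truth-vs-estimate recovery table -----------------------------
        stage = "recovery"
        truth_rows = []
        truth_by_session = {
            (t["subject"], t["condition"]): t for t in cohort.truth["runs"]
        }
        for _, r in roi_long.iterrows():
            t = truth_by_session[(r.subject, r.condition)]
            truth_rows.append(
                {
                    "subject": r.subject,
                    "condition": r.condition,
                    "network": r.roi,
                    "truth_multiplier": t["multipliers"][r.roi],
                    "estimated_mean_falff": r.mean_falff,
                }
            )
        pd.DataFrame(truth_rows).to_csv(
            out_dir / "truth_recovery.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = "truth_recovery.tsv"
    except DiametricError as err:
        manifest["failed_stage"] = stage
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise DiametricError(f"stage '{stage}' failed: {err}") from err

    manifest["outputs"] = sorted(
        str(p.relative_to(out_dir)) for p in out_dir.glob("*.tsv")
    ) + ["inference_report.json"]
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
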