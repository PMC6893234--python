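"""Group inference: permutation tests with TFCE, cluster-size FDR,
mixed-model repeated-measures ANOVA with Tukey post hoc, covariate
correlations, and the median-split practice-hours comparison.

Conventions
-----------
* Permutation p-values are (b + 1) / (m + 1) with b the count of null
  statistics at least as extreme as the observed one, so p is never zero.
* When fewer distinct relabelings exist than requested permutations, the
  null is enumerated exactly and the result is flagged ``exact``.
* Within TFCE permutation the max-statistic (FWE-style) correction is used;
  cluster-size FDR forms clusters at the uncorrected height threshold and
  BH-adjusts cluster-size p-values across clusters.  Both styles are
  reported with explicit method labels.
* Connected components use 6-connectivity (faces only) throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import VolumeMask

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class TfceParams:
    """TFCE exponents and height-integration control.

    By default the threshold integral is evaluated exactly: the cluster
    extent e(h, v) is piecewise constant between the map's distinct values,
    so summing closed-form height-cell integrals over those breakpoints
    reproduces the continuum definition to machine precision.  For large
    maps a fixed step can be forced with ``dh`` (or ``n_steps``, giving
    dh = max_stat / n_steps); extent is then sampled at each cell's lower
    edge while the h^H factor is still integrated exactly within the cell.
    """

    height_exponent: float = 2.0
    extent_exponent: float = 0.5
    dh: float | None = None
    n_steps: int | None = None
    connectivity: int = 6

    def __post_init__(self):
        if self.height_exponent <= 0 or self.extent_exponent <= 0:
            raise ValidationError("TFCE exponents must be > 0")
        if self.dh is not None and self.dh <= 0:
            raise ValidationError("TFCE dh must be > 0")
        if self.n_steps is not None and self.n_steps < 1:
            raise ValidationError("TFCE n_steps must be >= 1")
        if self.connectivity not in _STRUCTURES:
            raise ValidationError("connectivity must be 6, 18, or 26")


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation counts and reporting thresholds (5000 is conventional
    for activity maps, 1000 for FC maps)."""

    n_permutations: int = 5000
    seed: int = 0
    height_p: float = 0.05
    cluster_fdr_q: float = 0.05

    def __post_init__(self):
        if self.n_permutations < 100:
            raise ValidationError("need >= 100 permutations for reported p")
        if not (0 < self.height_p < 1) or not (0 < self.cluster_fdr_q < 1):
            raise ValidationError("thresholds must be in (0, 1)")


def _tfce_one_tail(pos: np.ndarray, params: TfceParams) -> np.ndarray:
    """Sum of e(h, v)^E h^H dh over 0 < h <= stat(v) for one (positive) tail."""
    out = np.zeros_like(pos, dtype=float)
    vmax = float(pos.max(initial=0.0))
    if vmax <= 0:
        return out
    structure = _STRUCTURES[params.connectivity]
    H = params.height_exponent
    E = params.extent_exponent
    if params.dh is not None or params.n_steps is not None:
        dh = params.dh if params.dh is not None else vmax / params.n_steps
        edges = np.arange(0.0, vmax, dh)
        uppers = np.minimum(edges + dh, vmax)
        exact = False
    else:
        vals = np.unique(pos[pos > 0])
        edges = np.concatenate([[0.0], vals[:-1]])
        uppers = vals
        exact = True
    for a, b in zip(edges, uppers):
        supra = pos > a
        if not supra.any():
            break
        lab, _ = ndimage.label(supra, structure=structure)
        sizes = np.bincount(lab.ravel()).astype(float)
        sizes[0] = 0.0
        ext = sizes**E
        if exact:
            # every suprathreshold voxel has value >= b: full cell weight
            weight = (b ** (H + 1) - a ** (H + 1)) / (H + 1)
            out += np.where(supra, ext[lab] * weight, 0.0)
        else:
            weight = (np.minimum(pos, b) ** (H + 1) - a ** (H + 1)) / (H + 1)
            out += np.where(supra, ext[lab] * weight, 0.0)
    return out


def tfce_enhance(
    stat_map: np.ndarray,
    params: TfceParams | None = None,
    mask: VolumeMask | np.ndarray | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic map.

    TFCE(v) = sum over heights 0 < h <= stat(v) of e(h, v)^E * h^H * dh,
    with e(h, v) the voxel count of the suprathreshold connected cluster
    containing v.  Negative values are enhanced on the negated map and
    returned with negative sign.
    """
    if params is None:
        params = TfceParams()
    stat_map = np.asarray(stat_map, dtype=float)
    if mask is not None:
        m = mask.voxels if isinstance(mask, VolumeMask) else np.asarray(mask, bool)
        stat_map = np.where(m, stat_map, 0.0)
    if not np.isfinite(stat_map).all():
        raise ValidationError("stat map contains non-finite values")
    pos = _tfce_one_tail(np.maximum(stat_map, 0.0), params)
    neg = _tfce_one_tail(np.maximum(-stat_map, 0.0), params)
    return pos - neg


@dataclass
class PermutationResult:
    stat: np.ndarray | float
    p: np.ndarray | float
    n_permutations: int
    exact: bool
    method: str
    alternative: str
    tfce_stat: np.ndarray | None = None
    p_fwe: np.ndarray | None = None
    clusters: pd.DataFrame | None = None
    height_threshold: float | None = None


def _paired_t(d: np.ndarray) -> np.ndarray:
    """t statistic of mean(d) = 0 along axis 0 (d: n x ... )."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _unpaired_t(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (right - left) along axis 0."""
    n1, n2 = left.shape[0], right.shape[0]
    m1, m2 = left.mean(axis=0), right.mean(axis=0)
    v1 = left.var(axis=0, ddof=1)
    v2 = right.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.where(np.isfinite(t), t, 0.0)


def _directional(stat, alternative):
    if alternative == "greater":
        return np.asarray(stat)
    if alternative == "less":
        return -np.asarray(stat)
    if alternative == "two-sided":
        return np.abs(np.asarray(stat))
    raise ValidationError(f"unknown alternative '{alternative}'")


def _sign_patterns(n: int, n_permutations: int, rng):
    """Sign-flip matrix for the paired null; exact enumeration when small."""
    if 2**n <= n_permutations:
        pats = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return pats, True
    signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    return signs, False


def _label_permutations(n1: int, n2: int, n_permutations: int, rng):
    """Index sets assigned to 'right' under the unpaired null."""
    total = n1 + n2
    from math import comb

    if comb(total, n2) <= n_permutations:
        sets = [np.array(c) for c in itertools.combinations(range(total), n2)]
        return sets, True
    sets = [rng.permutation(total)[:n2] for _ in range(n_permutations)]
    return sets, False


def permutation_test(
    left: np.ndarray,
    right: np.ndarray,
    paired: bool,
    config: PermutationConfig | None = None,
    tfce: TfceParams | None = None,
    mask: VolumeMask | np.ndarray | None = None,
    alternative: str = "greater",
) -> PermutationResult:
    """Nonparametric two-sample test on scalars or stacked 3D maps.

    The statistic is a paired (sign-flip null) or pooled two-sample
    (label-permutation null) t; effect direction is right - left.  With
    ``tfce`` set (maps only) the max-TFCE statistic yields FWE-style voxel
    p-values and a cluster-size FDR table is produced at the uncorrected
    height threshold.
    """
    if config is None:
        config = PermutationConfig()
    rng = np.random.default_rng(config.seed)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    is_map = left.ndim > 1
    if is_map and left.shape[1:] != right.shape[1:]:
        raise ValidationError("left/right map shapes differ")
    if min(left.shape[0], right.shape[0]) < 3:
        raise ValidationError("group sizes must be >= 3")
    if tfce is not None and not is_map:
        raise ValidationError("TFCE applies to maps, not scalars")

    mask_arr = None
    if mask is not None:
        mask_arr = mask.voxels if isinstance(mask, VolumeMask) else np.asarray(
            mask, bool
        )

    if paired:
        if left.shape[0] != right.shape[0]:
            raise ValidationError("paired samples must be aligned")
        d = right - left
        obs = _paired_t(d)
        signs, exact = _sign_patterns(d.shape[0], config.n_permutations, rng)
        null_stats = np.stack(
            [_paired_t(d * s.reshape((-1,) + (1,) * (d.ndim - 1))) for s in signs]
        )
        method = "paired sign-flip t"
    else:
        obs = _unpaired_t(left, right)
        pooled = np.concatenate([left, right], axis=0)
        sets, exact = _label_permutations(
            left.shape[0], right.shape[0], config.n_permutations, rng
        )
        all_idx = np.arange(pooled.shape[0])
        null_list = []
        for right_idx in sets:
            mask_right = np.zeros(pooled.shape[0], dtype=bool)
            mask_right[right_idx] = True
            null_list.append(
                _unpaired_t(pooled[~mask_right], pooled[mask_right])
            )
        null_stats = np.stack(null_list)
        method = "unpaired label-permutation t"
    m = null_stats.shape[0]

    if mask_arr is not None and is_map:
        obs = np.where(mask_arr, obs, 0.0)
        null_stats = np.where(mask_arr, null_stats, 0.0)

    obs_dir = _directional(obs, alternative)
    null_dir = _directional(null_stats, alternative)
    b = (null_dir >= obs_dir - 1e-12).sum(axis=0)
    # exact enumeration includes the identity relabeling, so b/m is already
    # a valid p; sampled nulls add the observed statistic: (b+1)/(m+1)
    p = b / m if exact else (b + 1) / (m + 1)

    result = PermutationResult(
        stat=obs if is_map else float(obs),
        p=p if is_map else float(p),
        n_permutations=m,
        exact=exact,
        method=method,
        alternative=alternative,
    )

    if tfce is not None:
        obs_enh = tfce_enhance(obs, tfce, mask_arr)
        obs_enh_dir = _directional(obs_enh, alternative)
        null_max = np.empty(m)
        for i in range(m):
            enh = tfce_enhance(null_stats[i], tfce, mask_arr)
            null_max[i] = _directional(enh, alternative).max()
        b_fwe = (null_max[:, None] >= obs_enh_dir.reshape(1, -1) - 1e-12).sum(axis=0)
        result.tfce_stat = obs_enh
        p_fwe = b_fwe / m if exact else (b_fwe + 1) / (m + 1)
        result.p_fwe = p_fwe.reshape(obs.shape)

    if is_map:
        result.clusters, result.height_threshold = _cluster_fdr(
            obs, null_stats, config, alternative, tfce or TfceParams()
        )
    return result


def _cluster_fdr(obs, null_stats, config, alternative, params):
    """Cluster-size FDR: clusters at the uncorrected height threshold; each
    cluster's size is compared against the permutation null distribution of
    the maximum cluster size; BH across clusters."""
    structure = _STRUCTURES[params.connectivity]
    null_dir = _directional(null_stats, alternative)
    obs_dir = _directional(obs, alternative)
    thresh = float(np.quantile(null_dir.ravel(), 1.0 - config.height_p))
    lab, n_lab = ndimage.label(obs_dir > thresh, structure=structure)
    m = null_stats.shape[0]
    null_max_size = np.zeros(m, dtype=int)
    for i in range(m):
        lab_i, n_i = ndimage.label(null_dir[i] > thresh, structure=structure)
        if n_i:
            null_max_size[i] = np.bincount(lab_i.ravel())[1:].max()
    rows = []
    for k in range(1, n_lab + 1):
        vox = lab == k
        size = int(vox.sum())
        peak_flat = np.argmax(np.where(vox, obs_dir, -np.inf))
        peak = tuple(int(i) for i in np.unravel_index(peak_flat, obs.shape))
        p_k = (np.sum(null_max_size >= size) + 1) / (m + 1)
        rows.append(
            {"cluster": k, "size": size, "peak_voxel": peak, "p": p_k}
        )
    clusters = pd.DataFrame(rows)
    if len(clusters):
        clusters["p_fdr"] = fdr_adjust(clusters["p"].values)
    else:
        clusters["p_fdr"] = pd.Series(dtype=float)
    return clusters, thresh


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def paired_ttest(left, right, alternative: str = "greater") -> TTestResult:
    """Classical paired t test (df = n - 1); effect = right - left."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    if left.shape != right.shape:
        raise ValidationError("paired samples must be aligned")
    res = stats.ttest_rel(right, left, alternative=alternative)
    return TTestResult(float(res.statistic), int(left.size - 1), float(res.pvalue))


@dataclass
class RmAnovaResult:
    chi2: float
    df: int
    p: float
    condition_means: dict
    tukey: pd.DataFrame
    n_subjects: int


def rm_anova(data: pd.DataFrame, value_col: str = "value") -> RmAnovaResult:
    """One-way repeated-measures test via a linear mixed model.

    Fits value ~ condition with a random subject intercept by maximum
    likelihood and compares against the intercept-only model:
    chi2 = 2 (ll_full - ll_null), df = k - 1.  Post hoc: pairwise condition
    contrasts with Tukey adjustment (studentized range on the model's
    estimated marginal means, residual df (n-1)(k-1)).
    """
    df = data[["subject", "condition", value_col]].rename(
        columns={value_col: "value"}
    )
    wide = df.pivot(index="subject", columns="condition", values="value")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) with incomplete conditions"
        )
        wide = wide.drop(index=incomplete)
    n, k = wide.shape
    if n < 3:
        raise ValidationError("need at least 3 complete subjects")
    if k < 2:
        raise ValidationError("need at least 2 conditions")
    long = wide.reset_index().melt(
        id_vars="subject", var_name="condition", value_name="value"
    )
    means = long.groupby("condition")["value"].mean().to_dict()
    conditions = sorted(means)

    if np.allclose(long["value"], long["value"].iloc[0]):
        tukey = _tukey_table(conditions, means, scale=0.0, n=n, df_error=1)
        tukey["p"] = 1.0
        return RmAnovaResult(0.0, k - 1, 1.0, means, tukey, n)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        def _fit(formula):
            # ML surfaces can be flat in the variance ratio; keep the best
            # of several optimizers by log-likelihood
            model = mixedlm(formula, long, groups="subject")
            best = None
            for method in (None, "lbfgs", "powell", "cg"):
                try:
                    kwargs = {"method": method, "maxiter": 500} if method else {}
                    fit = model.fit(reml=False, **kwargs)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
                    best = fit
            if best is None:
                raise ValidationError("mixed model failed to converge")
            return best

        full = _fit("value ~ C(condition)")
        null = _fit("value ~ 1")
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    dof = k - 1
    p = float(stats.chi2.sf(chi2, dof))
    df_error = (n - 1) * (k - 1)
    tukey = _tukey_table(conditions, means, float(full.scale), n, df_error)
    return RmAnovaResult(float(chi2), dof, p, means, tukey, n)


def _tukey_table(conditions, means, scale, n, df_error):
    rows = []
    k = len(conditions)
    for a, b in itertools.combinations(conditions, 2):
        diff = means[b] - means[a]
        if scale > 0:
            q = abs(diff) / np.sqrt(scale / n)
            p = float(stats.studentized_range.sf(q, k, df_error))
        else:
            p = 1.0
        rows.append(
            {"left": a, "right": b, "estimate": diff, "p": p}
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float | np.ndarray
    p: float | np.ndarray
    n: int
    method: str


def covariate_correlation(
    values,
    covariate,
    n_permutations: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> CorrelationResult:
    """Pearson R between per-session values and a covariate.

    ``method='permutation'`` shuffles the covariate (two-sided p on |R|);
    ``method='parametric'`` uses the t-distribution p.  ``values`` may be a
    1D scalar series or an (n_sessions x voxels) stack, in which case a
    voxelwise R map is returned with max-|R| FWE permutation p-values.
    """
    values = np.asarray(values, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = cov.shape[0]
    if n < 5:
        raise ValidationError("need >= 5 sessions with a covariate")
    if values.shape[0] != n:
        raise ValidationError("values and covariate lengths differ")
    if np.ptp(cov) == 0:
        raise ValidationError("constant covariate")

    flat = values.reshape(n, -1)
    c = cov - cov.mean()
    c_norm = np.sqrt((c**2).sum())
    Vc = flat - flat.mean(axis=0)
    v_norm = np.sqrt((Vc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (c @ Vc) / (c_norm * v_norm)
    r = np.where(np.isfinite(r), r, 0.0)

    if method == "parametric":
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_permutations)
        b = np.zeros(flat.shape[1])
        for i in range(n_permutations):
            cp = c[rng.permutation(n)]
            with np.errstate(invalid="ignore", divide="ignore"):
                rn = (cp @ Vc) / (c_norm * v_norm)
            rn = np.abs(np.where(np.isfinite(rn), rn, 0.0))
            b += rn >= np.abs(r) - 1e-12
            null_max[i] = rn.max()
        p = (b + 1) / (n_permutations + 1)
    else:
        raise ValidationError(f"unknown method '{method}'")

    if values.ndim == 1:
        return CorrelationResult(float(r[0]), float(np.atleast_1d(p)[0]), n, method)
    shape = values.shape[1:]
    return CorrelationResult(r.reshape(shape), np.asarray(p).reshape(shape), n, method)


@dataclass
class MedianSplitResult:
    median: float
    n_ties: int
    group_means: dict
    chi2: float
    df: int
    p: float
    tukey: pd.DataFrame


def median_split_compare(
    em_values, em_hours, hc_values
) -> MedianSplitResult:
    """Split meditators at their median practice hours and compare
    {HC, EM_low, EM_high} with a likelihood-ratio group test and
    Tukey-Kramer post hoc.  Ties at the median go to the lower group."""
    em_values = np.asarray(em_values, float)
    em_hours = np.asarray(em_hours, float)
    hc_values = np.asarray(hc_values, float)
    if em_values.shape != em_hours.shape:
        raise ValidationError("EM values and hours must align")
    if np.ptp(em_hours) == 0:
        raise ValidationError("degenerate split: all EM practice hours equal")
    med = float(np.median(em_hours))
    low = em_hours <= med
    n_ties = int((em_hours == med).sum())
    groups = {
        "HC": hc_values,
        "EM_low": em_values[low],
        "EM_high": em_values[~low],
    }
    if min(len(v) for v in groups.values()) < 2:
        raise ValidationError("each split group needs >= 2 subjects")

    long = pd.DataFrame(
        [
            {"group": g, "value": v}
            for g, vals in groups.items()
            for v in vals
        ]
    )
    full = ols("value ~ C(group)", long).fit()
    null = ols("value ~ 1", long).fit()
    N = len(long)
    rss_full = float(full.ssr)
    rss_null = float(null.ssr)
    chi2 = N * np.log(rss_null / rss_full) if rss_full > 0 else np.inf
    dof = 2
    p = float(stats.chi2.sf(chi2, dof))

    mse = rss_full / (N - 3)
    df_error = N - 3
    names = list(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        diff = float(np.mean(groups[b]) - np.mean(groups[a]))
        se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
        q = abs(diff) / se if se > 0 else np.inf
        rows.append(
            {
                "left": a,
                "right": b,
                "estimate": diff,
                "p": float(stats.studentized_range.sf(q, 3, df_error)),
            }
        )
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    return MedianSplitResult(
        med, n_ties, means, float(chi2), dof, p, pd.DataFrame(rows)
    )


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
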