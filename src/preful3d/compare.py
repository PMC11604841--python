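"""Regional and statistical comparison of VDP maps and values.

Includes the carina-based eight-region lung partition, Dice overlap with
anterior-posterior slab matching, Bland-Altman agreement, a random-intercept
linear mixed model with Satterthwaite degrees of freedom and the
Nakagawa-Schielzeth marginal R^2, and one-way ANOVA with Bonferroni-adjusted
pairwise comparisons.

Axis convention (package-wide): axis 0 runs right->left, axis 1
anterior->posterior, axis 2 inferior->superior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RegionPartition",
    "REGION_NAMES",
    "split_regions",
    "dice",
    "slab_match",
    "bland_altman",
    "lmm_correlation",
    "anova_bonferroni",
    "regional_vdp",
]

# label = 1 + 4*is_left + 2*is_inferior + 1*is_posterior
REGION_NAMES = {
    1: "right-superior-anterior",
    2: "right-superior-posterior",
    3: "right-inferior-anterior",
    4: "right-inferior-posterior",
    5: "left-superior-anterior",
    6: "left-superior-posterior",
    7: "left-inferior-anterior",
    8: "left-inferior-posterior",
}


@dataclass
class RegionPartition:
    labels: np.ndarray      # 0 outside mask, 1..8 inside
    carina_voxel: tuple
    names: dict = None

    def __post_init__(self):
        if self.names is None:
            self.names = dict(REGION_NAMES)


def split_regions(mask: np.ndarray, carina_voxel) -> RegionPartition:
    """Partition a lung mask into eight regions by the three planes through
    the carina: sagittal (left/right), transverse (superior/inferior) and
    coronal (anterior/posterior).  Voxels with x < carina_x are the right
    lung under the package axis convention."""
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    cx, cy, cz = (int(v) for v in carina_voxel)
    if not (0 <= cx < mask.shape[0] and 0 <= cy < mask.shape[1] and 0 <= cz < mask.shape[2]):
        raise ValueError("carina voxel outside the volume")
    xs, ys, zs = np.meshgrid(*[np.arange(n) for n in mask.shape], indexing="ij")
    is_left = xs >= cx
    is_inferior = zs < cz
    is_posterior = ys >= cy
    labels = np.where(mask, 1 + 4 * is_left + 2 * is_inferior + is_posterior, 0)
    empty = [REGION_NAMES[i] for i in range(1, 9) if not np.any(labels == i)]
    if empty:
        warnings.warn(f"empty lung regions: {', '.join(empty)}")
    return RegionPartition(labels=labels, carina_voxel=(cx, cy, cz))


def regional_vdp(defect_mask: np.ndarray, partition: RegionPartition):
    """Per-region VDP (percent) and voxel counts; region key 'global' included."""
    defect_mask = np.asarray(defect_mask, dtype=bool)
    out = {}
    lung = partition.labels > 0
    out["global"] = (100.0 * (defect_mask & lung).sum() / max(lung.sum(), 1), int(lung.sum()))
    for i, name in REGION_NAMES.items():
        region = partition.labels == i
        n = int(region.sum())
        vdp = 100.0 * (defect_mask & region).sum() / n if n else np.nan
        out[name] = (vdp, n)
    return out


def dice(a: np.ndarray, b: np.ndarray):
    """Dice similarity coefficient of two boolean volumes.  Two empty masks
    return (1.0, flagged=True)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0, True
    return 2.0 * int((a & b).sum()) / denom, False


def slab_match(map3d: np.ndarray, slab_vox: int, axis: int = 1) -> np.ndarray:
    """Non-overlapping mean pooling along the anterior-posterior axis,
    emulating thick-slab out-of-plane resolution.  Boolean inputs are
    pooled then re-binarized with the >= 0.5 tie rule.  The pooled value is
    broadcast back over its slab so shapes are preserved."""
    arr = np.asarray(map3d)
    was_bool = arr.dtype == bool
    arr = arr.astype(np.float64)
    n = arr.shape[axis]
    if n % slab_vox:
        warnings.warn(f"axis extent {n} not divisible by slab {slab_vox}; last slab truncated")
    out = np.empty_like(arr)
    for start in range(0, n, slab_vox):
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(start, min(start + slab_vox, n))
        sl = tuple(sl)
        out[sl] = arr[sl].mean(axis=axis, keepdims=True)
    if was_bool:
        return out >= 0.5
    return out


def bland_altman(x, y):
    """Bias and 1.96-SD limits of agreement of paired differences x - y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (REML) with Satterthwaite inference
# ---------------------------------------------------------------------------

def _gls_beta(x_mat, y, v_inv):
    xtvx = x_mat.T @ v_inv @ x_mat
    beta = np.linalg.solve(xtvx, x_mat.T @ v_inv @ y)
    return beta, xtvx


def _neg2_reml(log_lam, x_mat, y, zzt):
    n, p = x_mat.shape
    lam = np.exp(log_lam)
    v = np.eye(n) + lam * zzt
    v_inv = np.linalg.inv(v)
    beta, xtvx = _gls_beta(x_mat, y, v_inv)
    r = y - x_mat @ beta
    quad = float(r @ v_inv @ r)
    sig2 = max(quad / (n - p), 1e-12 * float(np.var(y)) + 1e-300)
    sign, logdet_v = np.linalg.slogdet(v)
    _, logdet_x = np.linalg.slogdet(xtvx)
    return logdet_v + logdet_x + (n - p) * np.log(sig2), sig2


def _neg2_reml_theta(theta, x_mat, y, zzt):
    """-2 REML log-likelihood (up to a constant) in (sigma_u^2, sigma_e^2)."""
    s2u, s2e = theta
    n, p = x_mat.shape
    v = s2e * np.eye(n) + s2u * zzt
    v_inv = np.linalg.inv(v)
    beta, xtvx = _gls_beta(x_mat, y, v_inv)
    r = y - x_mat @ beta
    _, logdet_v = np.linalg.slogdet(v)
    _, logdet_x = np.linalg.slogdet(xtvx)
    return logdet_v + logdet_x + float(r @ v_inv @ r)


def _satterthwaite_df(theta, x_mat, y, zzt, contrast):
    """Satterthwaite df for contrast' beta via the delta method on the REML
    variance-component covariance (numerical derivatives)."""
    n, p = x_mat.shape

    def var_contrast(th):
        s2u, s2e = th
        v = s2e * np.eye(n) + max(s2u, 0.0) * zzt
        v_inv = np.linalg.inv(v)
        xtvx = x_mat.T @ v_inv @ x_mat
        return float(contrast @ np.linalg.solve(xtvx, contrast))

    f0 = var_contrast(theta)
    h = np.maximum(1e-4 * np.abs(theta), 1e-8)
    grad = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        hi = var_contrast(theta + e)
        lo = var_contrast(np.maximum(theta - e, 0.0))
        step = (theta[i] + h[i]) - max(theta[i] - h[i], 0.0)
        grad[i] = (hi - lo) / step

    # observed information of the REML criterion (0.5 * hessian of -2ll)
    def f(th):
        return _neg2_reml_theta(np.maximum(th, 1e-12), x_mat, y, zzt)

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            hess[i, j] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov_theta = np.linalg.inv(0.5 * hess)
    except np.linalg.LinAlgError:
        return np.nan
    denom = float(grad @ cov_theta @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return np.nan
    return 2.0 * f0**2 / denom


def lmm_correlation(x, y, subject_ids):
    """Correlate paired values with a random-intercept mixed model.

    Fits ``y = b0 + b1*x + u_subject + eps`` by REML, reports the
    Nakagawa-Schielzeth marginal R^2 (from an ML refit of the variance
    components) and the Satterthwaite-approximated p-value of the slope.

    Returns a dict with keys ``slope, intercept, r2_marginal, p_value, df,
    sigma2_u, sigma2_e, singular``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    subject_ids = np.asarray(subject_ids)
    if x.size != y.size or x.size != subject_ids.size:
        raise ValueError("x, y, subject_ids must have equal length")
    subjects, z_idx = np.unique(subject_ids, return_inverse=True)
    if subjects.size < 3:
        raise ValueError("need at least three subjects")
    n = x.size
    x_mat = np.column_stack([np.ones(n), x])
    z_mat = np.zeros((n, subjects.size))
    z_mat[np.arange(n), z_idx] = 1.0
    zzt = z_mat @ z_mat.T

    res = optimize.minimize_scalar(
        lambda ll: _neg2_reml(ll, x_mat, y, zzt)[0],
        bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    log_lam = float(res.x)
    crit0, _ = _neg2_reml(-12.0, x_mat, y, zzt)
    crit_opt, sig2e = _neg2_reml(log_lam, x_mat, y, zzt)
    if crit0 <= crit_opt + 1e-10:  # boundary: no subject variance
        log_lam, singular = -np.inf, True
        lam = 0.0
        _, sig2e = _neg2_reml(-50.0, x_mat, y, zzt)
    else:
        lam = np.exp(log_lam)
        singular = lam < 1e-8
    sig2u = lam * sig2e
    sig2e = max(sig2e, 1e-12 * float(np.var(y)) + 1e-300)

    v = sig2e * np.eye(n) + sig2u * zzt
    v_inv = np.linalg.inv(v)
    beta, xtvx = _gls_beta(x_mat, y, v_inv)
    cov_beta = np.linalg.inv(xtvx)
    se_slope = float(np.sqrt(cov_beta[1, 1]))
    t_stat = float(beta[1] / se_slope) if se_slope > 0 else np.inf

    if singular:
        df = float(n - 2)
    else:
        df = _satterthwaite_df(np.array([sig2u, sig2e]), x_mat, y, zzt,
                               np.array([0.0, 1.0]))
        if not np.isfinite(df) or df < 1.0:
            df = float(n - 2)
    p_value = float(2.0 * stats.t.sf(abs(t_stat), df))

    # ML refit of the variance components for the marginal R^2 so that the
    # single-observation-per-subject case reduces exactly to the OLS R^2
    def neg2_ml(theta):
        s2u, s2e = np.maximum(theta, 1e-12)
        v_ml = s2e * np.eye(n) + s2u * zzt
        v_ml_inv = np.linalg.inv(v_ml)
        b, _ = _gls_beta(x_mat, y, v_ml_inv)
        r = y - x_mat @ b
        _, logdet = np.linalg.slogdet(v_ml)
        return logdet + float(r @ v_ml_inv @ r)

    var_y = max(np.var(y), 1e-30)
    ml = optimize.minimize(neg2_ml, x0=np.array([max(sig2u, 1e-6 * var_y), sig2e]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-10 * var_y, "fatol": 1e-12})
    s2u_ml, s2e_ml = np.maximum(ml.x, 0.0)
    s2e_ml = max(s2e_ml, 1e-12 * var_y + 1e-300)
    v_ml_inv = np.linalg.inv(s2e_ml * np.eye(n) + s2u_ml * zzt)
    beta_ml, _ = _gls_beta(x_mat, y, v_ml_inv)
    var_fixed = float(np.var(x_mat @ beta_ml))  # population variance
    r2_marginal = var_fixed / (var_fixed + s2u_ml + s2e_ml)

    if singular:
        warnings.warn("singular fit: subject variance estimated at zero; "
                      "model reduces to ordinary regression")
    return {
        "slope": float(beta[1]),
        "intercept": float(beta[0]),
        "r2_marginal": float(r2_marginal),
        "p_value": p_value,
        "df": float(df),
        "sigma2_u": float(sig2u),
        "sigma2_e": float(sig2e),
        "singular": bool(singular),
    }


def anova_bonferroni(groups: dict):
    """One-way ANOVA plus pairwise two-sample t-tests with Bonferroni
    adjustment (p multiplied by the number of comparisons, clipped at 1).

    ``groups`` maps group name -> 1D sample.  Returns (anova_p, {pair: p}).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[k], dtype=np.float64) for k in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least two values")
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in all groups")
    _, anova_p = stats.f_oneway(*samples)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    pairwise = {}
    for i, j in pairs:
        if np.var(samples[i]) == 0 and np.var(samples[j]) == 0:
            p_raw = 0.0 if samples[i].mean() != samples[j].mean() else 1.0
        else:
            _, p_raw = stats.ttest_ind(samples[i], samples[j])
        pairwise[f"{names[i]} vs {names[j]}"] = float(min(1.0, len(pairs) * p_raw))
    return float(anova_p), pairwise
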