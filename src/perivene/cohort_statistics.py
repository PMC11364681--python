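"""Cohort statistics: ICV correction, normality-gated association and group
tests, and ICC(2,1) reliability on Ln(x+1)-transformed volumes.

Gating follows the normality rule: Pearson / t test when the Kolmogorov-
Smirnov check (Lilliefors-corrected, since the normal's parameters are
estimated from the sample) passes for every variable involved, otherwise
Spearman / Mann-Whitney U.  All tests are two-sided at alpha = 0.05 with no
multiple-testing correction.  Ties are handled by average ranks throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "ICCResult",
    "correct_for_icv",
    "ks_normality",
    "correlate",
    "compare_groups",
    "icc_2_1",
    "run_cohort_analysis",
]

ALPHA = 0.05

# Monte-Carlo null distributions for the Lilliefors statistic, cached per
# sample size.  The internal seed is fixed so p-values are reproducible.
_LILLIEFORS_SEED = 20240426
_LILLIEFORS_NSIM = 2000
_lilliefors_cache: dict[tuple[int, int], np.ndarray] = {}


@dataclass
class StatResult:
    """One test outcome: the method actually dispatched, its estimate
    (r, U, t or D), the two-sided p-value and sample size(s)."""

    method: str
    estimate: float
    p_value: float
    n: int
    n2: int | None = None
    normal: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.method in ("pearson", "spearman") and not -1.0000001 <= self.estimate <= 1.0000001:
            raise ValueError(f"correlation estimate out of range: {self.estimate}")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "estimate": float(self.estimate),
            "p_value": float(self.p_value),
            "n": int(self.n),
        }
        if self.n2 is not None:
            d["n2"] = int(self.n2)
        if self.normal is not None:
            d["normal"] = bool(self.normal)
        return d


@dataclass
class ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""

    icc: float
    ci_low: float
    ci_high: float
    transform: str
    n: int
    k: int
    msr: float
    msc: float
    mse: float

    def to_dict(self) -> dict:
        return {
            "icc": float(self.icc),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "transform": self.transform,
            "n": int(self.n),
            "k": int(self.k),
            "msr": float(self.msr),
            "msc": float(self.msc),
            "mse": float(self.mse),
        }


def correct_for_icv(volume_mm3, icv_cm3):
    """Corrected volume in mm^3 cm^-3: measured volume divided by ICV."""
    icv = np.asarray(icv_cm3, dtype=float)
    if np.any(icv <= 0):
        raise ValueError("ICV must be > 0")
    out = np.asarray(volume_mm3, dtype=float) / icv
    return float(out) if out.ndim == 0 else out


def _lilliefors_null(n: int, n_sim: int = _LILLIEFORS_NSIM) -> np.ndarray:
    key = (n, n_sim)
    if key not in _lilliefors_cache:
        rng = np.random.default_rng(_LILLIEFORS_SEED)
        i = np.arange(1, n + 1)
        out = np.empty(n_sim)
        pos = 0
        block = max(1, int(5_000_000 // n))  # bound memory for large samples
        while pos < n_sim:
            b = min(block, n_sim - pos)
            x = rng.standard_normal((b, n))
            x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
            x.sort(axis=1)
            cdf = stats.norm.cdf(x)
            d_plus = (i / n - cdf).max(axis=1)
            d_minus = (cdf - (i - 1) / n).max(axis=1)
            out[pos : pos + b] = np.maximum(d_plus, d_minus)
            pos += b
        _lilliefors_cache[key] = out
    return _lilliefors_cache[key]


def ks_normality(x, alpha: float = ALPHA) -> StatResult:
    """One-sample KS test against a normal with the sample's own mean and SD,
    with the p-value taken from a seeded Monte-Carlo (Lilliefors) null.

    The sample is classified normal iff p >= alpha.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1D sample")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample has zero variance")
    n = x.size
    z = np.sort((x - x.mean()) / sd)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d = max((i / n - cdf).max(), (cdf - (i - 1) / n).max())
    null = _lilliefors_null(n)
    p = (1.0 + np.count_nonzero(null >= d)) / (null.size + 1.0)
    return StatResult(method="ks", estimate=float(d), p_value=float(p), n=n, normal=bool(p >= alpha))


def _is_normal(x) -> bool:
    try:
        return bool(ks_normality(x).normal)
    except ValueError:
        return False


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 10):
    enumerate every permutation of one rank vector."""
    n = rx.size
    sx = rx - rx.mean()
    denom = math.sqrt(float((sx**2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    total = math.factorial(n)
    count = 0
    chunk = 200_000
    it = itertools.permutations(ry)
    thresh = abs(r_obs) - 1e-12
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        r_perm = (block - ry.mean()) @ sx / denom
        count += int(np.count_nonzero(np.abs(r_perm) >= thresh))
    return count / total


def correlate(x, y, method: str = "auto") -> StatResult:
    """Association between two samples.

    ``auto`` dispatches Pearson only when BOTH variables pass the KS
    normality check, otherwise Spearman.  Spearman uses average ranks for
    ties; its two-sided p comes from the t-approximation for n > 10 and from
    exact permutation for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D samples of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")

    if method == "auto":
        method = "pearson" if (_is_normal(x) and _is_normal(y)) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return StatResult(method="pearson", estimate=float(r), p_value=float(p), n=n)
    if method != "spearman":
        raise ValueError("method must be 'pearson', 'spearman' or 'auto'")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _spearman_exact_p(rx, ry, r)
    else:
        rr = min(max(r, -1.0), 1.0)
        if abs(rr) == 1.0:
            p = 0.0
        else:
            t = rr * math.sqrt((n - 2) / (1.0 - rr**2))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return StatResult(method="spearman", estimate=r, p_value=float(min(p, 1.0)), n=n)


def compare_groups(x, y, method: str = "auto") -> StatResult:
    """Two-group comparison.

    ``auto`` dispatches Welch's t test only when BOTH groups pass the KS
    normality check, otherwise the Mann-Whitney U test.  U is exact when
    min(n, m) <= 8 and the pooled data is tie-free; otherwise the normal
    approximation with continuity and tie correction is used.  The reported
    U is the statistic of the first group (swapping groups maps U to nm - U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("groups must be 1D samples")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("groups contain non-finite values")

    if method == "auto":
        method = "t" if (_is_normal(x) and _is_normal(y)) else "mann_whitney"
    if method == "t":
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return StatResult(method="t", estimate=float(t), p_value=float(p), n=x.size, n2=y.size)
    if method != "mann_whitney":
        raise ValueError("method must be 't', 'mann_whitney' or 'auto'")

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    mode = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=mode, use_continuity=True)
    return StatResult(method="mann_whitney", estimate=float(u), p_value=float(p), n=x.size, n2=y.size)


def icc_2_1(measurements, transform: str = "none", alpha: float = ALPHA) -> ICCResult:
    """ICC(2,1) with a 95% F-based confidence interval.

    Two-way random effects, absolute agreement, single measures:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` on the (optionally
    Ln(x+1)-transformed) complete n x k matrix.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected an n_subjects x k_raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix is incomplete or contains non-finite values")
    if transform == "ln1p":
        if np.any(m < 0):
            raise ValueError("Ln(x+1) transform requires all values >= 0")
        y = np.log1p(m)
    elif transform == "none":
        y = m
    else:
        raise ValueError("transform must be 'none' or 'ln1p'")

    grand = y.mean()
    rows = y.mean(axis=1)
    cols = y.mean(axis=0)
    msr = k * float(((rows - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((cols - grand) ** 2).sum()) / (k - 1)
    mse = float(((y - rows[:, None] - cols[None, :] + grand) ** 2).sum()) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise ValueError("matrix has no variance: ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (Satterthwaite dof); guard the MSE=0 limit numerically
    mse_ci = max(mse, 1e-12 * max(msr, msc, 1.0))
    fj = msc / mse_ci
    a = k * icc * fj + n * (1.0 + (k - 1) * icc) - k * icc
    vn = (k - 1) * (n - 1) * a**2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1.0 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd if vd > 0 else (k - 1) * (n - 1)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (msr - f1 * mse_ci) / (f1 * (k * msc + (k * n - k - n) * mse_ci) + n * msr)
    ub = n * (f2 * msr - mse_ci) / (k * msc + (k * n - k - n) * mse_ci + n * f2 * msr)
    lb = min(lb, icc)
    ub = min(max(ub, icc), 1.0)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lb),
        ci_high=float(ub),
        transform=transform,
        n=n,
        k=k,
        msr=msr,
        msc=msc,
        mse=mse,
    )


_REQUIRED_COLUMNS = ("age", "sex", "dv_volume", "psd_volume", "icv")


def run_cohort_analysis(cohort: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """The full per-cohort analysis battery as a machine-readable report.

    For each structure (dv, psd), corrected and uncorrected for ICV:
    KS normality, age association (auto-gated correlation), sex comparison
    (auto-gated group test) and median/IQR; plus the cross-correlation
    between the two corrected volumes.  Significance is flagged at
    p < alpha.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if np.any(cohort["icv"].to_numpy(dtype=float) <= 0):
        raise ValueError("ICV must be > 0 for every subject")
    for col in ("dv_volume", "psd_volume"):
        if np.any(cohort[col].to_numpy(dtype=float) < 0):
            raise ValueError(f"{col} must be >= 0")

    age = cohort["age"].to_numpy(dtype=float)
    male = cohort["sex"].astype(str).str.upper().str.startswith("M").to_numpy()
    icv = cohort["icv"].to_numpy(dtype=float)

    report: dict = {"n": int(len(cohort)), "alpha": alpha, "analyses": {}}
    report["age"] = {"ks": ks_normality(age).to_dict()}

    corrected_values = {}
    for struct, col in (("dv", "dv_volume"), ("psd", "psd_volume")):
        raw = cohort[col].to_numpy(dtype=float)
        for corrected in (True, False):
            vals = correct_for_icv(raw, icv) if corrected else raw
            if corrected:
                corrected_values[struct] = vals
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            age_assoc = correlate(age, vals, method="auto")
            sex_cmp = compare_groups(vals[male], vals[~male], method="auto")
            key = f"{struct}_{'corrected' if corrected else 'uncorrected'}"
            report["analyses"][key] = {
                "n": int(vals.size),
                "median": float(med),
                "iqr": [float(q25), float(q75)],
                "units": "mm3/cm3" if corrected else "mm3",
                "ks": ks_normality(vals).to_dict(),
                "age_association": age_assoc.to_dict(),
                "sex_comparison": sex_cmp.to_dict(),
                "age_significant": bool(age_assoc.p_value < alpha),
                "sex_significant": bool(sex_cmp.p_value < alpha),
            }

    cross = correlate(corrected_values["dv"], corrected_values["psd"], method="auto")
    report["cross_correlation"] = {
        **cross.to_dict(),
        "significant": bool(cross.p_value < alpha),
    }
    return report
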