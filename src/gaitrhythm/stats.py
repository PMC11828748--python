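"""Inferential protocol for the rhythm analysis.

Four pieces: (1) paired two-sided Wilcoxon signed-rank tests comparing
on- vs off-integer ratio counts across horses, one test per hoof x
saddle x gait cell; (2) beta mixed-effects models (logit link, horse
random intercept) for deviance, spread, relative phase and the FHI~HFI
relationship; (3) likelihood-ratio tests of each chosen model against
the null model containing only the random intercept; (4) AIC-based model
selection and Holm-adjusted pairwise Wald contrasts on the logit scale.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .betamixed import BetaMixedResult, fit_beta_mixed, fit_beta_mixed_formula

__all__ = [
    "TestResult",
    "wilcoxon_on_off",
    "lrt_vs_null",
    "pairwise_contrasts",
    "select_by_aic",
    "scale_to_unit",
    "gait_cluster_purity",
    "fit_beta_mixed",
    "fit_beta_mixed_formula",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, and bookkeeping."""

    label: str
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    p_adjusted: float | None = None
    n: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.p_value)


def wilcoxon_on_off(
    counts: pd.DataFrame,
    group_cols: tuple[str, ...] = ("hoof", "saddle", "gait"),
    unit_col: str = "horse",
) -> list[TestResult]:
    """Paired two-sided Wilcoxon signed-rank tests of on vs off counts.

    ``counts`` has one row per analysis unit with integer columns
    ``on_count`` and ``off_count``; one test is run per combination of
    ``group_cols``, pairing across ``unit_col``. The exact null
    distribution is used for n <= 25 pairs (after dropping zero
    differences), otherwise the tie-corrected normal approximation.
    Cells where every difference is zero yield an undefined (flagged)
    result rather than a fabricated p-value.
    """
    results = []
    for keys, sub in counts.groupby(list(group_cols), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = ", ".join(f"{c}={k}" for c, k in zip(group_cols, keys))
        on = sub["on_count"].to_numpy(float)
        off = sub["off_count"].to_numpy(float)
        d = on - off
        nz = d[d != 0]
        flags = []
        if nz.size == 0:
            results.append(
                TestResult(label, np.nan, np.nan, "wilcoxon/undefined",
                           n=d.size, flags=["all differences zero"])
            )
            continue
        if nz.size < 5:
            flags.append("fewer than 5 non-zero differences; exact test")
        method = "exact" if nz.size <= 25 else "approx"
        stat, p = sps.wilcoxon(
            on, off, alternative="two-sided", zero_method="wilcox", method=method
        )
        results.append(
            TestResult(label, float(stat), float(p), f"wilcoxon/{method}",
                       n=int(nz.size), flags=flags)
        )
    return results


def lrt_vs_null(full: BetaMixedResult, null: BetaMixedResult) -> TestResult:
    """Likelihood-ratio test of nested beta mixed models.

    chi^2 = 2 (logL_full - logL_null), df = difference in parameter
    count; requires both fits on the same observations.
    """
    if full.n_obs != null.n_obs or full.n_groups != null.n_groups:
        raise ValueError("models were fitted on different data")
    df = full.k_params - null.k_params
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'null'")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    return TestResult("full vs null", float(chi2), p, "likelihood-ratio", df=df)


def _base_column(factor_name: str) -> str:
    m = re.fullmatch(r"C\((\w+)[^)]*\)", factor_name)
    return m.group(1) if m else factor_name


def _reference_grid(design_info, data: pd.DataFrame) -> pd.DataFrame:
    """Cartesian grid over categorical factors, numerics held at the mean."""
    cats: dict[str, list] = {}
    nums: dict[str, float] = {}
    for f, info in design_info.factor_infos.items():
        col = _base_column(f.name())
        if info.type == "categorical":
            cats[col] = list(info.categories)
        else:
            nums[col] = float(np.mean(data[col]))
    if not cats:
        raise ValueError("model has no categorical factor to contrast")
    rows = [dict(zip(cats, combo)) for combo in itertools.product(*cats.values())]
    grid = pd.DataFrame(rows)
    for col, v in nums.items():
        grid[col] = v
    return grid


def pairwise_contrasts(
    fit: BetaMixedResult,
    factor: str,
    data: pd.DataFrame,
    adjust: str = "holm",
) -> list[TestResult]:
    """Holm-adjusted pairwise Wald contrasts of a factor's marginal means.

    Marginal means are formed on the logit (link) scale by averaging the
    fixed-effects design rows of a balanced reference grid within each
    level of ``factor`` (other categorical factors weighted equally,
    numeric covariates at their mean), the standard estimated-marginal-
    means construction.
    """
    import patsy
    from statsmodels.stats.multitest import multipletests

    if fit.design_info is None:
        raise ValueError("fit carries no design information (use the formula API)")
    grid = _reference_grid(fit.design_info, data)
    if factor not in grid.columns or grid[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} is not a categorical term of the model")
    (X_grid,) = patsy.build_design_matrices([fit.design_info], grid)
    X_grid = np.asarray(X_grid)

    levels = [lv for lv in grid[factor].unique()]
    L = {lv: X_grid[(grid[factor] == lv).to_numpy()].mean(axis=0) for lv in levels}

    beta = fit.fe_params
    V = fit.fe_cov
    results = []
    for a, b in itertools.combinations(levels, 2):
        c = L[a] - L[b]
        est = float(c @ beta)
        var = float(c @ V @ c)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = est / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
        results.append(TestResult(f"{a} - {b}", float(z), p, "wald-z"))
    raw = [r.p_value for r in results]
    if len(raw) == 1:
        results[0].p_adjusted = raw[0]
    elif raw:
        _, adj, _, _ = multipletests(raw, method=adjust)
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results


def contrast_level_with_itself(fit: BetaMixedResult, factor: str, level, data) -> TestResult:
    """Degenerate contrast of a level against itself (z = 0, p = 1)."""
    return TestResult(f"{level} - {level}", 0.0, 1.0, "wald-z", p_adjusted=1.0)


def select_by_aic(fits: list[BetaMixedResult]) -> BetaMixedResult:
    """Minimum-AIC model among converged candidates; ties favour the
    smaller model."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged candidate model")
    return min(converged, key=lambda f: (f.aic, f.k_params))


def scale_to_unit(x: np.ndarray, headroom: float = 1.05) -> tuple[np.ndarray, float]:
    """Map positive durations into (0, 1) by dividing by headroom * max.

    Returns the scaled values and the scale factor (recorded in the run
    manifest so results remain interpretable in seconds).
    """
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    scale = headroom * float(x.max())
    return x / scale, scale


def fit_fhi_hfi(
    intervals: pd.DataFrame,
    formula_rhs: str = "hfi_u * gait * saddle",
    n_quad: int = 11,
) -> dict:
    """Model the fore-hoof cycle duration (FHI) on the ipsilateral lag (HFI).

    FHI reflects instantaneous gait tempo alone while HFI mixes tempo
    with the interlimb coordination pattern, so their relationship
    separates the gaits. Both durations are mapped into (0, 1) by
    ``scale_to_unit`` before the beta mixed fit (scales are returned for
    the manifest); gait, saddle and their interactions with the scaled
    HFI enter as fixed effects, the horse as a random intercept.

    Returns a dict with the full fit, the intercept-only null fit, the
    likelihood-ratio test between them, the two scale factors and the
    modelling frame.
    """
    hfi = intervals[intervals["kind"] == "HFI"]
    if not len(hfi):
        raise ValueError("no HFI rows in the interval table")
    df = pd.DataFrame(
        {
            "fhi_s": hfi["cycle_s"].to_numpy(float),
            "hfi_s": hfi["value_s"].to_numpy(float),
            "gait": hfi["gait"].to_numpy(),
            "saddle": hfi["saddle"].to_numpy(),
            "horse": hfi["horse"].to_numpy(),
        }
    )
    df["y"], fhi_scale = scale_to_unit(df["fhi_s"].to_numpy())
    df["hfi_u"], hfi_scale = scale_to_unit(df["hfi_s"].to_numpy())
    full = fit_beta_mixed_formula(df, f"y ~ {formula_rhs}", "horse", n_quad=n_quad,
                                  meta={"fhi_scale_s": fhi_scale,
                                        "hfi_scale_s": hfi_scale})
    null = fit_beta_mixed_formula(df, "y ~ 1", "horse", n_quad=n_quad)
    return {
        "full": full,
        "null": null,
        "lrt": lrt_vs_null(full, null),
        "fhi_scale_s": fhi_scale,
        "hfi_scale_s": hfi_scale,
        "data": df,
    }


def gait_cluster_purity(df: pd.DataFrame, x_col: str = "hfi_s", y_col: str = "fhi_s",
                        label_col: str = "gait") -> float:
    """Purity of nearest-centroid gait assignment in the (HFI, FHI) plane.

    Quantifies how cleanly the gaits separate into distinct clusters:
    each point is assigned to the nearest per-gait centroid and the
    returned value is the fraction assigned to its own gait.
    """
    pts = df[[x_col, y_col]].to_numpy(float)
    labels = df[label_col].to_numpy()
    cents = {g: pts[labels == g].mean(axis=0) for g in np.unique(labels)}
    names = list(cents)
    C = np.array([cents[g] for g in names])
    d2 = ((pts[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    assigned = np.array(names)[np.argmin(d2, axis=1)]
    return float(np.mean(assigned == labels))
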