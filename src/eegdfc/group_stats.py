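"""Nonparametric group statistics on the cumulant table.

Patient-vs-control contrasts use the two-sided Mann-Whitney U test (exact
null distribution for small samples without ties, tie-corrected normal
approximation otherwise), Benjamini-Hochberg FDR correction within each
contrast's family of band x cumulant tests, and the rank-biserial-style
effect size r = |Z| / sqrt(n1 + n2).  A Pearson screen correlates each
band x cumulant metric with a per-subject dose covariate (e.g.
chlorpromazine-equivalent antipsychotic dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .as_metrics import CUMULANT_NAMES

ALPHA = 0.05
TENDENCY = 0.10


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for ``sample_a`` (U counts pairs a > b,
    ties half).  Exact p when n1 + n2 <= 20 and no ties; tie-corrected
    normal approximation otherwise."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _u_null_moments(n1: int, n2: int, pooled=None) -> tuple[float, float]:
    """Mean and SD of U under the null, with tie correction from pooled data."""
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_term = 0.0
    if pooled is not None:
        _, counts = np.unique(np.asarray(pooled, dtype=float), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return mu, float(np.sqrt(var))


def effect_size_r(U: float, n1: int, n2: int, pooled=None) -> float:
    """r = |Z| / sqrt(n1 + n2) with Z the (tie-corrected) normal
    approximation of U; the standard Mann-Whitney effect size."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    mu, sd = _u_null_moments(n1, n2, pooled)
    if sd == 0.0:
        raise ValueError("zero variance: all observations tied")
    return float(abs(U - mu) / sd / np.sqrt(n1 + n2))


def fdr_correct(p_values, family=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, within each family.

    ``family`` is an optional per-test label array; adjustment is applied
    separately inside each label (default: one family for all tests).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if family is None:
        fam = np.zeros(len(p), dtype=int)
    else:
        fam = np.asarray(family)
        if len(fam) != len(p):
            raise ValueError("family labels must match p-values in length")
    for label in np.unique(fam):
        idx = fam == label
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


@dataclass
class CovariateScreenResult:
    band: str
    cumulant: str
    rho: float
    p: float


def pearson_screen(metric_table: pd.DataFrame, covariate,
                   metrics=CUMULANT_NAMES) -> pd.DataFrame:
    """Pearson correlation of each band x cumulant metric with a dose-like
    covariate; p-values from the t-distribution of the correlation.

    ``covariate`` is either a column name of ``metric_table`` or a mapping
    ``subject_id -> value``.  Needs >= 3 complete subjects per cell.
    """
    table = metric_table.copy()
    if isinstance(covariate, str):
        if covariate not in table.columns:
            raise ValueError(f"covariate column {covariate!r} not in table")
        table["_dose"] = table[covariate]
    else:
        table["_dose"] = table["subject_id"].map(dict(covariate))
    rows = []
    for band, sub in table.groupby("band", sort=False):
        for name in metrics:
            ok = sub[[name, "_dose"]].dropna()
            if len(ok) < 3:
                raise ValueError(f"fewer than 3 subjects for {band}/{name}")
            x, y = ok[name].to_numpy(), ok["_dose"].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(f"zero-variance metric or covariate for {band}/{name}")
            rho, p = _st.pearsonr(x, y)
            rows.append({"band": band, "cumulant": name,
                         "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)


def _significance_label(p: float, alpha: float = ALPHA,
                        tendency: float = TENDENCY) -> str:
    if p < alpha:
        return "significant"
    if p < tendency:
        return "tendency"
    return ""


def run_group_analysis(
    cumulant_table: pd.DataFrame,
    control: str = "HC",
    fdr_family: str = "per-contrast",
    alpha: float = ALPHA,
    dose_column: str | None = "chlorpromazine_equivalent",
    metrics=CUMULANT_NAMES,
) -> dict:
    """All patient-vs-control comparisons per band per cumulant, FDR within
    the declared family, effect sizes attached; plus a dose screen per
    patient group when the covariate is present.

    ``fdr_family``: "per-contrast" (one family of band x cumulant tests per
    group pair, the default) or "global" (all contrasts jointly).
    """
    groups = list(dict.fromkeys(cumulant_table["group"]))
    if control not in groups:
        raise ValueError(f"control group {control!r} missing from table")
    patients = [g for g in groups if g != control]
    if not patients:
        raise ValueError("need at least one non-control group")
    if fdr_family not in ("per-contrast", "global"):
        raise ValueError("fdr_family must be 'per-contrast' or 'global'")

    bands = list(dict.fromkeys(cumulant_table["band"]))
    rows = []
    for patient in patients:
        for band in bands:
            sub = cumulant_table[cumulant_table["band"] == band]
            a = sub[sub["group"] == patient]
            b = sub[sub["group"] == control]
            for name in metrics:
                x = a[name].dropna().to_numpy()
                y = b[name].dropna().to_numpy()
                U, p = mann_whitney_u(x, y)
                r = effect_size_r(U, len(x), len(y), pooled=np.concatenate([x, y]))
                rows.append({
                    "contrast": f"{patient} vs {control}", "band": band,
                    "cumulant": name, "n1": len(x), "n2": len(y),
                    "U": U, "p_raw": p, "r": r,
                })
    comparisons = pd.DataFrame(rows)
    fam = comparisons["contrast"].to_numpy() if fdr_family == "per-contrast" else None
    comparisons["p_fdr"] = fdr_correct(comparisons["p_raw"].to_numpy(), family=fam)
    comparisons["significance"] = [
        _significance_label(p, alpha) for p in comparisons["p_fdr"]
    ]

    screens: dict[str, pd.DataFrame] = {}
    if dose_column is not None and dose_column in cumulant_table.columns:
        for patient in patients:
            sub = cumulant_table[cumulant_table["group"] == patient]
            n_dosed = sub.dropna(subset=[dose_column])["subject_id"].nunique()
            if n_dosed >= 3:
                screens[patient] = pearson_screen(sub, dose_column, metrics)
    return {
        "comparisons": comparisons,
        "covariate_screens": screens,
        "fdr_family": fdr_family,
        "alpha": alpha,
    }
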