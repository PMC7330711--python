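"""Group comparison and symptom-correlation statistics.

Edgewise community edge counts are compared between groups with the
classical pooled-variance (Student) two-sample t-test, two-sided, one test
per (band x measure) with NO multiple-comparison correction by default —
significance is flagged at the 5% and 1% levels.  An opt-in
Benjamini-Hochberg correction is available but goes beyond the default
analysis.  Associations between graph indices and clinical scale scores
(BDI-II, HAMD-17, ASRM, YMRS) are assessed with Spearman rank correlations
within the patient group.

Sign convention: ``t`` is computed as (group1 - group2) with group order
(HC, BD), so a *negative* t means the patient mean is larger.  The opposite
orientation is carried alongside as ``t_bd_minus_hc`` to avoid ambiguity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ttest_ind_pooled",
    "ttest_from_summary",
    "edgewise_group_comparison",
    "spearman",
    "symptom_correlations",
    "benjamini_hochberg",
]


def ttest_ind_pooled(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) independent-samples t-test.

    Returns ``(t, p)`` with ``df = n_a + n_b - 2``.  Raises on samples of
    size < 2, non-finite values, or zero pooled variance (t undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 observations per group, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def ttest_from_summary(m1: float, sd1: float, n1: int,
                       m2: float, sd2: float, n2: int) -> float:
    """Pooled-variance t from printed summary statistics (mean, SD, n).

    ``t = (m1 - m2) / sqrt(s_p^2 (1/n1 + 1/n2))`` with
    ``s_p^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)``.
    Lets published group-comparison tables be recomputed without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            return 0.0
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(res.statistic)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Raises on constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _counts_wide(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot long counts (subject_id, band, measure, count) to wide."""
    required = {"subject_id", "band", "measure", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return counts.pivot_table(
        index="subject_id", columns=["band", "measure"], values="count"
    )


def edgewise_group_comparison(
    counts: pd.DataFrame,
    groups: "pd.Series | dict",
    alpha_primary: float = 0.01,
    alpha_secondary: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-(band, measure) pooled t-tests of edge counts, HC vs BD.

    ``counts`` is long format with columns
    ``subject_id  band  measure  count``; ``groups`` maps subject_id to
    ``"HC"``/``"BD"``.  Returns one row per band x measure with columns
    ``band measure t t_bd_minus_hc p sig05 sig01`` (plus ``p_fdr`` when
    ``fdr=True``).  Measures constant across all subjects (zero pooled
    variance) get t=NaN, p=NaN and are never flagged.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    wide = _counts_wide(counts)
    unknown = set(wide.index) - set(groups.index)
    if unknown:
        raise ValueError(f"subjects without a group label: {sorted(unknown)}")
    g = groups.loc[wide.index]
    for name in ("HC", "BD"):
        if (g == name).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {name}")
    hc = wide.loc[g[g == "HC"].index].to_numpy(dtype=float)
    bd = wide.loc[g[g == "BD"].index].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant-count measures trigger scipy's precision-loss warning;
        # they are reported as NaN below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(hc, bd, equal_var=True, axis=0)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (hc.var(axis=0, ddof=1) == 0) & (bd.var(axis=0, ddof=1) == 0)
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    out = pd.DataFrame(
        {
            "band": [b for b, _ in wide.columns],
            "measure": [m for _, m in wide.columns],
            "t": t,
            "t_bd_minus_hc": -t,
            "p": p,
        }
    )
    out["sig05"] = out["p"] < alpha_secondary
    out["sig01"] = out["p"] < alpha_primary
    if fdr:
        out["p_fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = sps.false_discovery_control(p[ok], method="bh")
    return out


def symptom_correlations(
    counts: pd.DataFrame,
    scores: pd.DataFrame,
    selected_measures: "list[tuple[str, str]] | None" = None,
    scales: tuple[str, ...] = ("bdi", "hamd", "asrm", "ymrs"),
    group: str = "BD",
) -> pd.DataFrame:
    """Spearman correlations of graph indices with clinical scores.

    Restricted to the patient group, mirroring the within-patient analysis.
    ``counts`` is the long count table; ``scores`` has columns
    ``subject_id group`` plus one column per scale.  ``selected_measures``
    is a list of (band, measure) pairs — typically those significant in the
    group comparison; all measures when omitted.  Returns columns
    ``band measure scale rho p n``.  A constant score vector makes the
    correlation undefined and raises; a constant measure is reported with
    NaN rho (common at extreme densities where a count saturates).
    """
    wide = _counts_wide(counts)
    sc = scores.set_index("subject_id") if "subject_id" in scores.columns else scores
    subj = [s for s in wide.index if s in sc.index and sc.loc[s, "group"] == group]
    if len(subj) < 3:
        raise ValueError(f"need >= 3 {group} subjects with scores, got {len(subj)}")
    pairs = selected_measures if selected_measures is not None else list(wide.columns)
    rows = []
    for band, measure in pairs:
        x_all = wide.loc[subj, (band, measure)].to_numpy(dtype=float)
        for scale in scales:
            if scale not in sc.columns:
                continue
            y_all = sc.loc[subj, scale].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            if ok.sum() < 3:
                rows.append((band, measure, scale, np.nan, np.nan, int(ok.sum())))
                continue
            if np.unique(y_all[ok]).size < 2:
                raise ValueError(
                    f"score vector {scale!r} is constant over the {group} group: "
                    "Spearman correlation undefined"
                )
            if np.unique(x_all[ok]).size < 2:
                rows.append((band, measure, scale, np.nan, np.nan, int(ok.sum())))
                continue
            rho, p = spearman(x_all[ok], y_all[ok])
            rows.append((band, measure, scale, rho, p, int(ok.sum())))
    return pd.DataFrame(rows, columns=["band", "measure", "scale", "rho", "p", "n"])
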