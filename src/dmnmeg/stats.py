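"""Nonparametric group statistics for power and connectivity measures.

Relative spectral power and AEC-c-derived measures are bounded in [0, 1]
and typically non-normal, so group comparisons use the rank-based
Kruskal-Wallis test (with midrank tie correction and the chi-square
approximation for p). Multiple comparisons across the ROI x band grid are
corrected with the Benjamini-Hochberg step-up false-discovery-rate
procedure, applied within each (measure, contrast) family. The cohort
demographics comparison uses the Pearson chi-square on a 2x2 table
without continuity correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: The two planned pairwise contrasts: seizure vs between-seizure data,
#: and between-seizure data vs healthy controls.
DEFAULT_CONTRASTS = (("ictal", "interictal"), ("interictal", "control"))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p for two or more samples.

    Accepts the samples as separate arguments or as a single iterable of
    samples. Fully tied data (every observation identical) returns
    H = 0, p = 1 rather than an error.
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for k, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {k} is empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = spstats.kruskal(*arrays)
    return float(h), float(p)


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns ``(q_values, reject)`` where ``q_i = min_{j >= rank(i)}
    m * p_(j) / j`` capped at 1, and ``reject`` flags q < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all table margins must be positive")
    res = spstats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# condition comparisons over the ROI x band grid


def _cell_groups(sub: pd.DataFrame, conditions: list[str]) -> list[np.ndarray] | None:
    groups = []
    for cond in conditions:
        vals = sub.loc[sub["condition"] == cond, "value"].to_numpy()
        if vals.size < 2:
            return None
        groups.append(vals)
    return groups


def compare_conditions(
    measures: pd.DataFrame,
    contrasts=DEFAULT_CONTRASTS,
    alpha: float = 0.05,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Omnibus and pairwise Kruskal-Wallis tests with per-family FDR.

    Parameters
    ----------
    measures
        Long-format table with columns ``subject``, ``condition``,
        ``roi``, ``band``, ``measure``, ``value`` (one row per segment,
        or per subject after averaging).
    contrasts
        Pairwise condition contrasts tested in addition to the omnibus
        test across all conditions present.
    alpha
        FDR level for the significance flag.
    per_subject
        Average each subject's values within (condition, roi, band,
        measure) before testing, so subjects rather than segments are the
        unit of observation.

    Returns
    -------
    DataFrame with one row per (measure, roi, band, contrast):
    per-condition medians, the median difference for pairwise contrasts,
    H, raw p, BH-FDR q (corrected within each measure x contrast family
    across all ROI x band cells) and the significance flag.
    """
    required = {"subject", "condition", "roi", "band", "measure", "value"}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"measures table missing columns: {sorted(missing)}")
    df = measures.copy()
    if per_subject:
        df = (
            df.groupby(["subject", "condition", "roi", "band", "measure"], as_index=False, sort=False)["value"]
            .mean()
        )
    all_conditions = list(dict.fromkeys(df["condition"]))

    rows = []
    for (measure, roi, band), sub in df.groupby(["measure", "roi", "band"], sort=False):
        medians = {
            f"median_{cond}": float(np.median(sub.loc[sub["condition"] == cond, "value"]))
            for cond in all_conditions
            if (sub["condition"] == cond).any()
        }
        jobs = [("omnibus", all_conditions)]
        jobs += [(f"{a}_vs_{b}", [a, b]) for a, b in contrasts]
        for contrast, conds in jobs:
            groups = _cell_groups(sub, conds)
            row = {"measure": measure, "roi": roi, "band": band, "contrast": contrast, **medians}
            if groups is None:
                logger.warning(
                    "cell (%s, %s, %s, %s) has a condition with < 2 observations; excluded from FDR",
                    measure, roi, band, contrast,
                )
                row.update(H=np.nan, p=np.nan)
            else:
                h, p = kruskal_wallis(*groups)
                row.update(H=h, p=p)
            if len(conds) == 2 and all(f"median_{c}" in medians for c in conds):
                row["median_diff"] = medians[f"median_{conds[0]}"] - medians[f"median_{conds[1]}"]
            rows.append(row)

    results = pd.DataFrame(rows)
    results["q"] = np.nan
    results["significant"] = False
    for (_, _), idx in results.groupby(["measure", "contrast"], sort=False).groups.items():
        sel = results.loc[idx]
        ok = sel["p"].notna()
        if ok.any():
            q, reject = fdr_bh(sel.loc[ok, "p"].to_numpy(), alpha=alpha)
            results.loc[sel.index[ok], "q"] = q
            results.loc[sel.index[ok], "significant"] = reject
    return results


def difference_map(measures: pd.DataFrame, measure: str, cond_a: str, cond_b: str) -> pd.DataFrame:
    """ROI x band matrix of median differences (cond_a minus cond_b)."""
    df = measures[measures["measure"] == measure]
    med = df.groupby(["roi", "band", "condition"])["value"].median().unstack("condition")
    for cond in (cond_a, cond_b):
        if cond not in med.columns:
            raise ValueError(f"condition {cond!r} absent from the measure table")
    diff = (med[cond_a] - med[cond_b]).unstack("band")
    return diff
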