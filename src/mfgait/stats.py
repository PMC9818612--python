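"""Group comparisons on the stability feature matrix.

Per-channel independent-samples t-tests between fallers and non-fallers
(pooled variance by default, Welch optional), posture-stability comparisons
within each sex, and Wilcoxon rank-sum checks that the groups are balanced
on age and BMI.  Raw per-channel p-values are reported (no correction was
applied in the original analysis); a Benjamini-Hochberg column is added as
a clearly labelled extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from mfgait.features import FeatureMatrix, posture_stability

__all__ = ["channel_ttests", "sex_group_comparison", "baseline_ranksum", "pooled_ttest"]

SIGNIFICANCE_LEVEL = 0.005  # headline per-channel threshold


def pooled_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided independent-samples t-test; (t, p).

    Degenerate inputs: both groups constant and equal -> t = 0, p = 1;
    both constant but unequal -> error (zero variance, infinite t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def channel_ttests(
    matrix: FeatureMatrix,
    alpha_level: float = SIGNIFICANCE_LEVEL,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Faller-vs-nofaller t-test per channel, rows in serial order.

    Columns: serial, marker, plane, mean_faller, mean_nofaller, t, p,
    significant (p < alpha_level), p_bh (Benjamini-Hochberg adjusted,
    an extension over the uncorrected original table).
    """
    is_faller = (matrix.labels == "faller").to_numpy()
    if is_faller.sum() < 2 or (~is_faller).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for col in matrix.values.columns:
        serial_str, rest = col.split("_", 1)
        marker, plane = rest.rsplit("_", 1)
        x = matrix.values[col].to_numpy(dtype=float)
        t, p = pooled_ttest(x[is_faller], x[~is_faller], equal_var=equal_var)
        rows.append(
            {
                "serial": int(serial_str),
                "marker": marker,
                "plane": f"{plane}-plane",
                "mean_faller": float(x[is_faller].mean()),
                "mean_nofaller": float(x[~is_faller].mean()),
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).sort_values("serial", ignore_index=True)
    table["significant"] = table["p"] < alpha_level
    table["p_bh"] = _benjamini_hochberg(table["p"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def sex_group_comparison(
    matrix: FeatureMatrix, mode: str = "joint_mean", equal_var: bool = True
) -> dict:
    """Posture-stability means for the four sex x status cells, with
    faller-vs-nofaller tests within each sex and across all subjects.

    Empty cells are reported as missing and their test skipped.
    """
    ps = matrix.values.apply(lambda row: posture_stability(row, mode=mode), axis=1)
    out: dict = {"cell_means": {}, "tests": {}, "posture_stability": ps}
    for sex in ("female", "male"):
        for label in ("faller", "nofaller"):
            mask = (matrix.sex == sex) & (matrix.labels == label)
            key = f"{sex}-{label}"
            out["cell_means"][key] = float(ps[mask].mean()) if mask.any() else None
    for scope in ("female", "male", "all"):
        mask = slice(None) if scope == "all" else (matrix.sex == scope).to_numpy()
        labels = matrix.labels.to_numpy()[mask]
        vals = ps.to_numpy()[mask]
        a = vals[labels == "faller"]
        b = vals[labels == "nofaller"]
        if len(a) < 2 or len(b) < 2:
            out["tests"][scope] = None
            continue
        t, p = pooled_ttest(a, b, equal_var=equal_var)
        out["tests"][scope] = {
            "t": t,
            "p": p,
            "mean_faller": float(a.mean()),
            "mean_nofaller": float(b.mean()),
        }
    return out


def baseline_ranksum(baseline: pd.DataFrame, columns: tuple[str, ...] = ("age", "bmi")) -> dict:
    """Wilcoxon rank-sum p-values comparing fallers and non-fallers.

    Exact null distribution for small groups (<= 10 per group, no ties),
    normal approximation with tie correction otherwise.  All-tied data
    gives p = 1.
    """
    is_faller = (baseline["label"] == "faller").to_numpy()
    out = {}
    for col in columns:
        a = baseline.loc[is_faller, col].to_numpy(dtype=float)
        b = baseline.loc[~is_faller, col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 subjects per group")
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            out[col] = 1.0
            continue
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        small = max(len(a), len(b)) <= 10
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        out[col] = float(min(res.pvalue, 1.0))
    return out
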