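"""Group-comparison statistics: ROUT outlier removal, normality-gated test
selection, post hoc procedures, and per-replicate normalization.

The decision tree mirrors the study workflow: outliers are removed with the
ROUT method (robust location/scale plus an FDR screen at rate Q); every group
is tested for normality with Shapiro–Wilk; Gaussian data are compared with an
unpaired two-sided Student's t test (two groups) or one-way ANOVA (three or
more, Dunnett's post hoc against a named control, otherwise Tukey's);
non-Gaussian data use the Mann–Whitney test or Kruskal–Wallis followed by
Dunn's multiple-comparison test (Holm-adjusted rank z statistics with
mid-ranks and tie-corrected variance).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatReport",
    "rout_outliers",
    "normality",
    "dunn_posthoc",
    "compare_groups",
    "normalize_per_replicate",
]


@dataclass
class StatReport:
    """Complete record of one group comparison (every branch taken)."""

    groups: dict[str, int]  # name -> n after outlier removal
    outliers_removed: dict[str, list[int]]
    rout_q: float
    normality: dict[str, tuple[float, float]]  # name -> (W, p)
    all_normal: bool
    test_used: str
    statistic: float
    p: float
    alpha: float
    posthoc: pd.DataFrame | None = None  # pairwise adjusted p-values
    control: str | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return json.dumps(d, indent=2, default=float)


def rout_outliers(values: Sequence[float], q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """ROUT-style outlier detection for a single sample.

    Robust location is the median; robust scale is the RSDR — the 68.27th
    percentile of absolute residuals with the small-sample correction
    n/(n−1).  Each point gets a t-like statistic residual/RSDR with n−1
    degrees of freedom, and the two-sided p-values are screened by a
    Benjamini–Hochberg step at rate ``q`` from the most extreme point inward.

    Returns ``(kept_indices, flagged_indices)``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        warnings.warn("ROUT needs n >= 3; no outliers removed")
        return np.arange(n), np.array([], dtype=int)
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return np.arange(n), np.array([], dtype=int)
    t = np.abs(resid) / rsdr
    p = 2 * sps.t.sf(t, df=n - 1)
    order = np.argsort(p)  # most extreme first
    flagged_mask = np.zeros(n, dtype=bool)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            k_max = rank
    if k_max:
        flagged_mask[order[:k_max]] = True
    flagged = np.nonzero(flagged_mask)[0]
    kept = np.nonzero(~flagged_mask)[0]
    return kept, flagged


def normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk (W, p); a constant sample is treated as non-normal (p=0)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return float("nan"), 0.0
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def dunn_posthoc(
    groups: Mapping[str, np.ndarray], control: str | None = None
) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons with Holm adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the tie
    correction T = Σ(t³ − t) / (12(N − 1)) over tied value groups.  When
    ``control`` is given, only comparisons against it are made.
    """
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    ranks = _midranks(pooled)
    n_total = len(pooled)
    mean_ranks = {}
    start = 0
    for k in names:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = (
        [(control, k) for k in names if k != control]
        if control is not None
        else list(combinations(names, 2))
    )
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * sps.norm.sf(abs(z))
        rows.append(dict(group1=a, group2=b, z=float(z), p_unadjusted=float(p)))
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    m = len(df)
    order = np.argsort(df["p_unadjusted"].to_numpy())
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * df["p_unadjusted"].iloc[idx]
        running = max(running, min(1.0, val))
        adj[idx] = running
    df["p_adjusted"] = adj
    return df


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
    alpha: float = 0.05,
    rout_q: float | None = 0.01,
) -> StatReport:
    """Run the full normality-gated decision tree on named samples.

    ``rout_q=None`` skips outlier removal.  Raises when any group has fewer
    than 3 observations after removal.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if control is not None and control not in groups:
        raise KeyError(f"control group {control!r} not among {list(groups)}")
    cleaned: dict[str, np.ndarray] = {}
    removed: dict[str, list[int]] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if rout_q is not None and len(x) >= 3:
            kept, flagged = rout_outliers(x, q=rout_q)
            removed[name] = [int(i) for i in flagged]
            x = x[kept]
        else:
            removed[name] = []
        if len(x) < 3:
            raise ValueError(f"group {name!r} has n={len(x)} < 3 after outlier removal")
        cleaned[name] = x

    norm: dict[str, tuple[float, float]] = {k: normality(v) for k, v in cleaned.items()}
    all_normal = all(p >= alpha for _, p in norm.values())
    names = list(cleaned)
    samples = [cleaned[k] for k in names]
    posthoc = None

    if all_normal:
        if len(names) == 2:
            res = sps.ttest_ind(samples[0], samples[1], equal_var=True)
            test_used, stat, p = "t", float(res.statistic), float(res.pvalue)
        else:
            res = sps.f_oneway(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
            if control is not None:
                treat = [cleaned[k] for k in names if k != control]
                dres = sps.dunnett(*treat, control=cleaned[control])
                posthoc = pd.DataFrame(
                    dict(
                        group1=[control] * len(dres.pvalue),
                        group2=[k for k in names if k != control],
                        statistic=[float(s) for s in dres.statistic],
                        p_adjusted=[float(pv) for pv in dres.pvalue],
                    )
                )
                test_used = "ANOVA+Dunnett"
            else:
                tres = sps.tukey_hsd(*samples)
                rows = []
                for i, j in combinations(range(len(names)), 2):
                    rows.append(
                        dict(
                            group1=names[i],
                            group2=names[j],
                            statistic=float(tres.statistic[i, j]),
                            p_adjusted=float(tres.pvalue[i, j]),
                        )
                    )
                posthoc = pd.DataFrame(rows)
                test_used = "ANOVA+Tukey"
    else:
        if len(names) == 2:
            res = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
            test_used, stat, p = "Mann-Whitney", float(res.statistic), float(res.pvalue)
        else:
            res = sps.kruskal(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
            posthoc = dunn_posthoc(cleaned, control=control)
            test_used = "Kruskal-Wallis+Dunn"

    return StatReport(
        groups={k: int(len(v)) for k, v in cleaned.items()},
        outliers_removed=removed,
        rout_q=rout_q if rout_q is not None else float("nan"),
        normality=norm,
        all_normal=all_normal,
        test_used=test_used,
        statistic=stat,
        p=p,
        alpha=alpha,
        posthoc=posthoc,
        control=control,
    )


def normalize_per_replicate(
    values: Sequence[float],
    replicates: Sequence,
    groups: Sequence[str],
    control_name: str,
) -> np.ndarray:
    """Divide each observation by its replicate's control-group mean.

    Removes between-experiment scale so replicates are comparable; every
    replicate must contain control observations.
    """
    values = np.asarray(values, dtype=float)
    replicates = np.asarray(replicates)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for rep in np.unique(replicates):
        sel = replicates == rep
        ctrl = values[sel & (groups == control_name)]
        if len(ctrl) == 0:
            raise ValueError(f"replicate {rep!r} has no {control_name!r} observations")
        out[sel] = values[sel] / ctrl.mean()
    return out
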