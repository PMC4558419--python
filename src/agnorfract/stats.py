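"""Group statistics: hierarchical averaging, ANOVA/Tukey, Pearson, FD frequencies.

The measurement hierarchy is image -> patient -> group; averaging is
always unweighted within each unit and never pools pixels across levels.
Group comparisons use classical one-way ANOVA with Tukey HSD post hoc
(Tukey-Kramer for unbalanced designs); correlations between tissue
compartments use the Pearson product-moment coefficient.

The fractal-dimension frequency analysis bins per-object (or per-image)
FDs, then repeats the ANOVA on the narrowed closed interval
[1.05, 1.09] where the distributions concentrate — a pure inclusive
subset filter that can recover group separation a full-range comparison
dilutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PearsonResult",
    "FdHistogram",
    "COHORT_COLUMNS",
    "aggregate",
    "one_way_anova",
    "tukey_hsd",
    "pearson_compartments",
    "fd_frequency_analysis",
    "narrow_filter",
]

logger = logging.getLogger(__name__)

#: long-format cohort table columns (one row per image x metric)
COHORT_COLUMNS = ("patient_id", "image_id", "image_kind", "group", "metric", "value")

#: default narrowed FD interval (closed)
NARROW_INTERVAL = (1.05, 1.09)


@dataclass
class AnovaResult:
    """One-way ANOVA summary: F(df_between, df_within) and p."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float

    def __str__(self) -> str:
        return f"F({self.df_between},{self.df_within}) = {self.f_stat:.3f}, P = {self.p_value:.3g}"


@dataclass
class PearsonResult:
    r: float
    p_value: float
    n: int


@dataclass
class FdHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    narrow_interval: tuple[float, float] = NARROW_INTERVAL


def _check_groups(values_by_group: Mapping, min_per_group: int = 2) -> dict[str, np.ndarray]:
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in values_by_group.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < min_per_group:
            raise ValueError(f"group {name!s} has fewer than {min_per_group} values")
        out[str(name)] = arr
    return out


def one_way_anova(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical between/within one-way ANOVA over >= 2 groups."""
    groups = _check_groups(values_by_group)
    arrays = list(groups.values())
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return AnovaResult(f_stat=float(f), df_between=k - 1, df_within=n - k, p_value=float(p))


def tukey_hsd(values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range adjusted p-values.

    Returns a table with columns ``group_a, group_b, mean_diff, p_adj,
    significant`` (one row per unordered pair, ``mean_diff = mean_a -
    mean_b``).  Unequal group sizes use the Tukey-Kramer adjustment.
    """
    groups = _check_groups(values_by_group)
    names = list(groups)
    res = sps.tukey_hsd(*groups.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = float(np.mean(groups[names[i]]) - np.mean(groups[names[j]]))
            p = float(res.pvalue[i, j])
            rows.append(
                dict(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=diff,
                    p_adj=min(max(p, 0.0), 1.0),
                    significant=p < alpha,
                )
            )
    return pd.DataFrame(rows)


def pearson_compartments(pairs: Sequence[tuple[float, float]]) -> PearsonResult:
    """Pearson r between compartment values (e.g. epithelium vs whole tissue)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (x, y) pairs")
    arr = arr[np.isfinite(arr).all(axis=1)]
    if len(arr) < 3:
        raise ValueError("Pearson correlation needs n >= 3 finite pairs")
    r, p = sps.pearsonr(arr[:, 0], arr[:, 1])
    return PearsonResult(r=float(r), p_value=float(p), n=len(arr))


# ---------------------------------------------------------------------------
# hierarchical averaging


def aggregate(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Average a long-format cohort table up one or two levels.

    ``level="patient"`` averages image values within each patient;
    ``level="group"`` averages patient means within each group (images are
    first averaged to patients — group means are means of patient means,
    never pixel or image pooling across patients).
    """
    missing = [c for c in ("group", "metric", "value") if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if level == "image":
        return table.copy()
    if level == "patient":
        keys = ["patient_id", "group", "metric"]
        if "image_kind" in table.columns:
            keys.insert(1, "image_kind")
        return table.groupby(keys, as_index=False, observed=True)["value"].mean()
    if level == "group":
        per_patient = aggregate(table, "patient") if "patient_id" in table.columns else table
        keys = ["group", "metric"]
        if "image_kind" in per_patient.columns:
            keys.insert(0, "image_kind")
        return per_patient.groupby(keys, as_index=False, observed=True)["value"].mean()
    raise ValueError(f"unknown aggregation level {level!r}")


# ---------------------------------------------------------------------------
# FD frequency / narrowed-interval analysis


def narrow_filter(values: Sequence[float], interval: tuple[float, float] = NARROW_INTERVAL) -> np.ndarray:
    """Inclusive subset of values inside the closed interval."""
    lo, hi = interval
    if not lo < hi:
        raise ValueError(f"narrow interval must be increasing, got ({lo}, {hi})")
    arr = np.asarray(list(values), dtype=float)
    return arr[(arr >= lo) & (arr <= hi)]


def fd_frequency_analysis(
    fds_by_group: Mapping[str, Sequence[float]],
    bin_width: float = 0.01,
    narrow: tuple[float, float] = NARROW_INTERVAL,
) -> tuple[dict[str, FdHistogram], AnovaResult, AnovaResult | None]:
    """Histogram FDs per group and run ANOVA on full and narrowed data.

    Returns per-group histograms (common bin edges), the full-range ANOVA,
    and the ANOVA restricted to the closed ``narrow`` interval.  Groups
    whose narrowed set has fewer than 2 values are dropped from the
    narrowed ANOVA with a logged warning; the narrowed result is None when
    fewer than 2 groups survive.
    """
    groups = _check_groups(fds_by_group)
    allv = np.concatenate(list(groups.values()))
    lo = np.floor(allv.min() / bin_width) * bin_width
    hi = np.ceil(allv.max() / bin_width) * bin_width
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    hists = {
        name: FdHistogram(bin_edges=edges, counts=np.histogram(v, bins=edges)[0], narrow_interval=narrow)
        for name, v in groups.items()
    }
    full = one_way_anova(groups)
    narrowed_groups = {}
    for name, v in groups.items():
        nv = narrow_filter(v, narrow)
        if len(nv) < 2:
            logger.warning("group %s has no data in the narrowed interval %s; dropped", name, narrow)
            continue
        narrowed_groups[name] = nv
    narrowed = one_way_anova(narrowed_groups) if len(narrowed_groups) >= 2 else None
    return hists, full, narrowed
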