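"""Cohort dispersion, duplicate inter-assay CV, delta kinetics, and design CVs.

All dispersion statistics use the sample SD (n-1 denominator), SE = SD/sqrt(n),
CV = SD/mean, and linearly interpolated percentiles, so box-whisker summaries
are reproducible bit-for-bit.  The duplicate inter-assay statistic is the
arithmetic mean over animals of per-pair CVs (an RMS aggregation is available
behind a flag).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .panel import LEUKOCYTE_SUBSETS, MONO_SUBSETS
from .quantify import SampleResult

PERCENTILES = (1, 10, 25, 50, 75, 90, 99)


def _values_by_subset(results: Sequence[SampleResult]) -> dict[str, np.ndarray]:
    return {
        s: np.array([r.absolute_counts[s] for r in results])
        for s in LEUKOCYTE_SUBSETS
    }


def summary_stats(values: np.ndarray) -> dict[str, float]:
    """n, mean, SD (n-1), SE, CV (SD/mean), linear-interpolation percentiles."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("summary needs at least 2 samples")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    out = {
        "n": n,
        "mean": mean,
        "sd": sd,
        "se": sd / np.sqrt(n),
        "cv": sd / mean if mean != 0 else np.nan,
        "cv_defined": mean != 0,
    }
    pct = np.percentile(values, PERCENTILES, method="linear")
    for p, v in zip(PERCENTILES, pct):
        out[f"p{p}"] = float(v)
    return out


def cohort_summary(results: Sequence[SampleResult]) -> pd.DataFrame:
    """Per-subset dispersion summary of absolute counts across a cohort.

    Also summarizes the per-animal monocyte subset fractions (% of
    MHCII-negative monocytes) in rows named ``fraction_<subset>``.
    """
    rows = []
    for s, values in _values_by_subset(results).items():
        rows.append({"quantity": s, **summary_stats(values)})
    for s in MONO_SUBSETS:
        fracs = np.array(
            [r.fractions[s] for r in results if r.fractions is not None]
        )
        if len(fracs) >= 2:
            rows.append({"quantity": f"fraction_{s}", **summary_stats(fracs)})
    return pd.DataFrame(rows).set_index("quantity")


def pair_cv(a: float, b: float) -> float:
    """CV of a duplicate pair: SD (n-1) over the two values divided by their mean."""
    mean = 0.5 * (a + b)
    if mean == 0:
        raise ValueError("pair with zero mean; CV undefined")
    return float(np.std([a, b], ddof=1) / mean)


def inter_assay_cv(
    duplicate_pairs: Sequence[tuple[SampleResult, SampleResult]],
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-subset inter-assay CV from duplicate acquisitions.

    Each pair shares one animal's blood; its CV reflects technical noise
    plus counting statistics.  The reported statistic aggregates per-pair
    CVs over animals by arithmetic mean (default) or RMS.
    """
    if len(duplicate_pairs) < 2:
        raise ValueError("need at least 2 duplicate pairs")
    if aggregate not in ("mean", "rms"):
        raise ValueError("aggregate must be 'mean' or 'rms'")
    rows = []
    for s in LEUKOCYTE_SUBSETS:
        cvs = np.array(
            [pair_cv(a.absolute_counts[s], b.absolute_counts[s]) for a, b in duplicate_pairs]
        )
        value = float(np.mean(cvs)) if aggregate == "mean" else float(np.sqrt(np.mean(cvs**2)))
        rows.append({"subset": s, "inter_assay_cv": value, "n_pairs": len(cvs)})
    return pd.DataFrame(rows).set_index("subset")


def delta_kinetics(results: Sequence[SampleResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal baseline-subtracted kinetics and group mean +/- SE per day.

    Every animal must have a day-0 (baseline) measurement; missing later
    days are simply absent rows.  Returns (per-animal deltas, group summary).
    """
    rows = []
    for r in results:
        for s in LEUKOCYTE_SUBSETS:
            rows.append(
                {
                    "animal_id": r.meta.get("animal_id"),
                    "group": r.meta.get("group"),
                    "day": r.meta.get("day"),
                    "subset": s,
                    "cells_per_ul": r.absolute_counts[s],
                }
            )
    frame = pd.DataFrame(rows)
    baselines = frame[frame["day"] == 0].set_index(["animal_id", "subset"])["cells_per_ul"]
    missing = set(zip(frame["animal_id"], frame["subset"])) - set(baselines.index)
    if missing:
        animals = sorted({a for a, _ in missing})
        raise ValueError(f"animals without a day-0 baseline: {animals}")
    frame["delta"] = frame["cells_per_ul"] - baselines.loc[
        pd.MultiIndex.from_frame(frame[["animal_id", "subset"]])
    ].to_numpy()
    group = (
        frame.groupby(["group", "day", "subset"])["delta"]
        .agg(mean="mean", se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    return frame, group


def cv_timecourse(results: Sequence[SampleResult], design: str) -> pd.DataFrame:
    """Per-day, per-monocyte-subset CV of absolute counts across animals.

    ``design`` labels the series ('intra-group' for sequential re-sampling
    of the same animals, 'inter-group' for independent cohorts per day).
    Requires n >= 2 animals at every day.
    """
    if design not in ("intra-group", "inter-group"):
        raise ValueError("design must be 'intra-group' or 'inter-group'")
    rows = []
    by_day: dict[float, list[SampleResult]] = {}
    for r in results:
        by_day.setdefault(r.meta.get("day"), []).append(r)
    for day in sorted(by_day):
        day_results = by_day[day]
        if len(day_results) < 2:
            raise ValueError(f"day {day}: need >= 2 animals for a CV")
        for s in MONO_SUBSETS:
            values = np.array([r.absolute_counts[s] for r in day_results])
            rows.append(
                {
                    "design": design,
                    "day": day,
                    "subset": s,
                    "cv": float(np.std(values, ddof=1) / np.mean(values)),
                    "n": len(values),
                }
            )
    return pd.DataFrame(rows)


def correlate(x: Iterable[float], y: Iterable[float], method: str = "rank") -> float:
    """Correlation coefficient; 'rank' = Spearman with midrank ties."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs paired vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector; correlation undefined")
    if method == "rank":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def group_compare(groups: dict[str, np.ndarray]) -> dict:
    """Two groups: unpaired two-sided t-test.  More: one-way ANOVA + Tukey HSD.

    Returns a dict with the test name, statistic, degrees of freedom, p-value,
    and (for ANOVA) the Tukey pairwise table.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    if all(np.std(v) == 0 for v in arrays.values()) and len(
        {v[0] for v in arrays.values()}
    ) == 1:
        # identical constant groups: no variance anywhere, define p = 1
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0}
    if len(arrays) == 2:
        (na, a), (nb, b) = arrays.items()
        t = stats.ttest_ind(a, b, equal_var=True)
        return {
            "test": "t",
            "statistic": float(t.statistic),
            "df": float(t.df),
            "p": float(t.pvalue),
            "groups": [na, nb],
        }
    values = list(arrays.values())
    f = stats.f_oneway(*values)
    flat = np.concatenate(values)
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(flat, labels)
    return {
        "test": "anova",
        "statistic": float(f.statistic),
        "df": (len(arrays) - 1, len(flat) - len(arrays)),
        "p": float(f.pvalue),
        "tukey": pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        ),
    }


def per_day_group_tests(
    results: Sequence[SampleResult],
    groups: tuple[str, str] = ("MI", "SHAM"),
    subsets: Sequence[str] = MONO_SUBSETS,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Day-wise two-group comparisons of baseline-subtracted counts.

    Per-day unpaired t-tests on the deltas with Bonferroni correction across
    days, as a transparent simplification of two-way ANOVA interaction
    contrasts.
    """
    per_animal, _ = delta_kinetics(results)
    rows = []
    for s in subsets:
        sub = per_animal[(per_animal["subset"] == s) & (per_animal["day"] > 0)]
        days = sorted(sub["day"].unique())
        for day in days:
            d = sub[sub["day"] == day]
            a = d[d["group"] == groups[0]]["delta"].to_numpy()
            b = d[d["group"] == groups[1]]["delta"].to_numpy()
            res = group_compare({groups[0]: a, groups[1]: b})
            p_adj = min(res["p"] * len(days), 1.0) if correction == "bonferroni" else res["p"]
            rows.append(
                {"subset": s, "day": day, "statistic": res["statistic"],
                 "p": res["p"], "p_adjusted": p_adj}
            )
    return pd.DataFrame(rows)
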