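"""IHC-threshold classification and marker-based survival stratification.

Patients are classified by the fraction of tumor cells negative for CDK2AP1
(low/neg when >= 45% by default, the operational rule pinned by the cohort's
31/69 split) or dichotomized on continuous miR expression.  Disease-free
survival is compared between groups by Kaplan-Meier estimation and the
log-rank test; two markers jointly define four groups (high/high .. low/low)
with an additional high/high-vs-rest contrast.

KM fitting and log-rank statistics are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test


def ihc_classify(frac_negative: float, threshold: float = 0.45, inclusive: bool = True) -> str:
    """Classify a tumor by its fraction of CDK2AP1-negative cancer cells."""
    if not 0.0 <= frac_negative <= 1.0:
        raise ValueError(f"frac_negative must lie in [0, 1], got {frac_negative}")
    low = frac_negative >= threshold if inclusive else frac_negative > threshold
    return "low_neg" if low else "positive"


def dichotomize(
    patients: pd.DataFrame,
    marker: str,
    rule: str = "median",
    q: float = 0.5,
    cutoff: float | None = None,
) -> pd.Series:
    """High/low labels for one continuous marker.

    ``median`` (equivalently ``quantile`` with q=0.5) sends values equal to
    the cutpoint to low; ``fixed`` uses an absolute cutoff.  A split leaving
    either side empty raises (no stratification is possible).
    """
    values = patients[marker].astype(float)
    if rule == "median":
        cut = float(values.median())
    elif rule == "quantile":
        cut = float(values.quantile(q))
    elif rule == "fixed":
        if cutoff is None:
            raise ValueError("rule='fixed' requires a cutoff")
        cut = float(cutoff)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels = pd.Series(np.where(values > cut, "high", "low"), index=patients.index)
    if labels.nunique() < 2:
        raise ValueError(
            f"marker {marker!r} cannot be split at {cut} (all values on one side)"
        )
    return labels


@dataclass
class StratResult:
    """Survival stratification: per-group KM curves and log-rank test."""

    labels: pd.Series
    statistic: float
    p_value: float
    km_curves: dict[str, pd.DataFrame]
    contrasts: dict[str, dict] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _km_curve(durations, events, label: str) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events, label=label)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    at_risk = kmf.event_table["at_risk"].reindex(curve["time"]).to_numpy()
    curve["at_risk"] = at_risk
    return curve


def km_logrank(
    patients: pd.DataFrame,
    labels: pd.Series,
    time_col: str = "dfs_time",
    event_col: str = "dfs_event",
) -> StratResult:
    """Kaplan-Meier estimate per group and two-sided log-rank p-value."""
    labels = labels.reindex(patients.index)
    if labels.isna().any():
        raise ValueError("every patient needs a group label")
    counts = labels.value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError(f"need >=2 non-empty groups, got counts {counts.to_dict()}")

    durations = patients[time_col].astype(float)
    events = patients[event_col].astype(bool)

    curves = {
        g: _km_curve(durations[labels == g], events[labels == g], g)
        for g in sorted(counts.index)
    }
    if counts.size == 2:
        a, b = sorted(counts.index)
        res = logrank_test(
            durations[labels == a], durations[labels == b],
            events[labels == a], events[labels == b],
        )
    else:
        res = multivariate_logrank_test(durations, labels, events)
    return StratResult(
        labels=labels,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        km_curves=curves,
    )


def stratify_two_markers(
    patients: pd.DataFrame,
    marker_a: str,
    marker_b: str,
    rule: str = "median",
    time_col: str = "dfs_time",
    event_col: str = "dfs_event",
    **rule_kwargs,
) -> StratResult:
    """Four-group stratification on two markers with a high/high contrast.

    Groups are labelled ``"high/high"`` .. ``"low/low"`` from the per-marker
    dichotomies.  Reports the overall log-rank across the populated groups
    and the pairwise contrast of high/high against all remaining patients;
    contrasts involving an empty group are skipped and listed.
    """
    la = dichotomize(patients, marker_a, rule=rule, **rule_kwargs)
    lb = dichotomize(patients, marker_b, rule=rule, **rule_kwargs)
    labels = la.str.cat(lb, sep="/")

    all_groups = ["high/high", "high/low", "low/high", "low/low"]
    skipped = [g for g in all_groups if (labels == g).sum() == 0]

    durations = patients[time_col].astype(float)
    events = patients[event_col].astype(bool)

    populated = [g for g in all_groups if g not in skipped]
    curves = {
        g: _km_curve(durations[labels == g], events[labels == g], g) for g in populated
    }
    if len(populated) >= 2:
        overall = multivariate_logrank_test(durations, labels, events)
        stat, p = float(overall.test_statistic), float(overall.p_value)
    else:
        stat, p = float("nan"), float("nan")

    contrasts: dict[str, dict] = {}
    if "high/high" in populated and len(populated) >= 2:
        hh = labels == "high/high"
        res = logrank_test(durations[hh], durations[~hh], events[hh], events[~hh])
        contrasts["high/high_vs_rest"] = {
            "statistic": float(res.test_statistic),
            "p_value": float(res.p_value),
            "n_high_high": int(hh.sum()),
            "n_rest": int((~hh).sum()),
        }
    elif "high/high" in skipped:
        warnings.warn("high/high group empty; contrast skipped", stacklevel=2)

    return StratResult(
        labels=labels, statistic=stat, p_value=p, km_curves=curves,
        contrasts=contrasts, skipped=skipped,
    )


def scan_optimal_threshold(
    patients: pd.DataFrame,
    grid,
    frac_col: str = "frac_cdk2ap1_negative",
    time_col: str = "dfs_time",
    event_col: str = "dfs_event",
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Grid search for the IHC fraction threshold maximizing log-rank.

    Scanning many cutpoints and reporting the best inflates the apparent
    significance (multiple testing / minimum-p optimism); the returned
    profile always carries a warning note, and an optional permutation test
    (label-permuting the survival outcomes and re-maximizing over the grid)
    estimates an honest p-value for the maximum statistic.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("grid must be non-empty")
    frac = patients[frac_col].astype(float).to_numpy()
    durations = patients[time_col].astype(float).to_numpy()
    events = patients[event_col].astype(bool).to_numpy()

    def _profile(dur, ev) -> list[float]:
        stats_ = []
        for t in grid:
            mask = frac >= t
            if mask.all() or not mask.any():
                stats_.append(float("nan"))
                continue
            res = logrank_test(dur[mask], dur[~mask], ev[mask], ev[~mask])
            stats_.append(float(res.test_statistic))
        return stats_

    statistic = _profile(durations, events)
    profile = pd.DataFrame({"threshold": grid, "logrank_statistic": statistic})
    if profile["logrank_statistic"].isna().all():
        raise ValueError("every grid point produced an empty group")
    best_idx = int(profile["logrank_statistic"].idxmax())
    best = float(profile.loc[best_idx, "threshold"])
    best_stat = float(profile.loc[best_idx, "logrank_statistic"])

    out = {
        "threshold": best,
        "statistic": best_stat,
        "profile": profile,
        "note": (
            "threshold chosen by maximizing the log-rank statistic over a grid; "
            "the associated p-value is optimistic unless permutation-corrected"
        ),
    }
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(durations))
            perm_stats = _profile(durations[perm], events[perm])
            if np.nanmax(perm_stats) >= best_stat:
                exceed += 1
        out["permutation_p"] = (exceed + 1) / (n_permutations + 1)
    return out
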