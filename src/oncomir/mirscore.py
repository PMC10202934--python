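"""miRNA prioritization scoring.

Candidate CDK2AP1-antagonist miRNAs are ranked by the sum of two integer
scores: an expression score (0-3) given by the quartile of the miR's mean
normalized intensity among all profiled miRs, and an interaction-evidence
tier reflecting experimental validation and the number of target-prediction
algorithms (out of 12) that call the miR-target pair.  The combined score
ranges from 1 to 8 and candidates scoring at or above a threshold (default
7) are selected.

The three evidence criteria are mapped to the numeric tiers {1, 3, 5}: with
expression in {0..3} this is the minimal odd-step assignment realizing the
full 1-8 range, and it makes "selected" mean validated, widely predicted and
expressed in the top half.  The mapping is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_TIER_VALUES = (1, 3, 5)


@dataclass
class ExpressionMatrix:
    """Normalized log-scale miR intensities with per-sample group labels.

    ``values`` is a miRs x samples frame; ``groups`` assigns every sample to
    ``"deficient"`` or ``"proficient"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.loc[list(self.values.columns)]) - {"deficient", "proficient"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def mir_ids(self) -> list[str]:
        return list(self.values.index)

    def group_means(self, group: str = "deficient") -> pd.Series:
        """Per-miR mean over the samples of one group (or ``"all"``)."""
        if group == "all":
            cols = list(self.values.columns)
        else:
            cols = [s for s in self.values.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        return self.values[cols].mean(axis=1)

    def to_csv(self, expr_path, groups_path) -> None:
        self.values.to_csv(expr_path)
        self.groups.rename_axis("sample_id").to_csv(groups_path)

    @classmethod
    def from_csv(cls, expr_path, groups_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, index_col=0)
        groups = pd.read_csv(groups_path, index_col=0)["group"]
        return cls(values=values, groups=groups)


def quantile_group_score(mean_value: float, all_means) -> int:
    """Quartile-membership score in {0, 1, 2, 3}.

    Quartile boundaries are the empirical 25/50/75% quantiles of
    ``all_means`` (linear interpolation); a value exactly on a boundary goes
    to the lower group, so fully tied inputs all score 0.
    """
    all_means = np.asarray(all_means, dtype=float)
    if all_means.size == 0:
        raise ValueError("all_means must be non-empty")
    boundaries = np.quantile(all_means, (0.25, 0.5, 0.75))
    return int(np.sum(mean_value > boundaries))


def evidence_tier_score(
    validated: bool,
    n_algorithms: int,
    min_algorithms: int = 6,
    tier_values: tuple[int, int, int] = DEFAULT_TIER_VALUES,
) -> int:
    """Interaction-evidence tier for one miR-target pair.

    Lowest tier: neither validated nor predicted by at least
    ``min_algorithms`` of the 12 programs; middle tier: exactly one of the
    two; top tier: both.
    """
    if not 0 <= n_algorithms <= 12:
        raise ValueError(f"n_algorithms must lie in [0, 12], got {n_algorithms}")
    predicted = n_algorithms >= min_algorithms
    return tier_values[int(bool(validated)) + int(predicted)]


def combine_and_select(
    matrix: ExpressionMatrix,
    evidence: pd.DataFrame,
    threshold: int = 7,
    expression_group: str = "deficient",
    min_algorithms: int = 6,
    tier_values: tuple[int, int, int] = DEFAULT_TIER_VALUES,
) -> pd.DataFrame:
    """Score every miR in the matrix and flag the selected candidates.

    ``evidence`` needs columns ``mir_id``, ``validated_sources`` (semicolon
    list, empty = not validated) and ``n_predicting_algorithms``.  A miR
    without an evidence record falls to the lowest tier (with a warning).
    Output is sorted by combined score descending, ties broken by mir_id.
    """
    if not 1 <= threshold <= 8:
        raise ValueError(f"threshold must lie in [1, 8], got {threshold}")
    if evidence["mir_id"].duplicated().any():
        dupes = evidence.loc[evidence["mir_id"].duplicated(), "mir_id"].tolist()
        raise ValueError(f"duplicate evidence records for {dupes}")

    means = matrix.group_means(expression_group)
    ev = evidence.set_index("mir_id")

    rows = []
    missing = []
    for mir in matrix.mir_ids:
        expr_group = quantile_group_score(means[mir], means.to_numpy())
        if mir in ev.index:
            rec = ev.loc[mir]
            validated = bool(str(rec["validated_sources"]).strip()) and str(
                rec["validated_sources"]
            ) not in ("nan",)
            tier = evidence_tier_score(
                validated, int(rec["n_predicting_algorithms"]), min_algorithms, tier_values
            )
        else:
            missing.append(mir)
            tier = tier_values[0]
        combined = expr_group + tier
        rows.append(
            {
                "mir_id": mir,
                "mean_expr": float(means[mir]),
                "expr_group": expr_group,
                "evidence_tier": tier,
                "combined": combined,
                "selected": combined >= threshold,
            }
        )
    if missing:
        warnings.warn(
            f"{len(missing)} miR(s) without evidence records fell to the lowest tier",
            stacklevel=2,
        )

    out = pd.DataFrame(rows, columns=["mir_id", "mean_expr", "expr_group",
                                      "evidence_tier", "combined", "selected"])
    return out.sort_values(
        ["combined", "mir_id"], ascending=[False, True], ignore_index=True
    )


def score_range(
    min_algorithms: int = 6, tier_values: tuple[int, int, int] = DEFAULT_TIER_VALUES
) -> tuple[int, int, list[int]]:
    """Enumerate every attainable combined score.

    Expression groups are realized empirically by scoring each element of a
    spread sample against itself; tiers by enumerating all (validated,
    n_algorithms) pairs.  Returns (minimum, maximum, all combined scores).
    """
    sample = list(range(1, 9))
    groups = sorted({quantile_group_score(v, sample) for v in sample})
    tiers = sorted(
        {
            evidence_tier_score(v, n, min_algorithms, tier_values)
            for v in (False, True)
            for n in range(13)
        }
    )
    combined = sorted(g + t for g in groups for t in tiers)
    return combined[0], combined[-1], combined
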