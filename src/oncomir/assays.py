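"""Quantification of qPCR and dual-luciferase assays, and the CDI.

Relative expression from RT-qPCR uses the 2^-dCt / 2^-ddCt method (reference
gene GAPDH for mRNAs, snoRNA-U6 for miRs).  Dual-luciferase wells are
normalized firefly/renilla, then to the mock (empty-vector) wells of the
same plate, because transfection batches differ plate to plate.

The Coefficient of Drug Interaction (CDI) quantifies cooperativity of two
treatments on the same readout:

    CDI = activity(A+B) / mean(activity(A), activity(B))

i.e. the quotient of the combination response over the *average* of the
single responses; values near 1 indicate additivity.  The more common
product convention CDI = AB / (A*B) is available via ``method="product"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def fold_change(records: pd.DataFrame, mode: str = "ddct") -> pd.DataFrame:
    """Relative expression per (sample, target) from Ct values.

    ``records`` needs columns sample_id, target_id, ct_target, ct_reference
    and, for ``mode="ddct"``, calibrator_id naming the reference sample each
    row is compared against.

    dct mode returns 2^-(ct_target - ct_reference); ddct additionally
    subtracts the calibrator's dCt for the same target before exponentiating.
    """
    if mode not in ("dct", "ddct"):
        raise ValueError(f"mode must be 'dct' or 'ddct', got {mode!r}")
    req = {"sample_id", "target_id", "ct_target", "ct_reference"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    ct_t = records["ct_target"].to_numpy(dtype=float)
    ct_r = records["ct_reference"].to_numpy(dtype=float)
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_r).all()):
        raise ValueError("Ct values must be finite")
    if (ct_t <= 0).any() or (ct_r <= 0).any():
        raise ValueError("Ct values must be positive")

    out = records[["sample_id", "target_id"]].copy()
    out["dct"] = ct_t - ct_r

    if mode == "dct":
        out["fold_change"] = 2.0 ** (-out["dct"])
        return out

    if "calibrator_id" not in records.columns or records["calibrator_id"].isna().any():
        raise ValueError("ddct mode requires a calibrator_id for every record")
    dct_lookup = out.set_index(["sample_id", "target_id"])["dct"]
    ddct = []
    for row, cal in zip(out.itertuples(index=False), records["calibrator_id"]):
        key = (cal, row.target_id)
        if key not in dct_lookup.index:
            raise ValueError(f"calibrator {cal!r} has no record for target {row.target_id!r}")
        ddct.append(row.dct - float(dct_lookup[key]))
    out["ddct"] = ddct
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def normalize_luciferase(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-condition relative luciferase activity with dispersion.

    Each well's firefly count is normalized to its renilla count; condition
    activity on a plate is the mean well ratio divided by the mean mock
    ratio of the *same* plate.  Conditions present on several plates are
    averaged across plates; SEM is over all contributing wells.
    """
    req = {"plate_id", "condition", "firefly", "renilla"}
    missing = req - set(wells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (wells["renilla"] <= 0).any():
        raise ValueError("renilla counts must be positive")

    df = wells.copy()
    df["ratio"] = df["firefly"] / df["renilla"]

    rel_parts = []
    for plate, sub in df.groupby("plate_id"):
        mock = sub.loc[sub["condition"] == "mock", "ratio"]
        if mock.empty:
            raise ValueError(f"plate {plate!r} has no mock wells")
        sub = sub.copy()
        sub["relative_activity"] = sub["ratio"] / mock.mean()
        rel_parts.append(sub)
    rel = pd.concat(rel_parts)

    def _condition_summary(g: pd.DataFrame) -> pd.Series:
        per_plate = g.groupby("plate_id")["relative_activity"].mean()
        sem = g["relative_activity"].std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0
        return pd.Series(
            {
                "relative_activity": per_plate.mean(),
                "sem": sem,
                "n_wells": len(g),
                "n_plates": per_plate.size,
            }
        )

    out = (
        rel.groupby("condition")[["plate_id", "relative_activity"]]
        .apply(_condition_summary)
        .reset_index()
    )
    out["n_wells"] = out["n_wells"].astype(int)
    out["n_plates"] = out["n_plates"].astype(int)
    return out


@dataclass
class CDIResult:
    combination: str
    cdi: float
    classification: str


def cdi(
    combo_activity: float,
    activity_a: float,
    activity_b: float,
    thresholds: tuple[float, float] = (0.9, 1.1),
    label: str = "combination",
    method: str = "average",
) -> CDIResult:
    """Coefficient of Drug Interaction of a two-treatment combination.

    ``method="average"`` (default): combination over the mean of the single
    activities.  ``method="product"``: the conventional Bliss-style quotient
    over their product.  Classification below/within/above ``thresholds``
    maps to synergistic / additive-like / antagonistic; the thresholds are a
    reporting convention, not a fitted quantity.
    """
    for name, v in (("combo_activity", combo_activity), ("activity_a", activity_a),
                    ("activity_b", activity_b)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    lo, hi = thresholds
    if not lo <= hi:
        raise ValueError("thresholds must be ordered (low, high)")
    if method == "average":
        value = combo_activity / ((activity_a + activity_b) / 2.0)
    elif method == "product":
        value = combo_activity / (activity_a * activity_b)
    else:
        raise ValueError(f"unknown method {method!r}")
    if value < lo:
        cls = "synergistic"
    elif value > hi:
        cls = "antagonistic"
    else:
        cls = "additive-like"
    return CDIResult(combination=label, cdi=float(value), classification=cls)


def cdi_table(
    activities: pd.DataFrame,
    thresholds: tuple[float, float] = (0.9, 1.1),
    method: str = "average",
) -> pd.DataFrame:
    """CDI for every combination condition in a luciferase activity table.

    Combinations are conditions named ``"A+B"`` whose components A and B are
    themselves present as single conditions.
    """
    act = activities.set_index("condition")["relative_activity"]
    rows = []
    for cond in act.index:
        if "+" not in cond:
            continue
        a, b = cond.split("+", 1)
        if a not in act.index or b not in act.index:
            raise ValueError(f"combination {cond!r} lacks single-treatment conditions")
        res = cdi(float(act[cond]), float(act[a]), float(act[b]),
                  thresholds=thresholds, label=cond, method=method)
        rows.append({"combination": cond, "cdi": res.cdi, "classification": res.classification})
    return pd.DataFrame(rows, columns=["combination", "cdi", "classification"])
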