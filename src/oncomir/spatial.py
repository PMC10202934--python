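"""Cell-level tissue-microarray co-expression pipeline.

Per-core cell tables (one row per segmented cell, with per-channel
nucleus/cytoplasm intensity statistics) are merged across the whole cohort,
outlier cells are flagged by z-score on the median-intensity channels, cores
are summarized in the tumor compartment (mean of median cytoplasmic miR-21,
mean of median nuclear CDK2AP1), ranked by inverse Pearson correlation of
the two markers, and stratified into miR-21 high/low groups for a CDK2AP1
contrast.  Excluded cells are flagged, never dropped, so cell counts are
conserved through the pipeline.

Coordinates are continuous micrometres with the origin at the core top-left;
the scan pixel size (0.345 um) is provenance metadata only and never enters
any computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .syndata import TRUTH_PREFIX

logger = logging.getLogger(__name__)

PIXEL_SIZE_UM = 0.345  # provenance metadata, not used in computation

MIR21_COLUMN = "mir21_cytoplasm_median"
CDK2AP1_COLUMN = "cdk2ap1_nucleus_median"


def median_channels(cells: pd.DataFrame) -> list[str]:
    """All median-intensity channel columns (hidden truth columns excluded)."""
    return [
        c
        for c in cells.columns
        if c.endswith("_median") and not c.startswith(TRUTH_PREFIX)
    ]


def merge_and_filter(
    tables: Iterable[pd.DataFrame] | pd.DataFrame,
    z_threshold: float = 3.0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Merge per-core cell tables and flag outlier cells by z-score.

    z-scores are computed per median-intensity channel over the merged
    cohort; a cell is excluded when |z| (or z, in one-sided mode) exceeds
    ``z_threshold`` in any channel.  Channels with zero variance yield no
    exclusions (z undefined) and a warning.  Excluded cells stay in the
    table with ``excluded=True``.
    """
    if isinstance(tables, pd.DataFrame):
        cells = tables.copy()
    else:
        tables = list(tables)
        if not tables:
            raise ValueError("no cell tables supplied")
        header = list(tables[0].columns)
        for t in tables[1:]:
            if list(t.columns) != header:
                raise ValueError("cell tables have inconsistent headers")
        cells = pd.concat(tables, ignore_index=True)

    excluded = np.zeros(len(cells), dtype=bool)
    for col in median_channels(cells):
        x = cells[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"channel {col!r} has zero variance; no exclusions", stacklevel=2)
            continue
        z = (x - x.mean()) / sd
        excluded |= (np.abs(z) if two_sided else z) > z_threshold
    cells["excluded"] = excluded
    frac = excluded.mean() if len(cells) else 0.0
    logger.info("outlier filter excluded %.2f%% of %d cells", 100 * frac, len(cells))
    return cells


def summarize_cores(cells: pd.DataFrame, min_tumor_cells: int = 500) -> pd.DataFrame:
    """Per-core tumor-compartment aggregates.

    Only non-excluded cells contribute.  Cores with fewer than
    ``min_tumor_cells`` contributing tumor cells get ``included=False`` but
    are retained.  ``pearson_r`` correlates median cytoplasmic miR-21 with
    median nuclear CDK2AP1 across the core's tumor cells; undefined
    correlations (constant input, <2 cells) are recorded as NaN.
    """
    if "excluded" not in cells.columns:
        raise ValueError("run merge_and_filter first (missing 'excluded' column)")
    rows = []
    for core_id, sub in cells.groupby("core_id", sort=True):
        ok = sub.loc[~sub["excluded"]]
        tum = ok.loc[ok["compartment"] == "tumor"]
        n_tumor = len(tum)
        x = tum[MIR21_COLUMN].to_numpy(dtype=float)
        y = tum[CDK2AP1_COLUMN].to_numpy(dtype=float)
        if n_tumor >= 2 and x.std() > 0 and y.std() > 0:
            r = float(np.corrcoef(x, y)[0, 1])
        else:
            r = float("nan")
        rows.append(
            {
                "core_id": core_id,
                "patient_id": sub["patient_id"].iloc[0],
                "n_tumor_cells": n_tumor,
                "n_stroma_cells": int((ok["compartment"] == "stroma").sum()),
                "mir21_tumor": float(x.mean()) if n_tumor else float("nan"),
                "cdk2ap1_tumor": float(y.mean()) if n_tumor else float("nan"),
                "pearson_r": r,
                "included": n_tumor >= min_tumor_cells,
            }
        )
    return pd.DataFrame(rows)


def rank_cores(summaries: pd.DataFrame) -> pd.DataFrame:
    """Included cores ordered by inverse Pearson correlation.

    Most negative r first; cores with undefined r go last; ties break by
    core_id.  Excluded cores never appear.
    """
    inc = summaries.loc[summaries["included"]].copy()
    inc["_nan"] = inc["pearson_r"].isna()
    out = inc.sort_values(["_nan", "pearson_r", "core_id"], ignore_index=True)
    return out.drop(columns="_nan")


def compare_compartments(
    cells: pd.DataFrame,
    channel: str = MIR21_COLUMN,
    test: str = "one_sample_t",
) -> dict:
    """Tumor-vs-stroma comparison of a channel, per core and cohort-wide.

    Per core, the stroma/tumor ratio of mean cell medians is computed; the
    cohort-level test is applied to the per-core log2 ratios against zero
    (``one_sample_t`` or ``wilcoxon``) or to the per-core tumor and stroma
    means (``welch``).  Cores missing a compartment are skipped with a
    warning.
    """
    if "excluded" not in cells.columns:
        cells = cells.copy()
        cells["excluded"] = False
    rows, skipped = [], []
    for core_id, sub in cells.groupby("core_id", sort=True):
        ok = sub.loc[~sub["excluded"]]
        tum = ok.loc[ok["compartment"] == "tumor", channel]
        stro = ok.loc[ok["compartment"] == "stroma", channel]
        if tum.empty or stro.empty:
            skipped.append(core_id)
            continue
        rows.append(
            {
                "core_id": core_id,
                "tumor_mean": float(tum.mean()),
                "stroma_mean": float(stro.mean()),
                "ratio": float(stro.mean() / tum.mean()) if tum.mean() > 0 else float("nan"),
            }
        )
    if skipped:
        warnings.warn(f"{len(skipped)} core(s) missing a compartment were skipped", stacklevel=2)
    per_core = pd.DataFrame(rows, columns=["core_id", "tumor_mean", "stroma_mean", "ratio"])

    result = {"channel": channel, "per_core": per_core, "n_cores": len(per_core),
              "skipped_cores": skipped, "test": test}
    if per_core.empty:
        result.update(mean_ratio=float("nan"), statistic=float("nan"), p_value=float("nan"))
        return result
    ratios = per_core["ratio"].to_numpy(dtype=float)
    result["mean_ratio"] = float(np.nanmean(ratios))
    with np.errstate(divide="ignore"):
        log2r = np.log2(ratios[np.isfinite(ratios) & (ratios > 0)])
    if test == "one_sample_t":
        stat, p = stats.ttest_1samp(log2r, 0.0) if log2r.size > 1 else (float("nan"),) * 2
    elif test == "wilcoxon":
        stat, p = stats.wilcoxon(log2r) if np.any(log2r != 0) else (0.0, 1.0)
    elif test == "welch":
        stat, p = stats.ttest_ind(per_core["stroma_mean"], per_core["tumor_mean"],
                                  equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    result["statistic"], result["p_value"] = float(stat), float(p)
    return result


@dataclass
class StratificationResult:
    """miR-21 high/low core stratification with a CDK2AP1 contrast."""

    cutoff: float
    pairing: str
    groups: pd.Series  # core_id -> {high, low}; excluded cores absent
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    statistic: float
    p_value: float
    status: str = "ok"
    n_pairs: int | None = None


def stratify_and_test(
    summaries: pd.DataFrame,
    mir21_cutoff: float = 150.0,
    pairing: str = "unpaired",
) -> StratificationResult:
    """Stratify included cores by tumor miR-21 and compare CDK2AP1.

    A core is ``high`` when its mean tumor-cell cytoplasmic miR-21 median
    exceeds ``mir21_cutoff`` (exact equality goes to ``low``); the cutoff is
    on the raw intensity scale.  ``unpaired`` compares core-level CDK2AP1
    with Welch's t; ``patient_paired`` averages per patient within each
    group and pairs patients represented in both.
    """
    if pairing not in ("unpaired", "patient_paired"):
        raise ValueError(f"unknown pairing {pairing!r}")
    inc = summaries.loc[summaries["included"]].copy()
    inc["strat_group"] = np.where(inc["mir21_tumor"] > mir21_cutoff, "high", "low")
    groups = inc.set_index("core_id")["strat_group"]
    high = inc.loc[inc["strat_group"] == "high"]
    low = inc.loc[inc["strat_group"] == "low"]

    base = dict(
        cutoff=mir21_cutoff,
        pairing=pairing,
        groups=groups,
        n_high=len(high),
        n_low=len(low),
        mean_high=float(high["cdk2ap1_tumor"].mean()) if len(high) else float("nan"),
        mean_low=float(low["cdk2ap1_tumor"].mean()) if len(low) else float("nan"),
    )
    if high.empty or low.empty:
        empty = "high" if high.empty else "low"
        return StratificationResult(
            statistic=float("nan"), p_value=float("nan"),
            status=f"skipped: empty {empty} group", **base
        )

    if pairing == "unpaired":
        stat, p = stats.ttest_ind(
            high["cdk2ap1_tumor"], low["cdk2ap1_tumor"], equal_var=False
        )
        return StratificationResult(statistic=float(stat), p_value=float(p), **base)

    per_patient = inc.groupby(["patient_id", "strat_group"])["cdk2ap1_tumor"].mean().unstack()
    paired = per_patient.dropna()
    if len(paired) < 2:
        return StratificationResult(
            statistic=float("nan"), p_value=float("nan"),
            status="skipped: fewer than 2 patients with cores in both groups",
            n_pairs=len(paired), **base
        )
    stat, p = stats.ttest_rel(paired["high"], paired["low"])
    return StratificationResult(
        statistic=float(stat), p_value=float(p), n_pairs=len(paired), **base
    )


def reconstruct(
    cells: pd.DataFrame,
    out_path,
    channel: str | None = None,
    log2: bool = True,
    point_size: float = 2.0,
):
    """Digital reconstruction of a core: cells scattered at (x, y).

    With ``channel=None`` cells are colored by compartment (tumor red,
    stroma gray); otherwise by the (optionally log2-normalized) median
    intensity of the named channel.  Writes the figure to ``out_path``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    # fixed hash salt keeps SVG element ids (hence bytes) reproducible
    matplotlib.rcParams["svg.hashsalt"] = "oncomir"
    fig, ax = plt.subplots(figsize=(5, 5))
    if channel is not None:
        available = median_channels(cells)
        if channel not in available:
            raise ValueError(f"unknown channel {channel!r}; available: {available}")
    if len(cells):
        if channel is None:
            colors = np.where(cells["compartment"] == "tumor", "red", "gray")
            ax.scatter(cells["x"], cells["y"], s=point_size, c=colors, linewidths=0)
        else:
            vals = cells[channel].to_numpy(dtype=float)
            if log2:
                vals = np.log2(vals + 1.0)
            sc = ax.scatter(cells["x"], cells["y"], s=point_size, c=vals,
                            cmap="viridis", linewidths=0,
                            vmin=float(vals.min()), vmax=float(vals.max()))
            label = f"log2({channel} + 1)" if log2 else channel
            fig.colorbar(sc, ax=ax, label=label)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: origin top-left
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.savefig(out_path, metadata=_stable_metadata(out_path))
    plt.close(fig)
    return out_path


def _stable_metadata(out_path) -> dict | None:
    # strip timestamps so vector output is byte-stable across runs
    path = str(out_path)
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "oncomir"}
    return None
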