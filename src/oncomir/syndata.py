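"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the package (miRNA prioritization, reporter-assay
quantification, the cell-level TMA pipeline, the variant-filter cascade and
survival stratification) can be exercised against cohorts produced here,
where the planted effect sizes, correlations, relative activities, hazard
ratios and outlier fractions are known exactly.

Ground-truth annotations that analysis stages must never read are stored in
columns prefixed with ``truth_`` (see :data:`TRUTH_PREFIX`).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TRUTH_PREFIX = "truth_"

#: fluorescence channels measured per cell (miR-21 by ISH, CDK2AP1 by IF,
#: keratin 34BE12 marks the tumor epithelium, DAPI the nuclei)
CHANNELS = ("dapi", "mir21", "keratin", "cdk2ap1")
REGIONS = ("nucleus", "cytoplasm")
STATS = ("mean", "median", "sd")

#: the twelve screen hits carried forward to qPCR validation; the first five
#: are the functionally validated CDK2AP1-antagonist candidates
DEFAULT_UPREGULATED = (
    "miR-21-5p",
    "miR-23b-3p",
    "miR-26b-5p",
    "miR-93-5p",
    "miR-155-5p",
    "miR-193a-5p",
    "miR-615-5p",
    "miR-592-5p",
    "miR-31-5p",
    "miR-31-3p",
    "miR-196a-5p",
    "miR-455-5p",
)

#: relative luciferase activities (reporter repression) per transfection;
#: singles span the observed 75%..42% reductions, combinations sit at the
#: average of the singles (no synergy)
DEFAULT_MIR_EFFECTS = {
    "mock": 1.0,
    "miR-21-5p": 0.25,
    "miR-23b-3p": 0.50,
    "miR-26b-5p": 0.55,
    "miR-93-5p": 0.45,
    "miR-155-5p": 0.58,
    "miR-21-5p+miR-23b-3p": 0.375,
    "miR-21-5p+miR-26b-5p": 0.40,
    "miR-21-5p+miR-93-5p": 0.35,
    "miR-21-5p+miR-155-5p": 0.415,
}

_STAGES = {
    "expression": 1,
    "evidence": 2,
    "luciferase": 3,
    "tma": 4,
    "survival": 5,
    "variants": 6,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design being emulated: a 7-cell-line
    deficient/proficient expression screen, triplicate dual-luciferase
    plates, a 144-patient tissue microarray with three 1-mm cores per tumor
    (432 cores), and survival cohorts with group-dependent hazards.
    """

    seed: int = 0

    # expression screen
    n_mirs: int = 60
    n_deficient: int = 4
    n_proficient: int = 3
    upregulated_set: tuple[str, ...] = DEFAULT_UPREGULATED
    effect_size: float = 2.0
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    expr_noise_sd: float = 0.5

    # interaction evidence
    n_evidence: int | None = None  # defaults to n_mirs
    tier_proportions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    min_algorithms: int = 6

    # luciferase plates
    mir_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIR_EFFECTS)
    )
    replicates: int = 3
    luciferase_cv: float = 0.05

    # TMA cohort
    n_patients: int = 144
    cores_per_patient: int = 3
    cells_per_core_range: tuple[int, int] = (900, 1500)
    tumor_fraction: float = 0.7
    target_pearson_r: float = -0.6
    stroma_mir21_shift: float = 2.0
    outlier_fraction: float = 0.03
    outlier_magnitude_sd: float = 8.0
    mir21_core_log_mean: float = math.log(150.0)
    cdk2ap1_core_log_mean: float = math.log(110.0)
    core_log_sd: float = 0.25
    cell_log_sd: float = 0.2

    # survival cohorts
    hazard_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"positive": 1.0, "low_neg": 2.0}
    )
    survival_group_rule: str = "ihc"  # ihc | random | marker_quadrant
    base_hazard: float = 0.03  # events per month in the reference group
    censoring_rate: float = 0.2
    ihc_split: float = 0.45
    marker_names: tuple[str, ...] = ("miR-21-5p", "miR-93-5p", "miR-155-5p")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("tumor_fraction",):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("outlier_fraction", "censoring_rate", "ihc_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cores_per_patient < 1:
            raise ValueError("cores_per_patient must be >= 1")
        if any(p < 0 for p in self.tier_proportions):
            raise ValueError("tier_proportions must be non-negative")
        if not math.isclose(sum(self.tier_proportions), 1.0, abs_tol=1e-9):
            raise ValueError("tier_proportions must sum to 1")
        if any(h <= 0 for h in self.hazard_ratios.values()):
            raise ValueError("hazard_ratios must be positive")
        if any(a <= 0 for a in self.mir_effects.values()):
            raise ValueError("mir_effects must be positive relative activities")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = self.cells_per_core_range
        if not 0 < lo <= hi:
            raise ValueError("cells_per_core_range must satisfy 0 < lo <= hi")
        if not -1.0 <= self.target_pearson_r <= 1.0:
            raise ValueError("target_pearson_r must lie in [-1, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-local generator derived from the root seed.

        Each generator draws from an independent stream so that adding or
        reordering stages never perturbs the others.
        """
        key = _STAGES[stage]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        for key in ("upregulated_set", "marker_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("cells_per_core_range", "tier_proportions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# expression screen
# ---------------------------------------------------------------------------

def gen_expression_matrix(cfg: SimConfig):
    """Normalized log-scale miR intensities for a deficient/proficient panel.

    miRs in ``cfg.upregulated_set`` have their deficient-group mean raised by
    ``cfg.effect_size`` (log2 units) over the proficient-group mean.

    Returns an :class:`oncomir.mirscore.ExpressionMatrix`.
    """
    from .mirscore import ExpressionMatrix

    if cfg.n_deficient < 1:
        raise ValueError("no samples in the deficient group")
    if cfg.n_proficient < 1:
        raise ValueError("no samples in the proficient group")
    rng = cfg.rng("expression")

    mir_ids = list(cfg.upregulated_set[: cfg.n_mirs])
    mir_ids += [f"miR-sim-{i:03d}" for i in range(len(mir_ids), cfg.n_mirs)]
    samples = [f"DEF{i + 1}" for i in range(cfg.n_deficient)] + [
        f"PRO{i + 1}" for i in range(cfg.n_proficient)
    ]
    groups = pd.Series(
        ["deficient"] * cfg.n_deficient + ["proficient"] * cfg.n_proficient,
        index=samples,
        name="group",
    )

    n_samples = len(samples)
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, size=cfg.n_mirs)
    values = baseline[:, None] + rng.normal(0.0, cfg.expr_noise_sd, size=(cfg.n_mirs, n_samples))
    up = np.isin(mir_ids, list(cfg.upregulated_set))
    values[np.ix_(up, groups.to_numpy() == "deficient")] += cfg.effect_size

    df = pd.DataFrame(values, index=pd.Index(mir_ids, name="mir_id"), columns=samples)
    return ExpressionMatrix(values=df, groups=groups)


# ---------------------------------------------------------------------------
# interaction evidence
# ---------------------------------------------------------------------------

def gen_evidence_table(cfg: SimConfig) -> pd.DataFrame:
    """miR-target interaction evidence records with a hidden true tier.

    Tier 1: not validated and predicted by < min_algorithms programs;
    tier 3: validated XOR widely predicted; tier 5: validated AND widely
    predicted.  Records are drawn per ``cfg.tier_proportions``.
    """
    rng = cfg.rng("evidence")
    n = cfg.n_evidence if cfg.n_evidence is not None else cfg.n_mirs
    m = cfg.min_algorithms

    mir_ids = list(cfg.upregulated_set[:n])
    mir_ids += [f"miR-sim-{i:03d}" for i in range(len(mir_ids), n)]

    tiers = rng.choice([1, 3, 5], size=n, p=list(cfg.tier_proportions))
    validated = np.zeros(n, dtype=bool)
    n_alg = np.zeros(n, dtype=int)
    sources = []
    source_pool = ("TarBase", "miRWalk", "miRTarBase", "miRecords")
    for i, tier in enumerate(tiers):
        if tier == 1:
            validated[i] = False
            n_alg[i] = rng.integers(0, m)
        elif tier == 3:
            if rng.random() < 0.5:
                validated[i] = True
                n_alg[i] = rng.integers(0, m)
            else:
                validated[i] = False
                n_alg[i] = rng.integers(m, 13)
        else:
            validated[i] = True
            n_alg[i] = rng.integers(m, 13)
        if validated[i]:
            k = int(rng.integers(1, len(source_pool) + 1))
            sources.append(";".join(sorted(rng.choice(source_pool, size=k, replace=False))))
        else:
            sources.append("")

    return pd.DataFrame(
        {
            "mir_id": mir_ids,
            "target_gene": "CDK2AP1",
            "validated_sources": sources,
            "n_predicting_algorithms": n_alg,
            f"{TRUTH_PREFIX}tier": tiers,
        }
    )


# ---------------------------------------------------------------------------
# dual-luciferase plates
# ---------------------------------------------------------------------------

def gen_luciferase_plate(cfg: SimConfig) -> pd.DataFrame:
    """Triplicate firefly/renilla wells per transfection condition.

    Each replicate is one plate containing every condition plus its own mock
    wells; a plate-level transfection-efficiency factor is shared by all
    wells of a plate, so normalizing to the plate's mock cancels it.  Noise
    on the firefly:renilla ratio is multiplicative log-normal with
    coefficient of variation ``cfg.luciferase_cv``.
    """
    if "mock" not in cfg.mir_effects:
        raise ValueError("mir_effects must contain the 'mock' condition")
    if not math.isclose(cfg.mir_effects["mock"], 1.0):
        raise ValueError("mock condition must have expected relative activity 1.0")
    rng = cfg.rng("luciferase")

    sigma = math.sqrt(math.log(1.0 + cfg.luciferase_cv**2))
    rows = []
    for plate in range(1, cfg.replicates + 1):
        base_ratio = float(np.exp(rng.normal(math.log(4.0), 0.15)))
        for condition, activity in cfg.mir_effects.items():
            renilla = float(np.exp(rng.normal(math.log(2e5), 0.2)))
            noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            ratio = base_ratio * activity * noise
            rows.append(
                {
                    "plate_id": f"plate{plate}",
                    "condition": condition,
                    "firefly": ratio * renilla,
                    "renilla": renilla,
                    f"{TRUTH_PREFIX}activity": activity,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TMA cohort
# ---------------------------------------------------------------------------

def _median_columns() -> list[str]:
    return [f"{ch}_{rg}_median" for ch in CHANNELS for rg in REGIONS]


def gen_tma_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Cell-level measurements for a multi-core tissue-microarray cohort.

    The model is log-normal throughout (fluorescence intensities are positive
    and right-skewed).  Within each core, tumor cells draw their (cytoplasmic
    miR-21 median, nuclear CDK2AP1 median) from a bivariate normal on the log
    scale with correlation ``cfg.target_pearson_r``; core-level log-means are
    themselves bivariate with the same correlation, so that between-core
    miR-21 spread implies a CDK2AP1 difference across miR-21 strata.  Stromal
    miR-21 is scaled by ``cfg.stroma_mir21_shift``.  A fixed fraction of
    cells is displaced upward on every median channel by
    ``cfg.outlier_magnitude_sd`` clean channel SDs and flagged in
    ``truth_outlier``.
    """
    rng = cfg.rng("tma")
    r = cfg.target_pearson_r
    lo, hi = cfg.cells_per_core_range
    n_cores = cfg.n_patients * cfg.cores_per_patient

    patient_ids = np.repeat(
        [f"P{p:03d}" for p in range(1, cfg.n_patients + 1)], cfg.cores_per_patient
    )
    core_ids = np.array(
        [
            f"{pid}-C{c + 1}"
            for pid in (f"P{p:03d}" for p in range(1, cfg.n_patients + 1))
            for c in range(cfg.cores_per_patient)
        ]
    )

    n_cells = rng.integers(lo, hi + 1, size=n_cores)
    n_tumor = np.round(cfg.tumor_fraction * n_cells).astype(int)
    total = int(n_cells.sum())

    cov_core = (cfg.core_log_sd**2) * np.array([[1.0, r], [r, 1.0]])
    core_logmeans = rng.multivariate_normal(
        [cfg.mir21_core_log_mean, cfg.cdk2ap1_core_log_mean], cov_core, size=n_cores
    )

    core_idx = np.repeat(np.arange(n_cores), n_cells)
    is_tumor = np.zeros(total, dtype=bool)
    offset = 0
    for i in range(n_cores):
        is_tumor[offset : offset + n_tumor[i]] = True
        offset += n_cells[i]

    # cell-level residuals: correlated for tumor cells, independent in stroma
    s = cfg.cell_log_sd
    z1 = rng.standard_normal(total)
    z2 = rng.standard_normal(total)
    e_mir = s * z1
    e_cdk = np.where(is_tumor, s * (r * z1 + math.sqrt(max(0.0, 1 - r**2)) * z2), s * z2)

    mu_mir = core_logmeans[core_idx, 0]
    mu_cdk = core_logmeans[core_idx, 1]
    mir21_cyt = np.exp(np.where(is_tumor, mu_mir, mu_mir + math.log(cfg.stroma_mir21_shift)) + e_mir)
    cdk_base = np.where(is_tumor, mu_cdk, math.log(70.0))
    cdk2ap1_nuc = np.exp(cdk_base + e_cdk)

    def ln(mean_log: float, sd_log: float, size=total) -> np.ndarray:
        return np.exp(rng.normal(mean_log, sd_log, size=size))

    med = {
        "mir21_cytoplasm_median": mir21_cyt,
        "mir21_nucleus_median": 0.6 * mir21_cyt * ln(0.0, 0.1),
        "cdk2ap1_nucleus_median": cdk2ap1_nuc,
        "cdk2ap1_cytoplasm_median": 0.5 * cdk2ap1_nuc * ln(0.0, 0.1),
        "dapi_nucleus_median": ln(math.log(140.0), 0.15),
        "dapi_cytoplasm_median": 0.3 * ln(math.log(140.0), 0.15),
        "keratin_cytoplasm_median": np.where(
            is_tumor, ln(math.log(180.0), 0.2), ln(math.log(35.0), 0.3)
        ),
        "keratin_nucleus_median": np.where(
            is_tumor, 0.4 * ln(math.log(180.0), 0.2), 0.4 * ln(math.log(35.0), 0.3)
        ),
    }

    # plant outliers: deterministic count, upward displacement on every
    # median channel by k clean SDs (a debris/saturation artifact affects the
    # whole cell, which keeps recovery tests sharp)
    n_out = int(round(cfg.outlier_fraction * total))
    outlier_idx = rng.choice(total, size=n_out, replace=False)
    truth_outlier = np.zeros(total, dtype=bool)
    truth_outlier[outlier_idx] = True
    for col in _median_columns():
        clean_sd = float(np.std(med[col]))
        med[col] = med[col].copy()
        med[col][outlier_idx] += cfg.outlier_magnitude_sd * clean_sd

    data: dict[str, np.ndarray] = {
        "core_id": core_ids[core_idx],
        "patient_id": patient_ids[core_idx],
    }
    u = rng.random(total)
    theta = rng.random(total) * 2 * math.pi
    radius = 500.0 * np.sqrt(u)
    data["x"] = radius * np.cos(theta) + 500.0
    data["y"] = radius * np.sin(theta) + 500.0
    data["compartment"] = np.where(is_tumor, "tumor", "stroma")

    for ch in CHANNELS:
        for rg in REGIONS:
            m = med[f"{ch}_{rg}_median"]
            data[f"{ch}_{rg}_median"] = m
            data[f"{ch}_{rg}_mean"] = m * ln(0.0, 0.05)
            data[f"{ch}_{rg}_sd"] = 0.15 * m * ln(0.0, 0.2)
    data[f"{TRUTH_PREFIX}outlier"] = truth_outlier

    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def gen_survival_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Patient-level survival records with group-dependent hazards.

    Event times are exponential with rate ``base_hazard * hazard_ratios[g]``.
    Censoring is independent exponential with per-patient rate
    ``lambda_event * c / (1 - c)`` so the expected censored fraction equals
    ``cfg.censoring_rate`` (and c=0 censors nothing).

    Group assignment (``cfg.survival_group_rule``):

    ``ihc``
        by the fraction of CDK2AP1-negative tumor cells vs ``cfg.ihc_split``
        (low_neg when the fraction is >= the split);
    ``random``
        uniformly over the keys of ``hazard_ratios``;
    ``marker_quadrant``
        by the signs of the first two marker covariates, giving the four
        labels high/high, high/low, low/high, low/low.
    """
    rng = cfg.rng("survival")
    n = cfg.n_patients
    hr = dict(cfg.hazard_ratios)

    frac_negative = rng.random(n)
    markers = {name: rng.standard_normal(n) for name in cfg.marker_names}

    rule = cfg.survival_group_rule
    if rule == "ihc":
        groups = np.where(frac_negative >= cfg.ihc_split, "low_neg", "positive")
    elif rule == "random":
        groups = rng.choice(sorted(hr), size=n)
    elif rule == "marker_quadrant":
        if len(cfg.marker_names) < 2:
            raise ValueError("marker_quadrant rule needs at least two markers")
        a = markers[cfg.marker_names[0]] > 0
        b = markers[cfg.marker_names[1]] > 0
        lab = np.where(a, "high", "low").astype(object)
        groups = np.char.add(np.char.add(lab.astype(str), "/"), np.where(b, "high", "low"))
    else:
        raise ValueError(f"unknown survival_group_rule {rule!r}")

    realized = set(groups.tolist())
    missing = [g for g in hr if g not in realized]
    if rule in ("ihc", "random") and missing:
        raise ValueError(f"empty survival group(s): {missing}")

    lam = cfg.base_hazard * np.array([hr.get(g, 1.0) for g in groups])
    event_time = rng.exponential(1.0 / lam)
    c = cfg.censoring_rate
    if c > 0:
        lam_c = lam * c / (1.0 - c)
        censor_time = rng.exponential(1.0 / lam_c)
    else:
        censor_time = np.full(n, np.inf)
    dfs_time = np.minimum(event_time, censor_time)
    dfs_event = event_time <= censor_time

    df = pd.DataFrame(
        {
            "patient_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "frac_cdk2ap1_negative": frac_negative,
            "ihc_class": np.where(frac_negative >= cfg.ihc_split, "low_neg", "positive"),
            "group": groups,
        }
    )
    for name, vals in markers.items():
        df[name] = vals
    df[f"{TRUTH_PREFIX}hazard"] = lam
    return df


# ---------------------------------------------------------------------------
# variant fixtures
# ---------------------------------------------------------------------------

def gen_variant_table(cfg: SimConfig) -> pd.DataFrame:
    """Toy annotated variant table with known filter-cascade survivors.

    Contains one violator for each of the four SNV/indel rules (functional
    class, recurrence, population MAF, repeat indel) plus clean survivors;
    ``truth_survivor`` marks the expected cascade output.
    """
    rng = cfg.rng("variants")
    rows = [
        # survivors
        dict(gene="GENE_A", functional_class="exonic_nonsynonymous", variant_type="snv",
             maf_1000g=np.nan, maf_esp6500=np.nan, maf_gnomad=0.0001,
             in_repeat_or_low_complexity=False, n_samples_with_variant=1, survivor=True),
        dict(gene="GENE_B", functional_class="splicing", variant_type="snv",
             maf_1000g=np.nan, maf_esp6500=np.nan, maf_gnomad=np.nan,
             in_repeat_or_low_complexity=False, n_samples_with_variant=4, survivor=True),
        # rule 1: synonymous exonic variant
        dict(gene="GENE_C", functional_class="exonic_synonymous", variant_type="snv",
             maf_1000g=np.nan, maf_esp6500=np.nan, maf_gnomad=np.nan,
             in_repeat_or_low_complexity=False, n_samples_with_variant=1, survivor=False),
        # rule 2: recurrent across samples (likely artifact)
        dict(gene="GENE_D", functional_class="exonic_nonsynonymous", variant_type="snv",
             maf_1000g=np.nan, maf_esp6500=np.nan, maf_gnomad=np.nan,
             in_repeat_or_low_complexity=False, n_samples_with_variant=5, survivor=False),
        # rule 3: common population polymorphism
        dict(gene="GENE_E", functional_class="exonic_nonsynonymous", variant_type="snv",
             maf_1000g=0.02, maf_esp6500=np.nan, maf_gnomad=np.nan,
             in_repeat_or_low_complexity=False, n_samples_with_variant=2, survivor=False),
        # rule 4: indel in an interspersed repeat
        dict(gene="GENE_F", functional_class="exonic_nonsynonymous", variant_type="indel",
             maf_1000g=np.nan, maf_esp6500=np.nan, maf_gnomad=np.nan,
             in_repeat_or_low_complexity=True, n_samples_with_variant=1, survivor=False),
    ]
    order = rng.permutation(len(rows))
    records = []
    for j, i in enumerate(order):
        row = dict(rows[i])
        survivor = row.pop("survivor")
        records.append(
            dict(
                sample_id="SCC-sim",
                chrom=f"chr{(i % 22) + 1}",
                pos=10_000 + 100 * int(i),
                ref="A",
                alt="T" if row["variant_type"] == "snv" else "TA",
                **row,
                **{f"{TRUTH_PREFIX}survivor": survivor},
            )
        )
    return pd.DataFrame(records)


def drop_truth_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Remove hidden ground-truth columns before handing data to analyses."""
    return df.loc[:, [c for c in df.columns if not c.startswith(TRUTH_PREFIX)]]
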