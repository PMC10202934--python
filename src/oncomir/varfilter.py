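"""Tumor-only somatic variant filter cascade and CNV call classification.

Without a matched normal, tumor-only exome calls are dominated by germline
polymorphisms and recurrent artifacts.  The cascade keeps protein-altering
calls and removes, in order:

1. variants that are neither exonic non-synonymous nor splice-affecting;
2. variants recurring in >= ``recurrence_cutoff`` sequenced samples
   (likely platform artifacts);
3. variants with population MAF >= ``maf_cutoff`` in any of 1000 Genomes,
   ESP6500 or gnomAD (likely germline; a missing MAF counts as rare — the
   absence from population databases is exactly the signal exploited);
4. small indels in interspersed repeats or low-complexity sequence.

Each removed variant is attributed to the first rule that triggers, so the
per-rule tally plus the survivors always sums to the input size.  The rules
are independent predicates, so the surviving set does not depend on rule
order — only the attribution does.

Copy-number segments are called gain when log2 ratio > 0.5 and P < 0.05,
loss when log2 ratio < -0.5 and P < 0.05, neutral otherwise (strict
inequalities).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FUNCTIONAL_CLASSES = ("exonic_nonsynonymous", "exonic_synonymous", "splicing", "other")
KEPT_CLASSES = ("exonic_nonsynonymous", "splicing")
MAF_COLUMNS = ("maf_1000g", "maf_esp6500", "maf_gnomad")

RULES = (
    "functional_class",
    "recurrent_artifact",
    "population_maf",
    "repeat_indel",
)


def filter_cascade(
    variants: pd.DataFrame,
    recurrence_cutoff: int = 5,
    maf_cutoff: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the tumor-only filter cascade.

    Returns (survivors, tally) where tally counts removals per rule plus the
    survivors under ``"survivors"``.
    """
    bad = set(variants["functional_class"]) - set(FUNCTIONAL_CLASSES)
    if bad:
        offender = variants.loc[
            variants["functional_class"].isin(bad)
        ].iloc[0]
        raise ValueError(
            f"unknown functional_class {offender['functional_class']!r} "
            f"in record {offender.get('gene', '?')}:{offender.get('pos', '?')}"
        )

    fc = variants["functional_class"]
    fail_class = ~fc.isin(KEPT_CLASSES)
    fail_recur = variants["n_samples_with_variant"] >= recurrence_cutoff

    maf_cols = [c for c in MAF_COLUMNS if c in variants.columns]
    if maf_cols:
        mafs = variants[maf_cols].to_numpy(dtype=float)
        finite = mafs[~np.isnan(mafs)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("MAF values must lie in [0, 1]")
        fail_maf = pd.Series(
            np.nanmax(np.where(np.isnan(mafs), -1.0, mafs), axis=1) >= maf_cutoff,
            index=variants.index,
        )
    else:
        fail_maf = pd.Series(False, index=variants.index)

    fail_repeat = (variants["variant_type"] == "indel") & variants[
        "in_repeat_or_low_complexity"
    ].astype(bool)

    fails = {
        "functional_class": fail_class,
        "recurrent_artifact": fail_recur,
        "population_maf": fail_maf,
        "repeat_indel": fail_repeat,
    }

    removed_by = pd.Series("", index=variants.index, dtype=object)
    for rule in RULES:
        newly = fails[rule] & (removed_by == "")
        removed_by[newly] = rule

    tally = {rule: int((removed_by == rule).sum()) for rule in RULES}
    survivors = variants.loc[removed_by == ""].copy()
    tally["survivors"] = len(survivors)
    return survivors, tally


def classify_cnv(
    log2_ratio: float,
    p_value: float,
    log2_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
) -> str:
    """Gain/loss/neutral call for one copy-number segment.

    Strict inequalities on both the ratio and the p-value, so a segment
    sitting exactly on a cutoff stays neutral.
    """
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p_value must lie in [0, 1], got {p_value}")
    if p_value < p_cutoff:
        if log2_ratio > log2_cutoff:
            return "gain"
        if log2_ratio < -log2_cutoff:
            return "loss"
    return "neutral"


def classify_cnv_table(
    segments: pd.DataFrame, log2_cutoff: float = 0.5, p_cutoff: float = 0.05
) -> pd.DataFrame:
    """Vectorized gain/loss/neutral calls for a CNV segment table."""
    out = segments.copy()
    out["call"] = [
        classify_cnv(l, p, log2_cutoff, p_cutoff)
        for l, p in zip(out["log2_ratio"], out["p_value"])
    ]
    return out


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_variants_tsv(path) -> pd.DataFrame:
    """Read an annotated variant table (TSV) into the cascade schema."""
    df = pd.read_csv(path, sep="\t")
    required = {"functional_class", "variant_type", "n_samples_with_variant",
                "in_repeat_or_low_complexity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return df


#: default mapping from ANNOVAR-style INFO keys to cascade fields
DEFAULT_VCF_INFO_KEYS = {
    "func": "Func.refGene",
    "exonic_func": "ExonicFunc.refGene",
    "maf_1000g": "1000g2015aug_all",
    "maf_esp6500": "esp6500siv2_all",
    "maf_gnomad": "gnomAD_genome_ALL",
    "repeat": "rmsk",
    "n_samples": "SAMPLE_COUNT",
}


def _functional_class(func: str | None, exonic_func: str | None) -> str:
    func = (func or "").lower()
    exonic_func = (exonic_func or "").lower()
    if "splicing" in func:
        return "splicing"
    if "exonic" in func:
        if "nonsynonymous" in exonic_func or "frameshift" in exonic_func or \
                "stop" in exonic_func:
            return "exonic_nonsynonymous"
        if "synonymous" in exonic_func:
            return "exonic_synonymous"
    return "other"


def read_variants_vcf(path, info_keys: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an ANNOVAR-annotated VCF into the cascade schema via cyvcf2.

    ``info_keys`` remaps the INFO field names if the annotation run used
    different keys.
    """
    from cyvcf2 import VCF

    keys = dict(DEFAULT_VCF_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)

    def _maf(variant, key: str) -> float:
        raw = variant.INFO.get(keys[key])
        if raw in (None, ".", ""):
            return float("nan")
        try:
            return float(raw)
        except (TypeError, ValueError):
            return float("nan")

    rows = []
    for v in VCF(str(path)):
        ref, alt = v.REF, (v.ALT[0] if v.ALT else "")
        rows.append(
            {
                "sample_id": v.INFO.get("SAMPLE", "unknown"),
                "gene": v.INFO.get("Gene.refGene", ""),
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": ref,
                "alt": alt,
                "functional_class": _functional_class(
                    v.INFO.get(keys["func"]), v.INFO.get(keys["exonic_func"])
                ),
                "variant_type": "snv" if len(ref) == 1 and len(alt) == 1 else "indel",
                "maf_1000g": _maf(v, "maf_1000g"),
                "maf_esp6500": _maf(v, "maf_esp6500"),
                "maf_gnomad": _maf(v, "maf_gnomad"),
                "in_repeat_or_low_complexity": v.INFO.get(keys["repeat"]) not in
                (None, ".", ""),
                "n_samples_with_variant": int(v.INFO.get(keys["n_samples"], 1)),
            }
        )
    return pd.DataFrame(rows)
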