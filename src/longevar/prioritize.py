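"""Deterministic variant-filtering rules.

Two filters drive the pipeline: selection of genotyping candidates
after the single-variant scan (nominal significance, rare-and-
differentially-enriched, or functional coding with any group
difference), and stratification of variants into functional classes
for stratified gene-based tests (coding, regulatory, combined).

A coding variant is "functional" when its predicted effect can alter
the protein: nonsynonymous, stop-gain, stop-loss, frameshift or
splice-site.  A non-coding variant is "regulatory" when its
RegulomeDB-style integer class is at most 5 AND it overlaps a
transcription-factor binding site or DNase hypersensitive site; a
3'UTR variant is functional when at least one CLIP-seq experiment
reports Argonaute binding over it (a proxy for microRNA targeting).
Variants without an annotation record classify as non-functional
(conservative), with a logged tally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import parse_regulome_score, variant_keys

__all__ = [
    "classify_coding_functional",
    "classify_regulatory",
    "classify_utr3_functional",
    "build_strata",
    "select_genotyping_candidates",
]

logger = logging.getLogger(__name__)

FUNCTIONAL_CODING_REGIONS = frozenset(
    {"exonic-nonsynonymous", "stopgain", "stoploss", "frameshift", "splicing"}
)

STRATA = ("all", "coding", "regulatory", "combined")


def classify_coding_functional(region_class: str) -> bool:
    """True iff the region class predicts an altered protein product."""
    return region_class in FUNCTIONAL_CODING_REGIONS


def classify_regulatory(regulome_score: str, tf_or_dhs_overlap: bool) -> bool:
    """True iff integer class of the regulome score <= 5 and the variant
    overlaps at least one TF binding site or DHS."""
    cls, _ = parse_regulome_score(regulome_score)
    return cls <= 5 and bool(tf_or_dhs_overlap)


def classify_utr3_functional(region_class: str, ago_evidence_count: int) -> bool:
    """True iff a 3'UTR variant has >= 1 Ago-binding experiment over it."""
    return region_class == "utr3" and int(ago_evidence_count) >= 1


def build_strata(
    variants: pd.DataFrame, annotations: pd.DataFrame | None
) -> dict[str, set]:
    """Partition variants into analysis strata.

    coding = functional coding classes; regulatory = RegulomeDB rule OR
    3'UTR-Ago rule; combined = coding UNION regulatory; all = everything.
    Returns a mapping stratum name -> set of (chrom, pos, ref, alt) keys.
    """
    keys = variant_keys(variants)
    ann_by_key: dict[tuple, dict] = {}
    if annotations is not None and len(annotations):
        for _, row in annotations.iterrows():
            k = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
            ann_by_key[k] = row

    coding, regulatory = set(), set()
    n_missing = 0
    for key, region in zip(keys, variants["region"]):
        if classify_coding_functional(region):
            coding.add(key)
        ann = ann_by_key.get(key)
        if ann is None:
            n_missing += 1
            continue
        if classify_regulatory(ann["regulome_score"], ann["tf_or_dhs_overlap"]):
            regulatory.add(key)
        elif classify_utr3_functional(region, ann["ago_evidence_count"]):
            regulatory.add(key)
    if n_missing:
        logger.info("build_strata: %d variants without annotation treated as non-functional", n_missing)
    return {
        "all": set(keys),
        "coding": coding,
        "regulatory": regulatory,
        "combined": coding | regulatory,
    }


def select_genotyping_candidates(
    scan: pd.DataFrame,
    p_cut: float = 0.05,
    maf_cut: float = 0.05,
    min_maf_diff: float = 0.0,
) -> pd.DataFrame:
    """Variants worth following up by targeted genotyping.

    A variant qualifies through any of:

    (a) allelic association p < ``p_cut``;
    (b) rare (pooled sample MAF < ``maf_cut``) and enriched in one
        group (group frequency difference > ``min_maf_diff``);
    (c) predicted-functional coding class with any group frequency
        difference (> ``min_maf_diff``).

    Returns the qualifying scan rows (deduplicated, input order) with a
    ``criteria`` column recording which rules fired.
    """
    mc = scan["maf_cases"].to_numpy(dtype=float)
    mk = scan["maf_controls"].to_numpy(dtype=float)
    p = scan["p_allelic"].to_numpy(dtype=float)
    pooled_maf = np.minimum((mc + mk) / 2.0, 1.0 - (mc + mk) / 2.0)
    diff = np.abs(mc - mk)

    crit_a = p < p_cut
    crit_b = (pooled_maf < maf_cut) & (diff > min_maf_diff)
    crit_c = (
        scan["region"].map(classify_coding_functional).to_numpy(dtype=bool)
        & (diff > min_maf_diff)
    )
    keep = np.nan_to_num(crit_a) | crit_b | crit_c
    out = scan.loc[keep].copy()
    out["criteria"] = [
        "".join(
            c for c, flag in zip("abc", (crit_a[i], crit_b[i], crit_c[i])) if flag
        )
        for i in np.flatnonzero(keep)
    ]
    return out.reset_index(drop=True)
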