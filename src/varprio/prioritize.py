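"""Step 1 of the workflow: filter, score, QC-encode, normalize and rank.

Each variant surviving the hard filters receives a raw priority score
``S = sum over annotation fields of the field's matched weight`` (for a field
matched by several rules — e.g. overlapping numeric intervals — the maximum
weight applies).  Variants with ``S`` below the configured cutoff are
dropped; the rest are normalized by the maximum raw score among survivors
(``S / S_max``), genotypes are QC-encoded per sample, and records are ranked
into the variant priority ordered list (VPOL).

Per-sample genotype codes: ``0`` reference, ``1`` heterozygous, ``2``
homozygous alternate, ``.`` quality-control failure (insufficient coverage
or skewed allele balance) or missing call.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

from .model import (
    ALT_HOM,
    HET,
    MISSING,
    MISSING_TOKEN,
    REF_HOM,
    AnnotatedVariant,
    GenotypeEvidence,
    VPOL,
    VPOLRecord,
    sort_and_rank,
)
from .ppf import PPF, FilterRule, QCThresholds, _try_float

log = logging.getLogger(__name__)


def apply_filters(variant: AnnotatedVariant, ppf: PPF) -> Tuple[bool, Optional[FilterRule]]:
    """Decide keep/drop for one variant.

    Returns ``(keep, triggered_rule)``: the variant is dropped iff any filter
    rule triggers (order-independent decision; the first triggering rule is
    reported).  Missing annotation values obey each rule's ``missing_passes``
    flag; an unparseable value hitting a numeric rule is treated as missing.
    """
    for rule in ppf.filters:
        value = variant.annotations.get(rule.field, MISSING_TOKEN)
        if rule.kind == "equals":
            if value == MISSING_TOKEN:
                if not rule.missing_passes:
                    return False, rule
            elif value == rule.value:
                return False, rule
            continue
        # numeric kinds
        x = None if value == MISSING_TOKEN else _try_float(value)
        if x is None:
            if value != MISSING_TOKEN:
                log.warning(
                    "unparseable numeric value %r in field %r treated as missing "
                    "while filtering", value, rule.field,
                )
            if not rule.missing_passes:
                return False, rule
            continue
        if rule.kind == "greater" and x > rule.threshold:
            return False, rule
        if rule.kind == "less" and x < rule.threshold:
            return False, rule
    return True, None


def score_variant(variant: AnnotatedVariant, ppf: PPF) -> int:
    """Raw priority score: per-field maximum matched weight, summed over fields.

    Missing values and fields matched by no rule contribute 0.  This is a
    total function — unparseable numeric annotation values simply match no
    interval rule.
    """
    score = 0
    annotations = variant.annotations
    for fname, rules in ppf.scoring_by_field().items():
        value = annotations.get(fname, MISSING_TOKEN)
        if value == MISSING_TOKEN:
            continue
        matched = [r.weight for r in rules if r.matches(value)]
        if matched:
            score += max(matched)
    return score


def qc_encode_genotype(ev: GenotypeEvidence, qc: QCThresholds) -> str:
    """Encode one genotype call as ``0``/``1``/``2``/``.`` after QC.

    Reference-homozygous calls are never depth-masked (masking them would
    destroy control information downstream).  Non-reference calls fail QC on
    coverage below ``min_depth`` or on an allele balance outside the
    symmetric band: heterozygotes must lie within
    ``[min_allele_balance, 1 - min_allele_balance]``, homozygous-alternate
    calls at or above ``1 - min_allele_balance``.  Checks whose inputs are
    absent from the source file cannot be disproven and pass.
    """
    if ev.gt == MISSING:
        return MISSING_TOKEN
    if ev.gt == REF_HOM:
        return "0"
    if ev.depth is not None and ev.depth < qc.min_depth:
        return MISSING_TOKEN
    ab = ev.allele_balance
    if ev.gt == HET:
        if ab is not None and (ab < qc.min_allele_balance or ab > 1 - qc.min_allele_balance):
            return MISSING_TOKEN
        return "1"
    # ALT_HOM
    if ab is not None and ab < 1 - qc.min_allele_balance:
        return MISSING_TOKEN
    return "2"


def prioritize(
    variants: Sequence[AnnotatedVariant],
    evidence: Sequence[Sequence[GenotypeEvidence]],
    ppf: PPF,
    samples: Sequence[str],
) -> VPOL:
    """Run the full prioritization pipeline and return the ranked VPOL.

    Pipeline: hard filters -> raw scoring -> raw-score cutoff (keep
    ``S >= score_cutoff``) -> normalization by the maximum surviving raw
    score (all normalized scores are 0 when that maximum is not positive)
    -> per-sample genotype QC encoding -> deterministic sort and 1-based
    ranking.  An empty result is valid, not an error.
    """
    if len(variants) != len(evidence):
        raise ValueError("variants and evidence lists must be parallel")

    survivors = []
    n_filtered = 0
    for variant, ev in zip(variants, evidence):
        keep, _rule = apply_filters(variant, ppf)
        if keep:
            survivors.append((variant, ev))
        else:
            n_filtered += 1

    scored = []
    n_cutoff = 0
    for variant, ev in survivors:
        s = score_variant(variant, ppf)
        if s >= ppf.score_cutoff:
            scored.append((variant, ev, s))
        else:
            n_cutoff += 1

    s_max = max((s for _, _, s in scored), default=0)
    records = []
    for variant, ev, s in scored:
        normalized = max(0.0, s / s_max) if s_max > 0 else 0.0
        encoded = {e.sample: qc_encode_genotype(e, ppf.qc) for e in ev}
        records.append(
            VPOLRecord(
                variant=variant, raw_score=s, normalized_score=normalized,
                encoded_genotypes=encoded,
            )
        )

    log.info(
        "prioritize: %d variants in, %d removed by filters, %d below cutoff, %d ranked",
        len(variants), n_filtered, n_cutoff, len(records),
    )
    return VPOL(records=sort_and_rank(records), samples=list(samples))
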