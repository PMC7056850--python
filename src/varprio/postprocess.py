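"""Step 2 of the workflow: reports and filters over a ranked variant list.

All filters return a subset of the input records with raw and normalized
scores untouched and ranks reassigned consecutively; they are therefore
idempotent.  Genotype predicates operate on the encoded per-sample codes
(``0``/``1``/``2``/``.``); a ``.`` code is non-informative everywhere — it
never counts as carrying an allele, and a de novo or dominant claim that
depends on a parent being reference fails closed when that parent is ``.``.
"""

from __future__ import annotations

import math
import re
from dataclasses import replace
from typing import Dict, List, Sequence

from .exceptions import ConfigurationError, ValidationError
from .model import (
    AFFECTED,
    MISSING_TOKEN,
    UNAFFECTED,
    GeneList,
    Pedigree,
    StatsReport,
    TrioRoles,
    VPOL,
    VPOLRecord,
    sort_and_rank,
)

#: default annotation field holding the gene symbol (ANNOVAR refGene naming)
DEFAULT_GENE_FIELD = "Gene.refGene"

_GENE_SPLIT = re.compile(r"[;,]")

INHERITANCE_MODELS = ("DN", "AD", "AR", "CH")

_CARRIER = ("1", "2")


def genes_of(record: VPOLRecord, gene_field: str) -> set:
    """Gene symbols of a record: the gene cell split on ``;`` and ``,``.

    Matching downstream is exact and case-sensitive; a missing cell yields
    the empty set.
    """
    cell = record.variant.annotations.get(gene_field, MISSING_TOKEN)
    if cell == MISSING_TOKEN:
        return set()
    return {g.strip() for g in _GENE_SPLIT.split(cell) if g.strip()}


def _subset(vpol: VPOL, records: Sequence[VPOLRecord]) -> VPOL:
    """Build a new VPOL from a record subset (fresh copies, ranks reassigned)."""
    copies = [replace(r) for r in records]
    return VPOL(records=sort_and_rank(copies), samples=list(vpol.samples))


def nearest_rank_threshold(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    ordered = sorted(values)
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return ordered[rank - 1]


def stats(vpol: VPOL, percentile: float = 75.0,
          gene_field: str = DEFAULT_GENE_FIELD) -> StatsReport:
    """Quick variant report: totals, per-sample carrier counts, top genes.

    For each sample, reports the genes having at least one variant whose
    normalized score reaches the nearest-rank *percentile* threshold and
    which that sample carries (encoded genotype ``1`` or ``2``).
    """
    if not (0 < percentile <= 100):
        raise ConfigurationError("percentile must lie in (0, 100]")
    if not vpol.records:
        return StatsReport(
            n_records=0, percentile=percentile, threshold=None,
            carrier_counts={s: 0 for s in vpol.samples},
            genes_by_sample={s: [] for s in vpol.samples},
        )
    threshold = nearest_rank_threshold(
        [r.normalized_score for r in vpol.records], percentile
    )
    carrier_counts = {s: 0 for s in vpol.samples}
    genes: Dict[str, set] = {s: set() for s in vpol.samples}
    for r in vpol.records:
        top = r.normalized_score >= threshold
        for s in vpol.samples:
            if r.encoded_genotypes.get(s) in _CARRIER:
                carrier_counts[s] += 1
                if top:
                    genes[s] |= genes_of(r, gene_field)
    return StatsReport(
        n_records=len(vpol.records), percentile=percentile, threshold=threshold,
        carrier_counts=carrier_counts,
        genes_by_sample={s: sorted(g) for s, g in genes.items()},
    )


def filter_by_genes(vpol: VPOL, genes: GeneList,
                    gene_field: str = DEFAULT_GENE_FIELD) -> VPOL:
    """Keep records whose gene annotation intersects the candidate gene list."""
    if vpol.records and gene_field not in vpol.records[0].variant.annotations:
        raise ConfigurationError(f"gene field {gene_field!r} is not present in the VPOL")
    kept = [r for r in vpol.records if genes_of(r, gene_field) & genes.symbols]
    return _subset(vpol, kept)


def filter_case_control(vpol: VPOL, pedigree: Pedigree) -> VPOL:
    """Keep variants carried by at least one affected sample and no unaffected one.

    Samples of unknown status are ignored; ``.`` genotypes never count as
    carrying, so a QC-failed control cannot rescue a variant from exclusion
    and a QC-failed case cannot establish presence.
    """
    cases = [s for s in vpol.samples if pedigree.status_of(s) == AFFECTED]
    controls = [s for s in vpol.samples if pedigree.status_of(s) == UNAFFECTED]
    if not cases:
        raise ConfigurationError("pedigree classifies no VPOL sample as affected")
    kept = [
        r for r in vpol.records
        if any(r.encoded_genotypes.get(s) in _CARRIER for s in cases)
        and not any(r.encoded_genotypes.get(s) in _CARRIER for s in controls)
    ]
    return _subset(vpol, kept)


# ---------------------------------------------------------------------------
# inheritance models
# ---------------------------------------------------------------------------

def _de_novo(p: str, f: str, m: str) -> bool:
    # both parents must be confidently reference: a "." parent could hide
    # an inherited allele, so the de novo claim fails closed
    return p in _CARRIER and f == "0" and m == "0"


def _autosomal_recessive(p: str, f: str, m: str) -> bool:
    return p == "2" and f == "1" and m == "1"


def _autosomal_dominant(p: str, affected_parent: str, unaffected_parent: str) -> bool:
    return p == "1" and affected_parent == "1" and unaffected_parent == "0"


def _paternal_specific(p: str, f: str, m: str) -> bool:
    return p == "1" and f in _CARRIER and m == "0"


def _maternal_specific(p: str, f: str, m: str) -> bool:
    return p == "1" and m in _CARRIER and f == "0"


def filter_inheritance(vpol: VPOL, pedigree: Pedigree, model: str,
                       gene_field: str = DEFAULT_GENE_FIELD) -> VPOL:
    """Filter a VPOL under a Mendelian trio inheritance model.

    Models (on encoded genotypes of the resolved proband/father/mother trio):

    * ``DN`` (de novo): proband carries (``1``/``2``), both parents ``0``.
    * ``AD`` (autosomal dominant): proband ``1``, the affected parent ``1``,
      the unaffected parent ``0``; requires exactly one affected parent.
    * ``AR`` (autosomal recessive): proband ``2``, both parents ``1``.
    * ``CH`` (compound heterozygous): heterozygous proband variants in genes
      carrying both a paternal-specific variant (father carries, mother
      ``0``) and a maternal-specific one (mother carries, father ``0``).
    """
    if model not in INHERITANCE_MODELS:
        raise ConfigurationError(
            f"unknown inheritance model {model!r}; expected one of {INHERITANCE_MODELS}"
        )
    trio = pedigree.resolve_trio(vpol.samples)

    def gt(record: VPOLRecord, sample: str) -> str:
        return record.encoded_genotypes.get(sample, MISSING_TOKEN)

    if model == "DN":
        kept = [r for r in vpol.records
                if _de_novo(gt(r, trio.proband), gt(r, trio.father), gt(r, trio.mother))]
    elif model == "AR":
        kept = [r for r in vpol.records
                if _autosomal_recessive(gt(r, trio.proband), gt(r, trio.father),
                                        gt(r, trio.mother))]
    elif model == "AD":
        if trio.affected_parent is None:
            raise ConfigurationError(
                "the dominant model requires exactly one affected parent in the pedigree"
            )
        unaffected_parent = (
            trio.mother if trio.affected_parent == trio.father else trio.father
        )
        kept = [r for r in vpol.records
                if _autosomal_dominant(gt(r, trio.proband), gt(r, trio.affected_parent),
                                       gt(r, unaffected_parent))]
    else:  # CH
        paternal_genes: set = set()
        maternal_genes: set = set()
        sided = []
        for r in vpol.records:
            p, f, m = gt(r, trio.proband), gt(r, trio.father), gt(r, trio.mother)
            pat = _paternal_specific(p, f, m)
            mat = _maternal_specific(p, f, m)
            if pat or mat:
                record_genes = genes_of(r, gene_field)
                sided.append((r, record_genes))
                if pat:
                    paternal_genes |= record_genes
                if mat:
                    maternal_genes |= record_genes
        both = paternal_genes & maternal_genes
        kept = [r for r, record_genes in sided if record_genes & both]

    return _subset(vpol, kept)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge_vpols(vpols: Sequence[VPOL]) -> VPOL:
    """Consolidate VPOLs from one prioritization setup into a single list.

    Inputs must share identical annotation field sets (same parameter-file
    provenance) and carry pairwise-disjoint sample names.  The output is the
    union over variant sites: a variant present in several inputs contributes
    one record with the sample columns concatenated (its raw score and
    annotations must agree across inputs), a variant absent from an input is
    encoded ``0`` for that input's samples.  Normalized scores are recomputed
    against the merged maximum and ranks reassigned.
    """
    if not vpols:
        raise ValidationError("no VPOLs to merge")

    all_samples: List[str] = []
    seen = set()
    for vpol in vpols:
        for s in vpol.samples:
            if s in seen:
                raise ValidationError(f"duplicate sample name {s!r} across merge inputs")
            seen.add(s)
            all_samples.append(s)

    field_sets = [frozenset(v.records[0].variant.annotations) for v in vpols if v.records]
    if field_sets and any(fs != field_sets[0] for fs in field_sets[1:]):
        raise ValidationError(
            "annotation field sets differ across merge inputs; these VPOLs were "
            "not produced with the same parameter file"
        )

    merged: Dict[tuple, dict] = {}
    for vpol in vpols:
        for r in vpol.records:
            key = r.variant.site_id
            entry = merged.get(key)
            if entry is None:
                merged[key] = {
                    "variant": r.variant,
                    "raw": r.raw_score,
                    "genotypes": dict(r.encoded_genotypes),
                }
                continue
            if entry["raw"] != r.raw_score:
                raise ValidationError(
                    f"conflicting raw scores for site {key}: "
                    f"{entry['raw']} vs {r.raw_score}"
                )
            if entry["variant"].annotations != r.variant.annotations:
                raise ValidationError(f"conflicting annotations for site {key}")
            entry["genotypes"].update(r.encoded_genotypes)

    s_max = max((e["raw"] for e in merged.values()), default=0)
    records = []
    for entry in merged.values():
        genotypes = {s: entry["genotypes"].get(s, "0") for s in all_samples}
        normalized = max(0.0, entry["raw"] / s_max) if s_max > 0 else 0.0
        records.append(
            VPOLRecord(
                variant=entry["variant"], raw_score=entry["raw"],
                normalized_score=normalized, encoded_genotypes=genotypes,
            )
        )
    return VPOL(records=sort_and_rank(records), samples=all_samples)
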