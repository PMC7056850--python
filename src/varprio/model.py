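"""Core domain types shared across the package.

The in-memory model is deliberately small: an :class:`AnnotatedVariant` is one
alternate allele at one site together with its annotation map (all values kept
as raw strings; missing is the single token ``"."``), a
:class:`GenotypeEvidence` is one sample's raw call at that site, and a
:class:`VPOLRecord` is a scored variant inside a ranked list (the VPOL,
*variant priority ordered list*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .exceptions import ConfigurationError, ValidationError

#: canonical missing-value token used everywhere after input normalization
MISSING_TOKEN = "."

# genotype call classes
REF_HOM = "ref-hom"
HET = "het"
ALT_HOM = "alt-hom"
MISSING = "missing"
GT_CLASSES = frozenset({REF_HOM, HET, ALT_HOM, MISSING})

# pedigree affected-status labels
AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"


def normalize_missing(value) -> str:
    """Map the common missing spellings (None, "", ".", "NA") onto ``"."``."""
    if value is None:
        return MISSING_TOKEN
    text = str(value).strip()
    if text in ("", ".", "NA"):
        return MISSING_TOKEN
    return text


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele at one genomic site with its annotations.

    Coordinates follow the VCF convention: ``pos`` is 1-based and ``chrom``
    is kept verbatim (no ``chr`` prefix normalization); identity comparisons
    use exact string equality.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError(
                f"ref and alt must be non-empty at {self.chrom}:{self.pos}"
            )

    @property
    def site_id(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeEvidence:
    """One sample's raw genotype call with read support.

    ``depth`` is the total read count at the site and ``alt_depth`` the
    alternate-supporting count; either may be ``None`` when the source file
    carried no DP/AD information, in which case downstream QC treats the
    corresponding check as unverifiable (it passes).
    """

    sample: str
    gt: str
    depth: Optional[int] = None
    alt_depth: Optional[int] = None

    def __post_init__(self):
        if self.gt not in GT_CLASSES:
            raise ValidationError(f"unknown genotype class {self.gt!r}")
        if self.depth is not None and self.depth < 0:
            raise ValidationError("depth must be >= 0")
        if self.alt_depth is not None:
            if self.alt_depth < 0:
                raise ValidationError("alt_depth must be >= 0")
            if self.depth is not None and self.alt_depth > self.depth:
                raise ValidationError("alt_depth cannot exceed depth")

    @property
    def allele_balance(self) -> Optional[float]:
        """Fraction of reads supporting the alternate allele (None if unknown)."""
        if self.depth is None or self.alt_depth is None or self.depth == 0:
            return None
        return self.alt_depth / self.depth


@dataclass(frozen=True)
class PedigreeEntry:
    family_id: str
    sample_id: str
    father_id: str  # "0" when absent
    mother_id: str
    sex: str
    status: str  # affected | unaffected | unknown


@dataclass(frozen=True)
class TrioRoles:
    """Sample identifiers of a complete proband/father/mother trio."""

    proband: str
    father: str
    mother: str
    affected_parent: Optional[str] = None


class Pedigree:
    """Family relationships and affected status parsed from a PED file."""

    def __init__(self, entries: Iterable[PedigreeEntry]):
        self.entries = list(entries)
        self._by_id = {}
        for e in self.entries:
            if e.sample_id in self._by_id:
                raise ValidationError(f"duplicate sample id {e.sample_id!r} in pedigree")
            self._by_id[e.sample_id] = e

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, sample_id: str) -> PedigreeEntry:
        return self._by_id[sample_id]

    def status_of(self, sample_id: str) -> str:
        e = self._by_id.get(sample_id)
        return e.status if e is not None else UNKNOWN

    def samples_with_status(self, status: str) -> list:
        return [e.sample_id for e in self.entries if e.status == status]

    def resolve_trio(self, available_samples: Iterable[str]) -> TrioRoles:
        """Find the unique complete trio whose members all appear in *available_samples*.

        A complete trio is an affected proband whose father and mother ids
        both resolve to pedigree entries. Raises :class:`ConfigurationError`
        when no such trio (or more than one) can be resolved.
        """
        available = set(available_samples)
        trios = []
        for e in self.entries:
            if e.status != AFFECTED:
                continue
            if e.father_id == "0" or e.mother_id == "0":
                continue
            if e.father_id not in self._by_id or e.mother_id not in self._by_id:
                continue
            if {e.sample_id, e.father_id, e.mother_id} <= available:
                trios.append(e)
        if not trios:
            raise ConfigurationError(
                "no complete trio (affected proband with both parents) resolvable "
                "from the pedigree and the available sample columns"
            )
        if len(trios) > 1:
            ids = ", ".join(e.sample_id for e in trios)
            raise ConfigurationError(f"multiple complete trios resolvable ({ids}); one is required")
        e = trios[0]
        affected_parents = [
            p for p in (e.father_id, e.mother_id) if self.status_of(p) == AFFECTED
        ]
        affected_parent = affected_parents[0] if len(affected_parents) == 1 else None
        return TrioRoles(
            proband=e.sample_id,
            father=e.father_id,
            mother=e.mother_id,
            affected_parent=affected_parent,
        )


@dataclass(frozen=True)
class GeneList:
    """A set of candidate gene symbols (trimmed, deduplicated, non-empty)."""

    symbols: frozenset

    def __post_init__(self):
        if not self.symbols:
            raise ValidationError("gene list is empty")

    @classmethod
    def from_iterable(cls, symbols: Iterable[str]) -> "GeneList":
        cleaned = {s.strip() for s in symbols if s.strip()}
        return cls(frozenset(cleaned))


@dataclass
class VPOLRecord:
    """A scored variant within a variant priority ordered list."""

    variant: AnnotatedVariant
    raw_score: int
    normalized_score: float
    encoded_genotypes: dict
    rank: int = 0


@dataclass
class VPOL:
    """A ranked variant list plus its ordered sample names."""

    records: list
    samples: list

    def __len__(self) -> int:
        return len(self.records)


def ranking_key(record: VPOLRecord) -> tuple:
    """Total deterministic ordering of VPOL records.

    Descending normalized score, then chromosome (string), position, ref and
    alt ascending, so ties are broken identically on every run.
    """
    v = record.variant
    return (-record.normalized_score, v.chrom, v.pos, v.ref, v.alt)


def sort_and_rank(records: Iterable[VPOLRecord]) -> list:
    """Return records sorted by :func:`ranking_key` with ranks 1..n assigned."""
    ordered = sorted(records, key=ranking_key)
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


@dataclass
class StatsReport:
    """Summary of a VPOL: totals, per-sample carrier counts and top genes."""

    n_records: int
    percentile: float
    threshold: Optional[float]
    carrier_counts: dict
    genes_by_sample: dict

    def to_text(self) -> str:
        lines = [f"scored variants\t{self.n_records}"]
        if self.threshold is not None:
            lines.append(
                f"normalized-score threshold (top {self.percentile:g}th percentile)\t"
                f"{self.threshold:g}"
            )
        for sample in self.carrier_counts:
            genes = ",".join(self.genes_by_sample.get(sample, [])) or "-"
            lines.append(
                f"sample\t{sample}\tcarried variants\t{self.carrier_counts[sample]}\t"
                f"top-percentile genes\t{genes}"
            )
        return "\n".join(lines) + "\n"
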