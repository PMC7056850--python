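"""Readers and writers for the tool's file formats.

Inputs are annotation-decorated VCF 4.x files (ANNOVAR-style ``key=value``
INFO pairs, plain or gzip-compressed, parsed with :mod:`pysam`) or annotated
tab-separated tables, plus 6-column PED pedigrees and one-symbol-per-line
gene lists.  The ranked output table (VPOL) is a plain TSV with a
``##samples=`` metadata line so it can be re-read losslessly.

Multi-allelic VCF records are split into one :class:`AnnotatedVariant` per
alternate allele at read time; per-allele comma lists (FORMAT ``AD``,
``Number=A`` INFO values) are apportioned to the matching allele while
line-level annotations are copied to every split allele.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pysam

from .exceptions import ConfigurationError, ParseError, ValidationError
from .model import (
    AFFECTED,
    ALT_HOM,
    HET,
    MISSING,
    MISSING_TOKEN,
    REF_HOM,
    UNAFFECTED,
    UNKNOWN,
    AnnotatedVariant,
    GeneList,
    GenotypeEvidence,
    Pedigree,
    PedigreeEntry,
    VPOL,
    VPOLRecord,
    normalize_missing,
    sort_and_rank,
)

log = logging.getLogger(__name__)

#: fixed leading columns of a VPOL file, before annotations and samples
VPOL_FIXED_COLUMNS = ("Rank", "Priority_Score", "Normalized_Score", "Chr", "Pos", "Ref", "Alt")
_VPOL_META_PREFIX = "##samples="


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_to_string(value, allele_index: int, n_alts: int) -> str:
    """Render one INFO value for one alternate allele as a raw string."""
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, bool):  # header Type=Flag
        return "1"
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:  # Number=A: apportion to this allele
            return normalize_missing(value[allele_index])
        return normalize_missing(",".join("." if v is None else str(v) for v in value))
    return normalize_missing(value)


def _classify_gt(gt_tuple, alt_allele_number: int) -> str:
    if gt_tuple is None or any(a is None for a in gt_tuple) or len(gt_tuple) == 0:
        return MISSING
    n_alt = sum(1 for a in gt_tuple if a == alt_allele_number)
    if n_alt == len(gt_tuple):
        return ALT_HOM
    if n_alt >= 1:
        return HET
    return REF_HOM


def _evidence_from_sample(sample_rec, sample: str, allele_index: int) -> GenotypeEvidence:
    gt = _classify_gt(sample_rec.get("GT"), allele_index + 1)
    if gt == MISSING:
        return GenotypeEvidence(sample=sample, gt=MISSING, depth=0, alt_depth=0)
    ad = sample_rec.get("AD")
    alt_depth = None
    if ad is not None and len(ad) > allele_index + 1 and ad[allele_index + 1] is not None:
        alt_depth = int(ad[allele_index + 1])
    depth = sample_rec.get("DP")
    if depth is None and ad is not None and all(a is not None for a in ad):
        depth = sum(int(a) for a in ad)
    if depth is not None:
        depth = int(depth)
        if alt_depth is not None and alt_depth > depth:
            # inconsistent DP vs AD in the source file; trust the AD sum
            depth = alt_depth
    return GenotypeEvidence(sample=sample, gt=gt, depth=depth, alt_depth=alt_depth)


def read_annotated_vcf(path, info_fields: Optional[Sequence[str]] = None):
    """Read an annotated VCF into the domain model.

    Parameters
    ----------
    path
        Plain or gzip/BGZF-compressed VCF 4.x file.
    info_fields
        When given, only these INFO keys populate the annotation maps (keys
        absent from the header are warned about and filled with ``"."``);
        otherwise every INFO key declared in the header is used, so all
        records carry an identical annotation field set.

    Returns
    -------
    (variants, evidence, samples)
        ``variants`` is one :class:`AnnotatedVariant` per (record, alternate
        allele) pair in file order; ``evidence`` is the parallel list of
        per-sample :class:`GenotypeEvidence` lists; ``samples`` the ordered
        sample names of the file.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except FileNotFoundError:
        raise
    except NotImplementedError:
        # htslib seeks only in BGZF; vanilla gzip needs decompressing first
        import gzip as _gzip
        import tempfile

        with _gzip.open(path, "rb") as src, tempfile.NamedTemporaryFile(
            suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(src.read())
            tmp_path = tmp.name
        try:
            return read_annotated_vcf(tmp_path, info_fields)
        finally:
            import os

            os.unlink(tmp_path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    samples = list(vcf.header.samples)
    header_keys = list(vcf.header.info.keys())
    if info_fields is not None:
        for name in info_fields:
            if name not in header_keys:
                log.warning(
                    "requested INFO field %r is not declared in %s; filling with '.'",
                    name, path,
                )
        keys = list(info_fields)
    else:
        keys = header_keys

    variants, evidence = [], []
    try:
        for rec in vcf:
            alts = rec.alts or ()
            n_alts = len(alts)
            for ai, alt in enumerate(alts):
                annotations = {}
                for key in keys:
                    if key in rec.info:
                        annotations[key] = _info_to_string(rec.info[key], ai, n_alts)
                    else:
                        annotations[key] = MISSING_TOKEN
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        annotations=annotations,
                    )
                )
                evidence.append(
                    [_evidence_from_sample(rec.samples[s], s, ai) for s in samples]
                )
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF record: {exc}") from exc
    finally:
        vcf.close()
    return variants, evidence, samples


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

DEFAULT_COORDINATE_COLUMNS = {"chrom": "Chr", "pos": "Pos", "ref": "Ref", "alt": "Alt"}


def _parse_sample_cell(cell: str, sample: str) -> GenotypeEvidence:
    """Parse a TSV genotype cell.

    Accepted shapes: VCF-style ``GT[:AD[:DP]]`` (e.g. ``0/1:25,14:39``) or a
    bare encoded genotype ``0``/``1``/``2``/``.``.
    """
    cell = normalize_missing(cell)
    if cell == MISSING_TOKEN:
        return GenotypeEvidence(sample=sample, gt=MISSING, depth=0, alt_depth=0)
    parts = cell.split(":")
    gt_token = parts[0].replace("|", "/")
    simple = {"0": REF_HOM, "1": HET, "2": ALT_HOM}
    if gt_token in simple and len(parts) == 1:
        return GenotypeEvidence(sample=sample, gt=simple[gt_token])
    alleles = gt_token.split("/")
    if "." in alleles:
        return GenotypeEvidence(sample=sample, gt=MISSING, depth=0, alt_depth=0)
    try:
        counts = [int(a) for a in alleles]
    except ValueError as exc:
        raise ParseError(f"cannot parse genotype cell {cell!r}") from exc
    n_alt = sum(1 for a in counts if a != 0)
    gt = ALT_HOM if n_alt == len(counts) else HET if n_alt else REF_HOM
    alt_depth = depth = None
    if len(parts) >= 2 and parts[1] not in ("", "."):
        ad = [int(x) for x in parts[1].split(",")]
        if len(ad) >= 2:
            alt_depth = ad[1]
            depth = sum(ad)
    if len(parts) >= 3 and parts[2] not in ("", "."):
        depth = int(parts[2])
    return GenotypeEvidence(sample=sample, gt=gt, depth=depth, alt_depth=alt_depth)


def read_annotated_tsv(path, coordinate_columns: Optional[dict] = None,
                       sample_columns: Optional[Sequence[str]] = None):
    """Read an annotated tab-separated table; same contract as :func:`read_annotated_vcf`.

    The first non-comment line is the header.  ``coordinate_columns`` maps the
    roles ``chrom``/``pos``/``ref``/``alt`` to column names (defaults
    ``Chr``/``Pos``/``Ref``/``Alt``).  Every other column becomes an
    annotation field, except the named ``sample_columns``, whose cells are
    parsed as genotypes by :func:`_parse_sample_cell`.  Empty cells and
    ``NA`` normalize to ``"."``.
    """
    coords = dict(DEFAULT_COORDINATE_COLUMNS)
    if coordinate_columns:
        coords.update(coordinate_columns)
    sample_columns = list(sample_columns or [])

    with open(path, "rt", encoding="utf-8") as fh:
        lines = [(i + 1, line.rstrip("\n")) for i, line in enumerate(fh)]
    body = [(n, l) for n, l in lines if l.strip() and not l.startswith("#")]
    if not body:
        raise ParseError(f"{path}: no header line found")
    header_no, header_line = body[0]
    header = header_line.split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ParseError(f"{path}: line {header_no}: duplicated column name(s) {dupes}")
    for role, col in coords.items():
        if col not in header:
            raise ConfigurationError(
                f"{path}: coordinate column {col!r} (role {role}) missing from header"
            )
    for col in sample_columns:
        if col not in header:
            raise ConfigurationError(f"{path}: sample column {col!r} missing from header")

    idx = {c: i for i, c in enumerate(header)}
    ann_cols = [c for c in header if c not in set(coords.values()) and c not in sample_columns]

    variants, evidence = [], []
    for line_no, line in body[1:]:
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {line_no}: expected {len(header)} columns, got {len(cells)}"
            )
        try:
            pos = int(cells[idx[coords["pos"]]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {line_no}: non-integer position") from exc
        annotations = {c: normalize_missing(cells[idx[c]]) for c in ann_cols}
        variants.append(
            AnnotatedVariant(
                chrom=cells[idx[coords["chrom"]]], pos=pos,
                ref=cells[idx[coords["ref"]]], alt=cells[idx[coords["alt"]]],
                annotations=annotations,
            )
        )
        evidence.append([_parse_sample_cell(cells[idx[s]], s) for s in sample_columns])
    return variants, evidence, sample_columns


# ---------------------------------------------------------------------------
# PED and gene lists
# ---------------------------------------------------------------------------

_PHENOTYPE_MAP = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


def read_pedigree(path) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file.

    Phenotype codes map 2 -> affected, 1 -> unaffected, 0/-9 -> unknown.
    """
    entries = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise ParseError(
                    f"{path}: line {line_no}: expected 6 PED columns, got {len(cols)}"
                )
            fam, sample, father, mother, sex, pheno = cols
            status = _PHENOTYPE_MAP.get(pheno)
            if status is None:
                raise ParseError(
                    f"{path}: line {line_no}: unknown phenotype code {pheno!r}"
                )
            entries.append(PedigreeEntry(fam, sample, father, mother, sex, status))
    return Pedigree(entries)


def read_gene_list(path) -> GeneList:
    """Read a candidate gene list: one symbol per line, ``#`` lines ignored."""
    symbols = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    if not symbols:
        raise ValidationError(f"{path}: gene list contains no symbols")
    return GeneList.from_iterable(symbols)


# ---------------------------------------------------------------------------
# VPOL
# ---------------------------------------------------------------------------

def _check_uniform_annotations(records: Sequence[VPOLRecord]) -> list:
    if not records:
        return []
    fields = list(records[0].variant.annotations)
    field_set = set(fields)
    for r in records[1:]:
        if set(r.variant.annotations) != field_set:
            raise ValidationError(
                "records carry inconsistent annotation field sets; cannot write a VPOL"
            )
    return fields


def write_vpol(vpol: VPOL, path) -> None:
    """Write a VPOL as tab-separated text.

    Records are (re)sorted into the canonical ranking order and ranks are
    assigned 1..n, so the file is always ordered by descending normalized
    score.  Column order: the fixed columns, then annotation fields (in the
    records' field order), then one encoded-genotype column per sample.
    """
    records = sort_and_rank(list(vpol.records))
    ann_fields = _check_uniform_annotations(records)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_VPOL_META_PREFIX + ",".join(vpol.samples) + "\n")
        fh.write("\t".join(list(VPOL_FIXED_COLUMNS) + ann_fields + list(vpol.samples)) + "\n")
        for r in records:
            v = r.variant
            row = [
                str(r.rank), str(r.raw_score), repr(float(r.normalized_score)),
                v.chrom, str(v.pos), v.ref, v.alt,
            ]
            row += [v.annotations[f] for f in ann_fields]
            row += [r.encoded_genotypes.get(s, MISSING_TOKEN) for s in vpol.samples]
            fh.write("\t".join(row) + "\n")


def read_vpol(path) -> VPOL:
    """Read a VPOL file written by :func:`write_vpol` (lossless round-trip)."""
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_VPOL_META_PREFIX):
            raise ParseError(f"{path}: missing '{_VPOL_META_PREFIX}' metadata line")
        samples = [s for s in first[len(_VPOL_META_PREFIX):].split(",") if s]
        header = fh.readline().rstrip("\n").split("\t")
        n_fixed = len(VPOL_FIXED_COLUMNS)
        if tuple(header[:n_fixed]) != VPOL_FIXED_COLUMNS:
            raise ParseError(f"{path}: unexpected VPOL header {header[:n_fixed]}")
        n_samples = len(samples)
        ann_fields = header[n_fixed:len(header) - n_samples] if n_samples else header[n_fixed:]
        if n_samples and header[len(header) - n_samples:] != samples:
            raise ParseError(f"{path}: sample columns do not match the metadata line")
        records = []
        for line_no, line in enumerate(fh, start=3):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} columns, got {len(cells)}"
                )
            variant = AnnotatedVariant(
                chrom=cells[3], pos=int(cells[4]), ref=cells[5], alt=cells[6],
                annotations=dict(zip(ann_fields, cells[n_fixed:n_fixed + len(ann_fields)])),
            )
            encoded = dict(zip(samples, cells[len(header) - n_samples:])) if n_samples else {}
            records.append(
                VPOLRecord(
                    variant=variant, raw_score=int(cells[1]),
                    normalized_score=float(cells[2]),
                    encoded_genotypes=encoded, rank=int(cells[0]),
                )
            )
    return VPOL(records=records, samples=samples)
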