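"""Seeded synthetic cohorts: annotated VCFs, pedigrees and truth manifests.

The generator emulates the input of a rare-disease family study: a cohort
VCF annotated with ANNOVAR-style consequence, population-frequency and
pathogenicity-predictor fields, GT:AD:DP sample columns whose genotypes are
Mendelian-consistent within each family, and an optional *planted* causal
variant following a chosen inheritance model (de novo, dominant, recessive
or compound heterozygous — the recessive case mirrors a consanguineous trio
with a rare homozygous stop-gain in the proband).

Background annotation values are simple parametric draws: they only need to
create realistic score diversity under a parameter file, not biological
realism.  Identical configuration and seed regenerate byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .exceptions import ConfigurationError
from .model import (
    ALT_HOM,
    HET,
    MISSING,
    REF_HOM,
    AnnotatedVariant,
    GenotypeEvidence,
    Pedigree,
    PedigreeEntry,
)

#: fixed gene-symbol pool (includes the genes used by the demo table so
#: gene-list filtering tests are stable)
GENE_POOL = (
    "HAAO", "CNOT2", "SLC52A2", "MAPK15", "CLTB", "SMYD5", "GAD1", "DAB2IP",
    "PSME4", "WNT10A", "NOTCH1", "GATA4", "NKX2-5", "TBX5", "MYH6", "MYH7",
    "TTN", "FLT4", "KDR", "CHD7", "KMT2D", "PTPN11", "RAF1", "SOS1",
    "JAG1", "NODAL", "ZIC3", "FOXH1", "GDF1", "ACVR2B", "LEFTY2", "CRELD1",
    "ELN", "FBN1", "COL3A1", "SMAD6", "TAB2", "NR2F2", "MEIS2", "ADAMTS10",
)

ANNOTATION_FIELDS = (
    "Gene.refGene", "Func.refGene", "ExonicFunc.refGene", "gnomAD_AF",
    "ExAC_AF", "CADD_phred", "Polyphen2_HVAR_pred", "MutationTaster_pred",
    "LRT_pred", "MetaSVM_pred", "GERPpp_RS",
)

FAMILY_STRUCTURES = ("trio", "quartet", "consanguineous-trio")

#: planted-variant annotation profiles per consequence class
_PLANT_PROFILES = {
    "stopgain": {
        "Func.refGene": "exonic", "ExonicFunc.refGene": "stopgain",
        "gnomAD_AF": "4.07e-06", "ExAC_AF": ".", "CADD_phred": "39",
        "Polyphen2_HVAR_pred": "D", "MutationTaster_pred": "A",
        "LRT_pred": "D", "MetaSVM_pred": "D", "GERPpp_RS": "5.26",
    },
    "frameshift_insertion": {
        "Func.refGene": "exonic", "ExonicFunc.refGene": "frameshift_insertion",
        "gnomAD_AF": ".", "ExAC_AF": ".", "CADD_phred": ".",
        "Polyphen2_HVAR_pred": ".", "MutationTaster_pred": ".",
        "LRT_pred": ".", "MetaSVM_pred": ".", "GERPpp_RS": ".",
    },
    "nonsynonymous_SNV": {
        "Func.refGene": "exonic", "ExonicFunc.refGene": "nonsynonymous_SNV",
        "gnomAD_AF": "5.14e-05", "ExAC_AF": ".", "CADD_phred": "28.3",
        "Polyphen2_HVAR_pred": "D", "MutationTaster_pred": "D",
        "LRT_pred": "D", "MetaSVM_pred": "D", "GERPpp_RS": "4.69",
    },
}


@dataclass(frozen=True)
class PlantedVariantSpec:
    """A causal variant to plant into family 0 of the cohort."""

    gene: str = "HAAO"
    model: str = "AR"  # DN | AD | AR | CH
    consequence: str = "stopgain"
    annotations: dict = field(default_factory=dict)  # overrides of the profile

    def __post_init__(self):
        if self.model not in ("DN", "AD", "AR", "CH"):
            raise ConfigurationError(f"unknown inheritance model {self.model!r}")
        if self.gene not in GENE_POOL:
            raise ConfigurationError(
                f"planted gene {self.gene!r} is not in the built-in gene pool"
            )
        if self.consequence not in _PLANT_PROFILES:
            raise ConfigurationError(
                f"no annotation profile for consequence {self.consequence!r}"
            )


@dataclass(frozen=True)
class CohortFixtureConfig:
    """Parameters of a synthetic cohort.

    The allele-frequency model is a mixture: a ``common_fraction`` of
    background variants draw their population frequency uniformly from
    [0.01, 0.5] (these are screened out by a 0.1% frequency filter), the
    rest log-uniformly from [1e-6, 1e-3].  Read depths are Poisson with mean
    ``mean_depth``; a ``low_depth_rate`` fraction of calls is re-drawn
    shallow (1-7 reads) so genotype-QC failures occur.
    """

    n_families: int = 1
    family_structure: str = "consanguineous-trio"
    n_background_variants: int = 5000
    seed: int = 0
    planted: Optional[PlantedVariantSpec] = None
    common_fraction: float = 0.5
    mean_depth: float = 35.0
    low_depth_rate: float = 0.02
    missing_rate: float = 0.01

    def __post_init__(self):
        if self.family_structure not in FAMILY_STRUCTURES:
            raise ConfigurationError(
                f"unknown family structure {self.family_structure!r}"
            )
        if self.n_families < 1:
            raise ConfigurationError("need at least one family")


@dataclass
class CohortData:
    """In-memory synthetic cohort: the reader-level model plus the truth."""

    variants: List[AnnotatedVariant]
    evidence: list  # parallel: one list of GenotypeEvidence per variant
    samples: List[str]
    pedigree: Pedigree
    manifest: dict


def _family_samples(structure: str, index: int) -> List[str]:
    base = [f"F{index}.P", f"F{index}.FA", f"F{index}.MO"]
    if structure == "quartet":
        base.append(f"F{index}.S1")
    return base


def _choice(rng, options, probs):
    return options[rng.choice(len(options), p=probs)]


def _background_annotations(rng, af: float) -> dict:
    func = _choice(rng, ("exonic", "intronic"), (0.9, 0.1))
    if func == "exonic":
        exonic_func = _choice(
            rng,
            ("synonymous_SNV", "nonsynonymous_SNV", "nonframeshift_deletion"),
            (0.5, 0.45, 0.05),
        )
    else:
        exonic_func = "."
    nonsyn = exonic_func == "nonsynonymous_SNV"
    ann = {
        "Gene.refGene": GENE_POOL[rng.integers(len(GENE_POOL))],
        "Func.refGene": func,
        "ExonicFunc.refGene": exonic_func,
        "gnomAD_AF": "." if rng.random() < 0.10 else f"{af:.3g}",
        "ExAC_AF": "." if rng.random() < 0.15 else f"{af * rng.uniform(0.5, 1.5):.3g}",
    }
    if rng.random() < 0.10:
        ann["CADD_phred"] = "."
    else:
        mu, sigma = (15.0, 8.0) if nonsyn else (5.0, 4.0)
        ann["CADD_phred"] = f"{float(np.clip(rng.normal(mu, sigma), 0.0, 55.0)):.1f}"
    if nonsyn:
        ann["Polyphen2_HVAR_pred"] = _choice(rng, ("D", "P", "B", "."), (0.15, 0.15, 0.6, 0.1))
        ann["MutationTaster_pred"] = _choice(rng, ("A", "D", "N", "."), (0.05, 0.15, 0.7, 0.1))
        ann["LRT_pred"] = _choice(rng, ("D", "N", "."), (0.2, 0.7, 0.1))
        ann["MetaSVM_pred"] = _choice(rng, ("D", "T", "."), (0.1, 0.8, 0.1))
    else:
        for key in ("Polyphen2_HVAR_pred", "MutationTaster_pred", "LRT_pred", "MetaSVM_pred"):
            ann[key] = "."
    ann["GERPpp_RS"] = "." if rng.random() < 0.10 else f"{rng.uniform(-2.0, 6.0):.2f}"
    return {k: ann[k] for k in ANNOTATION_FIELDS}


_BASES = ("A", "C", "G", "T")


def _random_alleles(rng):
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


#: planted genotype patterns per model: allele counts for (proband, father, mother)
_PLANT_GENOTYPES = {
    "DN": [(1, 0, 0)],
    "AD": [(1, 1, 0)],  # father is the affected parent
    "AR": [(2, 1, 1)],
    "CH": [(1, 1, 0), (1, 0, 1)],  # paternal-specific then maternal-specific
}


def _evidence_for_count(rng, sample: str, count: int, mean_depth: float,
                        low_depth_rate: float, missing_rate: float,
                        clean: bool = False) -> GenotypeEvidence:
    if not clean and rng.random() < missing_rate:
        return GenotypeEvidence(sample=sample, gt=MISSING, depth=0, alt_depth=0)
    if clean:
        depth = int(40 + rng.integers(0, 15))
    elif rng.random() < low_depth_rate:
        depth = int(rng.integers(1, 8))
    else:
        depth = max(1, int(rng.poisson(mean_depth)))
    p_alt = {0: 0.005, 1: 0.5, 2: 0.995}[count]
    alt_depth = int(rng.binomial(depth, p_alt))
    gt = {0: REF_HOM, 1: HET, 2: ALT_HOM}[count]
    return GenotypeEvidence(sample=sample, gt=gt, depth=depth, alt_depth=alt_depth)


def simulate_cohort(config: CohortFixtureConfig) -> CohortData:
    """Simulate a cohort in memory; see :func:`generate_cohort` for files."""
    rng = np.random.default_rng(config.seed)

    samples: List[str] = []
    ped_entries: List[PedigreeEntry] = []
    planted_model = config.planted.model if config.planted else None
    for i in range(config.n_families):
        fam = f"F{i}"
        members = _family_samples(config.family_structure, i)
        proband, father, mother = members[0], members[1], members[2]
        father_status = "2" if (planted_model == "AD" and i == 0) else "1"
        ped_entries.append(PedigreeEntry(fam, proband, father, mother, "1", "affected"))
        ped_entries.append(
            PedigreeEntry(fam, father, "0", "0", "1",
                          "affected" if father_status == "2" else "unaffected")
        )
        ped_entries.append(PedigreeEntry(fam, mother, "0", "0", "2", "unaffected"))
        if config.family_structure == "quartet":
            ped_entries.append(PedigreeEntry(fam, members[3], father, mother, "2", "unaffected"))
        samples.extend(members)
    pedigree = Pedigree(ped_entries)

    # --- background sites ---------------------------------------------------
    n = config.n_background_variants
    seen_sites = set()
    sites = []
    while len(sites) < n:
        chrom = int(rng.integers(1, 23))
        pos = int(rng.integers(100_000, 50_000_000))
        if (chrom, pos) in seen_sites:
            continue
        seen_sites.add((chrom, pos))
        sites.append((chrom, pos))

    n_common = int(round(config.common_fraction * n))
    afs = np.empty(n)
    afs[:n_common] = rng.uniform(0.01, 0.5, size=n_common)
    afs[n_common:] = 10 ** rng.uniform(-6, -3, size=n - n_common)
    rng.shuffle(afs)

    rows = []  # (chrom_int, pos, ref, alt, annotations, {sample: allele count}, clean)
    for (chrom, pos), af in zip(sites, afs):
        ref, alt = _random_alleles(rng)
        ann = _background_annotations(rng, float(af))
        counts = {}
        for i in range(config.n_families):
            members = _family_samples(config.family_structure, i)
            father_alleles = (rng.random(2) < af).astype(int)
            mother_alleles = (rng.random(2) < af).astype(int)
            counts[members[1]] = int(father_alleles.sum())
            counts[members[2]] = int(mother_alleles.sum())
            for child in [members[0]] + members[3:]:
                counts[child] = int(
                    father_alleles[rng.integers(2)] + mother_alleles[rng.integers(2)]
                )
        rows.append((chrom, pos, ref, alt, ann, counts, False))

    # --- planted variant(s) -------------------------------------------------
    manifest_planted = []
    if config.planted is not None:
        spec = config.planted
        chrom = 2
        base_pos = 43_013_958
        patterns = _PLANT_GENOTYPES[spec.model]
        for k, (p_count, f_count, m_count) in enumerate(patterns):
            pos = base_pos + 500 * k
            while (chrom, pos) in seen_sites:
                pos += 1
            seen_sites.add((chrom, pos))
            ref, alt = ("G", "A") if k == 0 else ("C", "T")
            ann = dict(_PLANT_PROFILES[spec.consequence])
            ann["Gene.refGene"] = spec.gene
            ann.update(spec.annotations)
            ann = {key: ann[key] for key in ANNOTATION_FIELDS}
            counts = {}
            for i in range(config.n_families):
                members = _family_samples(config.family_structure, i)
                if i == 0:
                    counts[members[0]] = p_count
                    counts[members[1]] = f_count
                    counts[members[2]] = m_count
                    for sib in members[3:]:
                        counts[sib] = 0
                else:
                    for s in members:
                        counts[s] = 0
            rows.append((chrom, pos, ref, alt, ann, counts, True))
            manifest_planted.append(
                {"site_id": [str(chrom), pos, ref, alt], "gene": spec.gene,
                 "model": spec.model, "consequence": spec.consequence}
            )

    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))

    variants, evidence = [], []
    for chrom, pos, ref, alt, ann, counts, clean in rows:
        variants.append(
            AnnotatedVariant(chrom=str(chrom), pos=pos, ref=ref, alt=alt, annotations=ann)
        )
        evidence.append(
            [
                _evidence_for_count(
                    rng, s, counts[s], config.mean_depth,
                    config.low_depth_rate, config.missing_rate, clean=clean,
                )
                for s in samples
            ]
        )

    manifest = {
        "seed": config.seed,
        "family_structure": config.family_structure,
        "n_families": config.n_families,
        "n_background_variants": config.n_background_variants,
        "samples": samples,
        "planted": manifest_planted,
    }
    return CohortData(variants=variants, evidence=evidence, samples=samples,
                      pedigree=pedigree, manifest=manifest)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratedPaths:
    vcf: Path
    ped: Path
    manifest: Path


def _gt_string(ev: GenotypeEvidence) -> str:
    if ev.gt == MISSING:
        return "./.:.:."
    gt = {REF_HOM: "0/0", HET: "0/1", ALT_HOM: "1/1"}[ev.gt]
    ref_depth = ev.depth - ev.alt_depth
    return f"{gt}:{ref_depth},{ev.alt_depth}:{ev.depth}"


def write_cohort_vcf(cohort: CohortData, path) -> None:
    """Write the cohort as a VCF 4.2 file with GT:AD:DP sample columns."""
    lines = ["##fileformat=VCFv4.2"]
    for c in range(1, 23):
        lines.append(f"##contig=<ID={c}>")
    for name in ANNOTATION_FIELDS:
        lines.append(
            f'##INFO=<ID={name},Number=1,Type=String,Description="{name} annotation">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples)
    )
    for variant, evs in zip(cohort.variants, cohort.evidence):
        info = ";".join(f"{k}={v}" for k, v in variant.annotations.items())
        row = [variant.chrom, str(variant.pos), ".", variant.ref, variant.alt,
               ".", "PASS", info, "GT:AD:DP"]
        row += [_gt_string(e) for e in evs]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pedigree(pedigree: Pedigree, path) -> None:
    status_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    lines = [
        "\t".join([e.family_id, e.sample_id, e.father_id, e.mother_id, e.sex,
                   status_code[e.status]])
        for e in pedigree.entries
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_cohort(config: CohortFixtureConfig, out_dir) -> GeneratedPaths:
    """Generate and write a cohort fixture: VCF, PED and truth manifest.

    Identical (config, seed) pairs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    paths = GeneratedPaths(
        vcf=out_dir / "cohort.vcf", ped=out_dir / "cohort.ped",
        manifest=out_dir / "truth.json",
    )
    write_cohort_vcf(cohort, paths.vcf)
    write_pedigree(cohort.pedigree, paths.ped)
    paths.manifest.write_text(
        json.dumps(cohort.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


# ---------------------------------------------------------------------------
# demo annotation table
# ---------------------------------------------------------------------------

#: Synthetic demo table: ten annotated variants shaped like the top of a
#: recessive-filtered ranking in a consanguineous rare-disease family — one
#: stop-gain, one frameshift insertion and eight missense calls with mixed
#: predictor support.  Gene symbols are real, coordinates are invented.
_DEMO_ROWS = [
    # chrom, pos, ref, alt, gene, exonic_func, gnomad, lrt, mt, pp2, cadd, metasvm, gerp
    ("2", 43013958, "G", "A", "HAAO", "stopgain", "4.07e-06", "D", "A", ".", "39", ".", "5.26"),
    ("12", 70750321, "T", "TAAAAA", "CNOT2", "frameshift_insertion", ".", ".", ".", ".", ".", ".", "."),
    ("8", 145583219, "G", "A", "SLC52A2", "nonsynonymous_SNV", "5.14e-05", "D", "D", "D", "28.3", "D", "4.69"),
    ("8", 144800711, "C", "T", "MAPK15", "nonsynonymous_SNV", "0.000384", "D", "D", "D", "32", "T", "4.02"),
    ("5", 175819608, "A", "G", "CLTB", "nonsynonymous_SNV", "0.000134", "D", "D", "P", "21.9", "T", "4.16"),
    ("2", 73300455, "C", "A", "SMYD5", "nonsynonymous_SNV", ".", "D", "D", "D", "28.4", "T", "3.76"),
    ("2", 171680190, "C", "T", "GAD1", "nonsynonymous_SNV", "9.02e-05", "N", "D", "P", "26.4", "D", "4.66"),
    ("9", 124508043, "T", "A", "DAB2IP", "nonsynonymous_SNV", "6.23e-05", "N", "D", "D", "18.1", "T", "4.69"),
    ("2", 54109321, "C", "A", "PSME4", "nonsynonymous_SNV", ".", "D", "D", "P", "20.3", "T", "4.42"),
    ("2", 219757877, "C", "G", "WNT10A", "nonsynonymous_SNV", ".", "D", "D", "P", "25.5", "T", "3.57"),
]

DEMO_TSV_COLUMNS = (
    "Chr", "Pos", "Ref", "Alt", "Gene.refGene", "Func.refGene",
    "ExonicFunc.refGene", "gnomAD_AF", "LRT_pred", "MutationTaster_pred",
    "Polyphen2_HVAR_pred", "CADD_phred", "MetaSVM_pred", "GERPpp_RS",
)


def write_demo_annotated_tsv(path) -> Path:
    """Write the built-in ten-variant demo annotation table (synthetic)."""
    lines = ["\t".join(DEMO_TSV_COLUMNS)]
    for chrom, pos, ref, alt, gene, exonic, gnomad, lrt, mt, pp2, cadd, msvm, gerp in _DEMO_ROWS:
        lines.append("\t".join([
            chrom, str(pos), ref, alt, gene, "exonic", exonic, gnomad,
            lrt, mt, pp2, cadd, msvm, gerp,
        ]))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
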