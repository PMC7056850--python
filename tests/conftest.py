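"""Shared fixtures and independent oracles used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from varprio import (
    AnnotatedVariant,
    PPF,
    ScoringRule,
    VPOL,
    VPOLRecord,
    load_default_ppf,
)
from varprio.fixtures import write_demo_annotated_tsv

TOKEN_VOCAB = ("D", "T", "P", "B", "A", "N", "stopgain", "nonsynonymous_SNV")


def make_variant(chrom="1", pos=100, ref="A", alt="T", **annotations):
    return AnnotatedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                            annotations={k: str(v) for k, v in annotations.items()})


def make_record(variant=None, raw=0, normalized=0.0, genotypes=None, rank=0, **ann):
    return VPOLRecord(
        variant=variant or make_variant(**ann), raw_score=raw,
        normalized_score=normalized, encoded_genotypes=dict(genotypes or {}),
        rank=rank,
    )


def random_scoring_fixture(rng, max_variants=100, max_fields=20):
    """A random (variants, ppf) pair exercising both rule kinds.

    Fields carry random numeric strings, categorical tokens or missing
    values; each field gets 0-3 random rules (categorical literals or
    half-open intervals, weights in [-5, 5]).
    """
    n_fields = int(rng.integers(1, max_fields + 1))
    n_variants = int(rng.integers(1, max_variants + 1))
    fields = [f"f{i}" for i in range(n_fields)]

    rules = []
    for name in fields:
        for _ in range(int(rng.integers(0, 4))):
            weight = int(rng.integers(-5, 6))
            if rng.random() < 0.5:
                rules.append(ScoringRule(field=name, kind="categorical",
                                         literal=TOKEN_VOCAB[rng.integers(len(TOKEN_VOCAB))],
                                         weight=weight))
            else:
                lo = float(np.round(rng.uniform(-10, 40), 2))
                hi = float(np.round(lo + rng.uniform(0.5, 30), 2))
                if rng.random() < 0.2:
                    lo = float("-inf")
                if rng.random() < 0.2:
                    hi = float("inf")
                rules.append(ScoringRule(field=name, kind="interval",
                                         lower=lo, upper=hi, weight=weight))
    if not rules:  # a PPF needs at least one scoring rule
        rules.append(ScoringRule(field=fields[0], kind="categorical",
                                 literal="D", weight=1))

    variants = []
    for i in range(n_variants):
        ann = {}
        for name in fields:
            u = rng.random()
            if u < 0.2:
                ann[name] = "."
            elif u < 0.6:
                ann[name] = f"{rng.uniform(-15, 50):.2f}"
            else:
                ann[name] = TOKEN_VOCAB[rng.integers(len(TOKEN_VOCAB))]
        variants.append(AnnotatedVariant(chrom="1", pos=i + 1, ref="A", alt="T",
                                         annotations=ann))
    return variants, PPF(scoring=rules)


def naive_score(variant, ppf):
    """Rule-by-rule scoring oracle, written independently of the package path."""
    total = 0
    for fname in sorted({r.field for r in ppf.scoring}):
        value = variant.annotations.get(fname, ".")
        if value == ".":
            continue
        best = None
        for rule in ppf.scoring:
            if rule.field != fname:
                continue
            if rule.kind == "categorical":
                hit = value == rule.literal
            else:
                try:
                    x = float(value)
                except ValueError:
                    hit = False
                else:
                    hit = rule.lower <= x < rule.upper
            if hit and (best is None or rule.weight > best):
                best = rule.weight
        if best is not None:
            total += best
    return total


@pytest.fixture(scope="session")
def default_ppf():
    return load_default_ppf()


@pytest.fixture(scope="session")
def demo_tsv(tmp_path_factory):
    path = tmp_path_factory.mktemp("demo") / "demo_variants.tsv"
    return write_demo_annotated_tsv(path)
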