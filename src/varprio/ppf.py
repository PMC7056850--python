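"""The prioritization parameter file (PPF): model, generation, parsing.

A PPF is the single configuration object that drives a prioritization run.
It holds, in order of application:

* **filters** — hard exclusion rules on annotation values (e.g. drop any
  variant whose ``gnomAD_AF`` exceeds 0.001, i.e. the 0.1% minor-allele
  frequency screen used for rare-disease work, or drop synonymous calls);
* **scoring** — weighted rules whose matched weights are summed into the
  variant's priority score: categorical rules match a literal annotation
  value, numeric rules match a half-open interval ``[lower, upper)``;
* **qc** — per-sample genotype quality thresholds (minimum coverage depth,
  minimum allele balance);
* **output** — the raw-score cutoff below which variants are left out of the
  ranked list.

The on-disk dialect is line-oriented plain text: ``#`` comment lines,
``[section]`` headers and tab-separated rule lines, so a template generated
from real data remains hand-editable.  A ready-to-use default PPF for
rare-disease cohorts ships with the package (:func:`default_ppf_path`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .exceptions import ParseError, ValidationError
from .model import MISSING_TOKEN, AnnotatedVariant

#: number of distinct values listed per character field in generated templates
DISTINCT_VALUE_CAP = 20


def _try_float(text: str) -> Optional[float]:
    try:
        return float(text)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# rule types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringRule:
    """A weighted match on one annotation field.

    ``kind`` is ``"categorical"`` (exact literal match on the raw string) or
    ``"interval"`` (numeric match on the half-open interval
    ``[lower, upper)``; either bound may be infinite).  Weights are integers
    and may be negative.
    """

    field: str
    kind: str
    weight: int
    literal: Optional[str] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self):
        if not self.field:
            raise ValidationError("scoring rule with empty field name")
        if self.kind == "categorical":
            if self.literal is None:
                raise ValidationError(f"categorical rule on {self.field!r} needs a literal")
        elif self.kind == "interval":
            if self.lower is None or self.upper is None:
                raise ValidationError(f"interval rule on {self.field!r} needs two bounds")
            if not self.lower < self.upper:
                raise ValidationError(
                    f"interval rule on {self.field!r}: lower bound {self.lower} "
                    f"must be < upper bound {self.upper}"
                )
        else:
            raise ValidationError(f"unknown scoring rule kind {self.kind!r}")

    def matches(self, value: str) -> bool:
        """Whether this rule fires for a (non-missing) annotation value."""
        if value == MISSING_TOKEN:
            return False
        if self.kind == "categorical":
            return value == self.literal
        x = _try_float(value)
        if x is None:
            return False
        return self.lower <= x < self.upper


@dataclass(frozen=True)
class FilterRule:
    """A hard exclusion rule on one annotation field.

    ``kind``: ``equals`` (drop on exact literal match), ``greater`` / ``less``
    (drop when the numeric value exceeds / falls below ``value``).  When the
    annotation is missing, ``missing_passes`` decides; it defaults to True —
    absence from e.g. a population-frequency database is evidence of rarity,
    not of commonness.
    """

    field: str
    kind: str
    value: str
    missing_passes: bool = True

    def __post_init__(self):
        if not self.field:
            raise ValidationError("filter rule with empty field name")
        if self.kind not in ("equals", "greater", "less"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.kind in ("greater", "less") and _try_float(self.value) is None:
            raise ValidationError(
                f"filter on {self.field!r}: numeric kind {self.kind!r} needs a "
                f"numeric threshold, got {self.value!r}"
            )

    @property
    def threshold(self) -> Optional[float]:
        return _try_float(self.value) if self.kind in ("greater", "less") else None


@dataclass(frozen=True)
class QCThresholds:
    """Per-sample genotype QC: minimum depth and allele balance.

    Defaults flag calls covered by fewer than 8 reads or with an allele
    balance outside [0.25, 0.75] (het) / below 0.75 (hom-alt).
    """

    min_depth: int = 8
    min_allele_balance: float = 0.25

    def __post_init__(self):
        if self.min_depth < 0:
            raise ValidationError("min_depth must be >= 0")
        if not (0 < self.min_allele_balance <= 0.5):
            raise ValidationError("min_allele_balance must lie in (0, 0.5]")


@dataclass
class PPF:
    """A parsed prioritization parameter file."""

    filters: list = field(default_factory=list)
    scoring: list = field(default_factory=list)
    qc: QCThresholds = field(default_factory=QCThresholds)
    score_cutoff: int = 0

    def scoring_by_field(self) -> dict:
        """Scoring rules grouped by annotation field (cached)."""
        cached = getattr(self, "_by_field", None)
        if cached is None:
            cached = {}
            for rule in self.scoring:
                cached.setdefault(rule.field, []).append(rule)
            self._by_field = cached
        return cached

    def referenced_fields(self) -> set:
        return {r.field for r in self.filters} | {r.field for r in self.scoring}


# ---------------------------------------------------------------------------
# field profiling
# ---------------------------------------------------------------------------

@dataclass
class FieldProfile:
    """Observed type and value range of one annotation field.

    A field is *numeric* iff every non-missing observed value parses as a
    number and at least one non-missing value exists; otherwise *character*.
    """

    field: str
    inferred_type: str  # numeric | character
    n_values: int
    missing_count: int
    min_value: Optional[float] = None
    max_value: Optional[float] = None
    distinct_values: list = field(default_factory=list)
    n_more_distinct: int = 0

    def describe(self) -> str:
        if self.inferred_type == "numeric":
            return (
                f"{self.field}: numeric, range [{self.min_value:g}, {self.max_value:g}], "
                f"missing {self.missing_count}/{self.n_values}"
            )
        shown = ", ".join(self.distinct_values)
        more = f" ...and {self.n_more_distinct} more" if self.n_more_distinct else ""
        return (
            f"{self.field}: character, values {{{shown}}}{more}, "
            f"missing {self.missing_count}/{self.n_values}"
        )


def profile_fields(variants: Sequence[AnnotatedVariant]) -> list:
    """Profile every distinct annotation field across *variants*.

    Returns one :class:`FieldProfile` per field, in first-seen order.  The
    distinct-value list of character fields is capped at
    :data:`DISTINCT_VALUE_CAP`, the remainder counted.
    """
    values: dict = {}
    for v in variants:
        for name, value in v.annotations.items():
            values.setdefault(name, []).append(value)

    profiles = []
    for name, vals in values.items():
        non_missing = [x for x in vals if x != MISSING_TOKEN]
        missing = len(vals) - len(non_missing)
        numbers = [_try_float(x) for x in non_missing]
        if non_missing and all(x is not None for x in numbers):
            profiles.append(
                FieldProfile(
                    field=name, inferred_type="numeric", n_values=len(vals),
                    missing_count=missing, min_value=min(numbers), max_value=max(numbers),
                )
            )
        else:
            distinct = sorted(set(non_missing))
            profiles.append(
                FieldProfile(
                    field=name, inferred_type="character", n_values=len(vals),
                    missing_count=missing,
                    distinct_values=distinct[:DISTINCT_VALUE_CAP],
                    n_more_distinct=max(0, len(distinct) - DISTINCT_VALUE_CAP),
                )
            )
    return profiles


def generate_ppf_template(profiles: Sequence[FieldProfile], path) -> None:
    """Write a valid, zero-weight PPF template describing *profiles*.

    Every field appears with its observed type/range as a comment and one or
    more weight-0 scoring rules, so the template parses as-is and scores
    everything 0 until the user edits the weights.
    """
    if not profiles:
        raise ValidationError("cannot generate a template from zero field profiles")
    lines = [
        "# Prioritization parameter template (auto-generated).",
        "# Edit weights, add filter rules, then rerun prioritization.",
        "",
        "[filters]",
        "# <field>\t<equals|greater|less>\t<value>\t[missing_passes true|false]",
        "",
        "[scoring]",
    ]
    for p in profiles:
        lines.append(f"# {p.describe()}")
        if p.inferred_type == "numeric":
            lines.append(f"{p.field}\tinterval\t-inf\tinf\t0")
        elif p.distinct_values:
            for value in p.distinct_values:
                lines.append(f"{p.field}\tcategorical\t{value}\t0")
        else:
            lines.append(f"{p.field}\tcategorical\t{MISSING_TOKEN}\t0")
    lines += [
        "",
        "[qc]",
        "min_depth\t8",
        "min_allele_balance\t0.25",
        "",
        "[output]",
        "score_cutoff\t0",
        "",
    ]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# parse / serialize
# ---------------------------------------------------------------------------

_SECTIONS = ("[filters]", "[scoring]", "[qc]", "[output]")
_TRUE = {"true", "t", "yes", "1"}
_FALSE = {"false", "f", "no", "0"}


def _split_rule_line(line: str) -> list:
    # tab is the canonical separator (literals may contain spaces);
    # fall back to whitespace splitting for hand-typed files
    return line.split("\t") if "\t" in line else line.split()


def _parse_bool(token: str, line_no: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ParseError(f"line {line_no}: expected true/false, got {token!r}")


def _parse_bound(token: str, line_no: int) -> float:
    x = _try_float(token)
    if x is None:
        raise ParseError(f"line {line_no}: expected a numeric bound, got {token!r}")
    return x


def parse_ppf(path) -> PPF:
    """Parse a PPF file; raises :class:`ParseError`/:class:`ValidationError`
    with line numbers on malformed content."""
    filters, scoring = [], []
    qc_kwargs: dict = {}
    cutoff = 0
    section = None
    with open(path, "rt", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                if line not in _SECTIONS:
                    raise ParseError(f"{path}: line {line_no}: unknown section {line!r}")
                section = line
                continue
            if section is None:
                raise ParseError(f"{path}: line {line_no}: rule line before any section")
            tokens = _split_rule_line(line)
            try:
                if section == "[filters]":
                    if len(tokens) not in (3, 4):
                        raise ParseError(f"line {line_no}: filter needs 3 or 4 fields")
                    missing_passes = True
                    if len(tokens) == 4:
                        missing_passes = _parse_bool(tokens[3], line_no)
                    filters.append(
                        FilterRule(field=tokens[0], kind=tokens[1], value=tokens[2],
                                   missing_passes=missing_passes)
                    )
                elif section == "[scoring]":
                    if len(tokens) >= 2 and tokens[1] == "categorical":
                        if len(tokens) != 4:
                            raise ParseError(f"line {line_no}: categorical rule needs 4 fields")
                        scoring.append(
                            ScoringRule(field=tokens[0], kind="categorical",
                                        literal=tokens[2], weight=int(tokens[3]))
                        )
                    elif len(tokens) >= 2 and tokens[1] == "interval":
                        if len(tokens) != 5:
                            raise ParseError(f"line {line_no}: interval rule needs 5 fields")
                        scoring.append(
                            ScoringRule(field=tokens[0], kind="interval",
                                        lower=_parse_bound(tokens[2], line_no),
                                        upper=_parse_bound(tokens[3], line_no),
                                        weight=int(tokens[4]))
                        )
                    else:
                        raise ParseError(
                            f"line {line_no}: scoring rule kind must be "
                            f"'categorical' or 'interval'"
                        )
                elif section == "[qc]":
                    if len(tokens) != 2:
                        raise ParseError(f"line {line_no}: qc line needs 'key value'")
                    key, value = tokens
                    if key == "min_depth":
                        qc_kwargs["min_depth"] = int(value)
                    elif key == "min_allele_balance":
                        qc_kwargs["min_allele_balance"] = float(value)
                    else:
                        raise ParseError(f"line {line_no}: unknown qc key {key!r}")
                elif section == "[output]":
                    if len(tokens) != 2 or tokens[0] != "score_cutoff":
                        raise ParseError(f"line {line_no}: expected 'score_cutoff <int>'")
                    cutoff = int(tokens[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {line_no}: {exc}") from exc
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {line_no}: {exc}") from exc
            except ParseError as exc:
                raise ParseError(f"{path}: {exc}") from exc
    return PPF(filters=filters, scoring=scoring, qc=QCThresholds(**qc_kwargs),
               score_cutoff=cutoff)


def _format_bound(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:g}"


def serialize_ppf(ppf: PPF) -> str:
    """Render a PPF back to its on-disk dialect (rule order preserved)."""
    lines = ["[filters]"]
    for r in ppf.filters:
        lines.append(f"{r.field}\t{r.kind}\t{r.value}\t{str(r.missing_passes).lower()}")
    lines.append("[scoring]")
    for r in ppf.scoring:
        if r.kind == "categorical":
            lines.append(f"{r.field}\tcategorical\t{r.literal}\t{r.weight}")
        else:
            lines.append(
                f"{r.field}\tinterval\t{_format_bound(r.lower)}\t"
                f"{_format_bound(r.upper)}\t{r.weight}"
            )
    lines += [
        "[qc]",
        f"min_depth\t{ppf.qc.min_depth}",
        f"min_allele_balance\t{ppf.qc.min_allele_balance:g}",
        "[output]",
        f"score_cutoff\t{ppf.score_cutoff}",
        "",
    ]
    return "\n".join(lines)


def write_ppf(ppf: PPF, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(serialize_ppf(ppf))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_ppf(ppf: PPF, observed_fields: Iterable[str]) -> ValidationReport:
    """Check a PPF against the annotation fields actually present.

    Rules on absent fields are inert (warning, the run proceeds); overlapping
    numeric intervals on one field are resolved by taking the maximum weight
    (warning); a PPF without any scoring rule cannot prioritize (error).
    """
    observed = set(observed_fields)
    report = ValidationReport()
    for name in sorted(ppf.referenced_fields() - observed):
        report.warnings.append(
            f"field {name!r} is referenced by the PPF but absent from the input; "
            f"its rules are inert"
        )
    for fname, rules in ppf.scoring_by_field().items():
        intervals = [r for r in rules if r.kind == "interval"]
        for i, a in enumerate(intervals):
            for b in intervals[i + 1:]:
                if a.lower < b.upper and b.lower < a.upper:
                    report.warnings.append(
                        f"field {fname!r}: overlapping intervals "
                        f"[{_format_bound(a.lower)}, {_format_bound(a.upper)}) and "
                        f"[{_format_bound(b.lower)}, {_format_bound(b.upper)}); "
                        f"the maximum weight among matches applies"
                    )
    if not ppf.scoring:
        report.errors.append("PPF defines no scoring rules; prioritization is impossible")
    return report


def default_ppf_path() -> str:
    """Path of the default rare-disease PPF shipped with the package."""
    return str(resources.files("varprio").joinpath("data/default.ppf"))


def load_default_ppf() -> PPF:
    return parse_ppf(default_ppf_path())
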