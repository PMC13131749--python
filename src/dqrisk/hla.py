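"""HLA nomenclature parsing and DQ heterodimer risk-genotype calling.

Celiac disease (CeD) risk is dominated by which HLA-DQ αβ heterodimers a
person can assemble from the products of their two DQA1 (α chain) and two
DQB1 (β chain) alleles.  The four CeD-compatible heterodimers and the
haplotypes encoding them in *cis* are

    DQ2.5  DQA1*05:01–DQB1*02:01
    DQ2.2  DQA1*02:01–DQB1*02:02
    DQ8.1  DQA1*03:01–DQB1*03:02
    DQ7.5  DQA1*05:05–DQB1*03:01

DQ2.5 can also be assembled in *trans* by a DQ2.2/DQ7.5 genotype: the
DQ7.5 chromosome contributes a DQA1*05 α chain and the DQ2.2 chromosome a
DQB1*02 β chain.  This module classifies haplotypes, calls cis/trans DQ2.5
carriage, and assigns the four-level risk category used throughout the
pipeline.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HlaAllele",
    "Haplotype",
    "DqHaplotypeClass",
    "DqRiskGenotype",
    "HlaParseError",
    "DEFAULT_RISK_MAP",
    "parse_allele",
    "classify_dq_haplotype",
    "call_heterodimers",
    "assign_risk_category",
    "infer_dq25_from_tagsnp",
    "concordance",
]

VALID_LOCI = ("A", "B", "C", "DPB1", "DQA1", "DQB1", "DRB1")

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<f1>\d+):(?P<f2>\d+)(?P<rest>(?::\d+)*[NLSCAQ]?)$"
)


class HlaParseError(ValueError):
    """Raised when an HLA allele string cannot be parsed."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A two-field HLA allele, e.g. ``DQB1*02:01``.

    ``field1`` is the allele group, ``field2`` the specific protein.
    Comparison and hashing are by ``(locus, field1, field2)``.
    """

    locus: str
    field1: int
    field2: int

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise HlaParseError(f"unknown HLA locus: {self.locus!r}")
        if self.field1 <= 0 or self.field2 <= 0:
            raise HlaParseError(
                f"allele fields must be positive: {self.field1}:{self.field2}"
            )

    def __str__(self) -> str:
        return f"{self.locus}*{self.field1:02d}:{self.field2:02d}"


def parse_allele(text: str) -> HlaAllele:
    """Parse ``"LOCUS*gg:pp"`` into an :class:`HlaAllele`.

    Higher-resolution fields and expression suffixes after the protein field
    (e.g. ``DQB1*02:01:01`` or ``B*44:02:01:02S``) are truncated to two
    fields with a warning.

    Raises
    ------
    HlaParseError
        If the locus is unknown or the string is malformed.
    """
    if not isinstance(text, str):
        raise HlaParseError(f"expected an allele string, got {type(text).__name__}")
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise HlaParseError(f"malformed HLA allele string: {text!r}")
    locus = m.group("locus")
    if locus not in VALID_LOCI:
        raise HlaParseError(f"unknown HLA locus {locus!r} in {text!r}")
    if m.group("rest"):
        warnings.warn(
            f"truncating {text!r} to two-field resolution", stacklevel=2
        )
    return HlaAllele(locus, int(m.group("f1")), int(m.group("f2")))


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's multi-locus HLA allele combination.

    At most one allele per locus; DQA1 and DQB1 are required for DQ
    classification but other loci are optional pass-through.
    """

    alleles: Mapping[str, HlaAllele] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frozen = {}
        for locus, allele in dict(self.alleles).items():
            if allele.locus != locus:
                raise ValueError(
                    f"allele {allele} filed under locus {locus!r}"
                )
            frozen[locus] = allele
        object.__setattr__(self, "alleles", frozen)

    @classmethod
    def from_strings(cls, alleles: Iterable[str]) -> "Haplotype":
        parsed = [parse_allele(a) for a in alleles]
        loci = [a.locus for a in parsed]
        if len(set(loci)) != len(loci):
            raise ValueError(f"duplicate locus in haplotype: {sorted(loci)}")
        return cls({a.locus: a for a in parsed})

    def __getitem__(self, locus: str) -> HlaAllele:
        return self.alleles[locus]

    def get(self, locus: str) -> HlaAllele | None:
        return self.alleles.get(locus)

    def __contains__(self, allele: HlaAllele) -> bool:
        return self.alleles.get(allele.locus) == allele

    def __str__(self) -> str:
        return "~".join(
            str(self.alleles[l]) for l in VALID_LOCI if l in self.alleles
        )

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.alleles.items())))


class DqHaplotypeClass(str, Enum):
    """The four CeD-compatible DQ haplotype classes, plus OTHER."""

    DQ2_5 = "DQ2.5"
    DQ2_2 = "DQ2.2"
    DQ8_1 = "DQ8.1"
    DQ7_5 = "DQ7.5"
    OTHER = "X"

    def __str__(self) -> str:
        return self.value


_DQ_CLASS_TABLE = {
    (HlaAllele("DQA1", 5, 1), HlaAllele("DQB1", 2, 1)): DqHaplotypeClass.DQ2_5,
    (HlaAllele("DQA1", 2, 1), HlaAllele("DQB1", 2, 2)): DqHaplotypeClass.DQ2_2,
    (HlaAllele("DQA1", 3, 1), HlaAllele("DQB1", 3, 2)): DqHaplotypeClass.DQ8_1,
    (HlaAllele("DQA1", 5, 5), HlaAllele("DQB1", 3, 1)): DqHaplotypeClass.DQ7_5,
}


def classify_dq_haplotype(dqa1: HlaAllele, dqb1: HlaAllele) -> DqHaplotypeClass:
    """Classify a (DQA1, DQB1) cis pair into a DQ haplotype class.

    Exact two-field match against the four risk haplotypes; anything else
    is OTHER.
    """
    if dqa1.locus != "DQA1":
        raise ValueError(f"expected a DQA1 allele, got {dqa1}")
    if dqb1.locus != "DQB1":
        raise ValueError(f"expected a DQB1 allele, got {dqb1}")
    return _DQ_CLASS_TABLE.get((dqa1, dqb1), DqHaplotypeClass.OTHER)


def _class_pair_key(
    a: DqHaplotypeClass, b: DqHaplotypeClass
) -> frozenset | tuple:
    # frozenset collapses order; homozygous pairs need the tuple form
    return frozenset((a, b)) if a != b else (a, a)


def _pair(a: str, b: str) -> frozenset | tuple:
    ca, cb = DqHaplotypeClass(a), DqHaplotypeClass(b)
    return _class_pair_key(ca, cb)


#: Default risk-category map over all 15 unordered DQ-class pairs.  The
#: published figure orders DQ2.5/DQ2.5 above DQ2.5/DQ2.2 above the rest, with
#: DQ7.5/X as the low-risk reference; the exact moderate/low membership is a
#: package decision and can be overridden per analysis.
DEFAULT_RISK_MAP: dict = {
    _pair("DQ2.5", "DQ2.5"): "high",
    _pair("DQ2.5", "DQ2.2"): "high",
    _pair("DQ2.5", "DQ7.5"): "moderate",
    _pair("DQ2.5", "DQ8.1"): "moderate",
    _pair("DQ2.5", "X"): "moderate",
    _pair("DQ2.2", "DQ7.5"): "moderate",
    _pair("DQ2.2", "DQ2.2"): "moderate",
    _pair("DQ8.1", "DQ8.1"): "moderate",
    _pair("DQ2.2", "X"): "low",
    _pair("DQ2.2", "DQ8.1"): "low",
    _pair("DQ8.1", "DQ7.5"): "low",
    _pair("DQ8.1", "X"): "low",
    _pair("DQ7.5", "DQ7.5"): "low",
    _pair("DQ7.5", "X"): "low",
    _pair("X", "X"): "none",
}

RISK_CATEGORIES = ("high", "moderate", "low", "none")


def assign_risk_category(
    classes: Sequence[DqHaplotypeClass],
    risk_map: Mapping | None = None,
) -> str:
    """Map an unordered pair of DQ haplotype classes to a risk category.

    The default map is :data:`DEFAULT_RISK_MAP`; pass ``risk_map`` to match
    a different published categorization.  Total and deterministic.
    """
    if len(classes) != 2:
        raise ValueError("expected exactly two DQ haplotype classes")
    table = DEFAULT_RISK_MAP if risk_map is None else risk_map
    key = _class_pair_key(classes[0], classes[1])
    category = table.get(key)
    if category is None:
        raise ValueError(f"risk map has no entry for pair {set(classes)}")
    return category


@dataclass(frozen=True)
class DqRiskGenotype:
    """The DQ-relevant summary of one participant's two haplotypes.

    ``dq25_cis`` — at least one chromosome carries the full DQ2.5 haplotype.
    ``dq25_trans`` — the DQ2.5 heterodimer is assembled across chromosomes,
    which happens exactly for the {DQ2.2, DQ7.5} genotype.
    """

    haplotype_classes: tuple
    dq25_cis: bool
    dq25_trans: bool
    risk_category: str

    @property
    def dq25_carrier(self) -> bool:
        """Can this genotype present gluten peptides on DQ2.5 (cis or trans)?"""
        return self.dq25_cis or self.dq25_trans

    def __str__(self) -> str:
        a, b = self.haplotype_classes
        return f"{a}/{b}"


def call_heterodimers(
    hap1: Haplotype,
    hap2: Haplotype,
    risk_map: Mapping | None = None,
) -> DqRiskGenotype:
    """Call cis/trans DQ2.5 carriage and risk category for a genotype.

    Symmetric in its arguments.  Both haplotypes must carry DQA1 and DQB1.
    """
    for i, hap in enumerate((hap1, hap2), start=1):
        for locus in ("DQA1", "DQB1"):
            if hap.get(locus) is None:
                raise ValueError(f"haplotype {i} is missing {locus}")
    c1 = classify_dq_haplotype(hap1["DQA1"], hap1["DQB1"])
    c2 = classify_dq_haplotype(hap2["DQA1"], hap2["DQB1"])
    return call_heterodimers_from_classes(c1, c2, risk_map=risk_map)


def call_heterodimers_from_classes(
    c1: DqHaplotypeClass,
    c2: DqHaplotypeClass,
    risk_map: Mapping | None = None,
) -> DqRiskGenotype:
    """As :func:`call_heterodimers`, starting from pre-classified haplotypes."""
    # canonical order so the genotype label is orientation-free
    order = list(DqHaplotypeClass)
    a, b = sorted((c1, c2), key=order.index)
    cis = DqHaplotypeClass.DQ2_5 in (a, b)
    trans = {a, b} == {DqHaplotypeClass.DQ2_2, DqHaplotypeClass.DQ7_5}
    category = assign_risk_category((a, b), risk_map=risk_map)
    return DqRiskGenotype((a, b), cis, trans, category)


def infer_dq25_from_tagsnp(dosage: int) -> bool:
    """Infer DQ2.5 carriage from the rs2187668 risk-allele dosage.

    rs2187668 is the standard tagSNP for the DQ2.5 haplotype; carrier iff
    dosage ≥ 1.
    """
    if dosage not in (0, 1, 2):
        raise ValueError(f"tagSNP dosage must be 0, 1 or 2, got {dosage!r}")
    return dosage >= 1


def concordance(calls_a: Sequence[bool], calls_b: Sequence[bool]) -> float:
    """Fraction of positions where two call vectors agree, in [0, 1]."""
    if len(calls_a) != len(calls_b):
        raise ValueError(
            f"call vectors differ in length: {len(calls_a)} vs {len(calls_b)}"
        )
    if len(calls_a) == 0:
        raise ValueError("cannot compute concordance of empty call vectors")
    agree = sum(bool(x) == bool(y) for x, y in zip(calls_a, calls_b))
    return agree / len(calls_a)
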