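"""KIR locus registry and allele-name handling.

KIR alleles follow the official nomenclature ``LOCUS*ddddd``: the first three
digits identify the encoded protein (the allotype), digits four and five
distinguish synonymous coding changes, and a trailing ``N`` marks a null
(unexpressed) allele.  Several loci are allelic series of a single ancestral
locus and are reported jointly in per-locus statistics (KIR2DL2/KIR2DL3 as
KIR2DL23, KIR3DL1/KIR3DS1 as KIR3DL1S1, KIR2DS3/KIR2DS5 as KIR2DS35,
KIR2DL5A/KIR2DL5B as KIR2DL5AB).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Individual KIR gene names, in genomic order (centromere to telomere).
KIR_GENE_ORDER: tuple[str, ...] = (
    "KIR3DL3",
    "KIR2DS2",
    "KIR2DL2",
    "KIR2DL3",
    "KIR2DL5B",
    "KIR2DS3",
    "KIR2DP1",
    "KIR2DL1",
    "KIR3DP1",
    "KIR2DL4",
    "KIR3DL1",
    "KIR3DS1",
    "KIR2DL5A",
    "KIR2DS5",
    "KIR2DS1",
    "KIR2DS4",
    "KIR3DL2",
)

#: Allelic series reported jointly under a combined label.
COMBINED_SERIES: dict[str, tuple[str, ...]] = {
    "KIR2DL23": ("KIR2DL2", "KIR2DL3"),
    "KIR3DL1S1": ("KIR3DL1", "KIR3DS1"),
    "KIR2DS35": ("KIR2DS3", "KIR2DS5"),
    "KIR2DL5AB": ("KIR2DL5A", "KIR2DL5B"),
}

#: Reverse map: gene -> series label (identity for genes outside a series).
SERIES_OF_GENE: dict[str, str] = {g: g for g in KIR_GENE_ORDER}
for _label, _members in COMBINED_SERIES.items():
    for _g in _members:
        SERIES_OF_GENE[_g] = _label

#: Framework genes present on essentially all haplotypes (copy 2 in a
#: standard diploid unless a structural variant removes one).
FRAMEWORK_LOCI: tuple[str, ...] = ("KIR3DL3", "KIR3DP1", "KIR2DL4", "KIR3DL2")

#: Pseudogenes: copy number is determined but no alleles are called.
PSEUDOGENES: tuple[str, ...] = ("KIR2DP1", "KIR3DP1")

VALID_LOCI: frozenset[str] = frozenset(KIR_GENE_ORDER) | frozenset(COMBINED_SERIES)

HLA_LOCI: tuple[str, ...] = ("A", "B", "C")


class NomenclatureError(ValueError):
    """Raised for malformed allele names or unknown loci."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A KIR allele name at three-digit (protein) or higher resolution.

    Parameters
    ----------
    locus : str
        A gene from :data:`KIR_GENE_ORDER` or a combined series label.
    digits : str
        Numeric part of the name (three or more digits).
    null_flag : bool
        True when the allele is a null (``N``-suffixed) variant.
    """

    locus: str
    digits: str
    null_flag: bool = False

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise NomenclatureError(f"unknown KIR locus: {self.locus!r}")
        if len(self.digits) < 3 or not self.digits.isdigit():
            raise NomenclatureError(
                f"allele digits must be >=3 numerals, got {self.digits!r}"
            )

    @property
    def protein_digits(self) -> str:
        return self.digits[:3]

    @property
    def full_digits(self) -> str:
        return self.digits

    def __str__(self) -> str:
        return f"{self.locus}*{self.digits}{'N' if self.null_flag else ''}"

    @classmethod
    def parse(cls, text: str, locus: str | None = None) -> "AlleleName":
        """Parse ``KIR2DL1*00201`` (or bare ``00201`` when *locus* is given)."""
        text = text.strip()
        if "*" in text:
            loc, _, rest = text.partition("*")
        else:
            if locus is None:
                raise NomenclatureError(f"no locus in allele name {text!r}")
            loc, rest = locus, text
        null = rest.endswith("N")
        if null:
            rest = rest[:-1]
        return cls(locus=loc, digits=rest, null_flag=null)


def truncate_resolution(allele: AlleleName, level: int = 3) -> AlleleName:
    """Truncate an allele name to *level* digits (3 = allotype resolution).

    The null suffix is retained: a null allele stays distinguishable from the
    expressed protein it would otherwise collapse onto.  Idempotent.
    """
    if level not in (3, 5):
        raise ValueError(f"resolution level must be 3 or 5, got {level}")
    if len(allele.digits) < level:
        raise NomenclatureError(
            f"{allele} has fewer than {level} digits; cannot truncate"
        )
    if len(allele.digits) == level:
        return allele
    return AlleleName(allele.locus, allele.digits[:level], allele.null_flag)


def series_label(gene: str) -> str:
    """Joint reporting label for a gene (e.g. KIR2DL2 -> KIR2DL23)."""
    if gene not in SERIES_OF_GENE:
        raise NomenclatureError(f"unknown KIR gene: {gene!r}")
    return SERIES_OF_GENE[gene]
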