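"""Genotype containers and readers/writers for the tabular input formats.

The KIR genotype table is TSV with one row per individual.  The first column
is the individual id; every other column is named after a KIR gene and holds
``<copy>:<allele>+<allele>+...`` — the locus copy number followed by exactly
that many allele calls (digit strings, optional trailing ``N``).  ``NEG``,
``0`` or an empty cell encode copy 0.  Pseudogene cells may carry the copy
number alone.  The HLA table is TSV with columns ``A_1 A_2 B_1 B_2 C_1 C_2``
holding two-field names such as ``C*04:01`` (homozygotes repeat the allele).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .nomenclature import (
    AlleleName,
    FRAMEWORK_LOCI,
    KIR_GENE_ORDER,
    NomenclatureError,
    PSEUDOGENES,
    VALID_LOCI,
    truncate_resolution,
)

__all__ = [
    "KirGenotype",
    "HlaGenotype",
    "PopulationSample",
    "CodonAlignment",
    "ParseError",
    "parse_kir_genotype_table",
    "write_kir_genotype_table",
    "parse_hla_genotype_table",
    "write_hla_genotype_table",
    "read_codon_fasta",
]


class ParseError(ValueError):
    pass


@dataclass
class KirGenotype:
    """Copy numbers and allele multisets for one individual, per KIR gene.

    ``copy_number[locus] == len(alleles[locus])`` for allele-called loci;
    pseudogenes carry copy number only.  Framework loci default to copy 2.
    """

    individual_id: str
    copy_number: dict[str, int] = field(default_factory=dict)
    alleles: dict[str, Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus in FRAMEWORK_LOCI:
            self.copy_number.setdefault(locus, 2)
        for locus, cn in self.copy_number.items():
            if locus not in VALID_LOCI:
                raise NomenclatureError(f"unknown KIR locus: {locus!r}")
            if cn < 0:
                raise ParseError(f"{self.individual_id}: negative copy at {locus}")
        self.validate()

    def validate(self) -> None:
        for locus, allele_multiset in self.alleles.items():
            n = sum(allele_multiset.values())
            cn = self.copy_number.get(locus, 0)
            if n != cn:
                raise ParseError(
                    f"{self.individual_id}: {locus} carries {n} alleles "
                    f"but copy number {cn}"
                )

    def copies(self, locus: str) -> int:
        return self.copy_number.get(locus, 0)

    def allele_list(self, locus: str, resolution: int | None = None) -> list[AlleleName]:
        out: list[AlleleName] = []
        for a, mult in sorted(self.alleles.get(locus, Counter()).items()):
            a = a if resolution is None else truncate_resolution(a, resolution)
            out.extend([a] * mult)
        return out

    def has_gene(self, locus: str) -> bool:
        return self.copies(locus) > 0


@dataclass
class HlaGenotype:
    """Two-field HLA class I genotype: exactly two alleles per locus."""

    individual_id: str
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus in ("A", "B", "C"):
            if locus not in self.alleles:
                raise ParseError(f"{self.individual_id}: missing HLA-{locus}")
            if len(self.alleles[locus]) != 2:
                raise ParseError(
                    f"{self.individual_id}: HLA-{locus} must carry exactly 2 alleles"
                )

    def locus_alleles(self, locus: str) -> tuple[str, str]:
        return self.alleles[locus]

    def all_alleles(self) -> list[str]:
        return [a for locus in ("A", "B", "C") for a in self.alleles[locus]]


@dataclass
class PopulationSample:
    """A named sample of individuals with paired KIR and HLA genotypes."""

    name: str
    records: list[tuple[KirGenotype, HlaGenotype | None]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"population {self.name!r} is empty")
        ids = [k.individual_id for k, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"population {self.name!r} has duplicate individual ids")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def kir(self) -> list[KirGenotype]:
        return [k for k, _ in self.records]

    @property
    def hla(self) -> list[HlaGenotype]:
        out = [h for _, h in self.records if h is not None]
        if len(out) != len(self.records):
            raise ValueError(f"population {self.name!r} lacks HLA records")
        return out


_CELL_RE = re.compile(r"^(\d+)(?::(.*))?$")


def _parse_cell(locus: str, cell: str) -> tuple[int, Counter]:
    cell = cell.strip()
    if cell in ("", "NEG", "0", "0:", "0:NEG"):
        return 0, Counter()
    m = _CELL_RE.match(cell)
    if not m:
        raise ParseError(f"malformed cell {cell!r} at {locus}")
    cn = int(m.group(1))
    allele_part = m.group(2)
    alleles: Counter = Counter()
    if allele_part:
        for tok in allele_part.split("+"):
            tok = tok.strip()
            if tok:
                alleles[AlleleName.parse(tok, locus=locus)] += 1
    n = sum(alleles.values())
    if m.group(2) is None and n == 0:
        # bare copy number: copy determined, alleles uncalled (pseudogenes,
        # or loci typed for presence only)
        return cn, Counter()
    if n != cn:
        raise ParseError(f"{locus}: {n} alleles listed for copy number {cn}")
    return cn, alleles


def parse_kir_genotype_table(
    path: str | Path,
) -> tuple[list[KirGenotype], list[tuple[str, str]]]:
    """Read a KIR genotype TSV.

    Returns ``(records, errors)`` where *errors* collects ``(individual_id,
    reason)`` for rows rejected by a record-level invariant (for example an
    allele-count/copy-number mismatch).  An unknown locus in the header is a
    file-level failure and raises immediately.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    loci = header[1:]
    for locus in loci:
        if locus not in VALID_LOCI:
            raise NomenclatureError(f"{path}: unknown locus in header: {locus!r}")
    records: list[KirGenotype] = []
    errors: list[tuple[str, str]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        ind = fields[0].strip()
        try:
            copy_number: dict[str, int] = {}
            alleles: dict[str, Counter] = {}
            for locus, cell in zip(loci, fields[1:]):
                cn, amset = _parse_cell(locus, cell)
                copy_number[locus] = cn
                if amset:
                    alleles[locus] = amset
            records.append(
                KirGenotype(individual_id=ind, copy_number=copy_number, alleles=alleles)
            )
        except (ParseError, NomenclatureError) as exc:
            errors.append((ind, str(exc)))
    return records, errors


def write_kir_genotype_table(
    records: list[KirGenotype], path: str | Path, loci: list[str] | None = None
) -> None:
    if loci is None:
        loci = [g for g in KIR_GENE_ORDER]
    rows = ["\t".join(["individual_id"] + loci)]
    for rec in records:
        cells = [rec.individual_id]
        for locus in loci:
            cn = rec.copies(locus)
            if cn == 0:
                cells.append("NEG")
                continue
            allele_part = "+".join(
                f"{a.digits}{'N' if a.null_flag else ''}"
                for a in rec.allele_list(locus)
            )
            cells.append(f"{cn}:{allele_part}" if allele_part else str(cn))
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


def parse_hla_genotype_table(path: str | Path) -> list[HlaGenotype]:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    needed = [f"{locus}_{i}" for locus in ("A", "B", "C") for i in (1, 2)]
    for col in needed:
        if col not in idx:
            raise ParseError(f"{path}: missing column {col!r}")
    out = []
    for line in lines[1:]:
        fields = line.split("\t")
        ind = fields[0].strip()
        alleles = {
            locus: (fields[idx[f"{locus}_1"]].strip(), fields[idx[f"{locus}_2"]].strip())
            for locus in ("A", "B", "C")
        }
        out.append(HlaGenotype(individual_id=ind, alleles=alleles))
    return out


def write_hla_genotype_table(records: list[HlaGenotype], path: str | Path) -> None:
    cols = [f"{locus}_{i}" for locus in ("A", "B", "C") for i in (1, 2)]
    rows = ["\t".join(["individual_id"] + cols)]
    for rec in records:
        cells = [rec.individual_id]
        for locus in ("A", "B", "C"):
            cells.extend(rec.alleles[locus])
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


@dataclass
class CodonAlignment:
    """Aligned coding sequences for the alleles of one locus.

    Sequences must share a length divisible by three; optional per-allele
    population frequencies weight pairwise comparisons.
    """

    locus: str
    names: list[str]
    sequences: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        length = len(self.sequences[0])
        if length % 3 != 0:
            raise ValueError(
                f"{self.locus}: alignment length {length} not divisible by 3"
            )
        for name, seq in zip(self.names, self.sequences):
            if len(seq) != length:
                raise ValueError(f"{self.locus}: {name} length differs from alignment")
            if set(seq) - set("ACGT-"):
                raise ValueError(f"{self.locus}: {name} has non-ACGT characters")
        if self.weights is not None and len(self.weights) != len(self.sequences):
            raise ValueError("weights length mismatch")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def __len__(self) -> int:
        return len(self.sequences)


def read_codon_fasta(path: str | Path) -> dict[str, CodonAlignment]:
    """Read coding sequences from FASTA, grouped by locus.

    Headers must carry ``LOCUS*allele`` names; records of distinct loci are
    split into separate alignments.
    """
    groups: dict[str, tuple[list[str], list[str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        locus = name.partition("*")[0] if "*" in name else name
        seq = str(rec.seq).upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
        groups.setdefault(locus, ([], []))
        groups[locus][0].append(name)
        groups[locus][1].append(seq)
    return {
        locus: CodonAlignment(locus=locus, names=names, sequences=seqs)
        for locus, (names, seqs) in groups.items()
    }
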