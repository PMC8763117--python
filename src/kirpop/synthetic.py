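"""Synthetic cohort generator for every input the analysis consumes.

The generator emulates two contrasting demographic settings:

* an *amerindian* preset — a small, isolated, bottlenecked population:
  very few haplotypes, cA01-dominant centromeric segments whose per-gene
  allele frequencies are strongly skewed (one near-fixed allele plus a rare
  one), more even telomeric allele frequencies, HLA pools lacking A3/A11
  and nearly lacking Bw4; and
* a *cosmopolitan* preset — an urban outbred population with many segment
  haplotypes and many low-frequency alleles at every locus, including
  structural variants (del6, ins4), a null 3DL1 and the full range of HLA
  epitope groups.

An ``hla_c_only`` HLA preset removes every Bw4/A3/A11-bearing HLA-A/B
allele so all KIR-HLA interactions are HLA-C mediated by construction.
Individuals are drawn in Hardy-Weinberg proportions (two independent
segment haplotypes per region), Wright-Fisher drift (loss-only, no
mutation) models post-founding isolation, a Chinese-restaurant-process
sampler provides neutral Ewens configurations, and a star-tree codon
simulator produces alignments with controlled dN/dS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .ewens import crp_sample
from .genotypes import (
    CodonAlignment,
    HlaGenotype,
    KirGenotype,
    PopulationSample,
    write_hla_genotype_table,
    write_kir_genotype_table,
)
from .haplotypes import HaplotypeCatalog, load_catalog
from .nomenclature import AlleleName

__all__ = [
    "AlleleVariant",
    "HaplotypePool",
    "PopulationConfig",
    "EwensConfig",
    "SyntheticPopulation",
    "MarkerPanel",
    "generate_haplotype_pool",
    "sample_population",
    "simulate_bottleneck",
    "simulate_ewens_sample",
    "simulate_codon_alignment",
    "generate_marker_panel",
    "HLA_PRESETS",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class AlleleVariant:
    """An allele-level haplotype: a catalog segment filled with alleles."""

    name: str
    segment: str  # catalog definition name
    freq: float
    alleles: tuple[tuple[str, tuple[str, ...]], ...]  # (locus, allele names)

    def allele_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.alleles)


@dataclass
class HaplotypePool:
    """Population pool of centromeric/telomeric allele-level haplotypes."""

    catalog: HaplotypeCatalog
    centromeric: list[AlleleVariant]
    telomeric: list[AlleleVariant]
    hla_freqs: dict[str, dict[str, float]]
    preset: str = "custom"

    def __post_init__(self) -> None:
        for side, variants in (("centromeric", self.centromeric), ("telomeric", self.telomeric)):
            total = sum(v.freq for v in variants)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{side} variant frequencies sum to {total}, not 1")
            for v in variants:
                definition = self.catalog.get(v.segment)
                amap = v.allele_map()
                for locus, copies in definition.copies.items():
                    if locus in ("KIR2DP1", "KIR3DP1"):
                        if locus in amap:
                            raise ValueError(f"{v.name}: pseudogene {locus} cannot carry alleles")
                        continue
                    got = len(amap.get(locus, ()))
                    if got != copies:
                        raise ValueError(
                            f"{v.name}: {locus} needs {copies} allele(s), got {got}"
                        )
                extra = set(amap) - set(definition.copies)
                if extra:
                    raise ValueError(f"{v.name}: alleles at absent loci {sorted(extra)}")
        for locus, freqs in self.hla_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"HLA-{locus} frequencies sum to {total}, not 1")

    def segment_frequencies(self) -> dict[str, float]:
        """Gene-content segment frequencies (variants pooled by segment)."""
        out: dict[str, float] = {}
        for v in self.centromeric + self.telomeric:
            out[v.segment] = out.get(v.segment, 0.0) + v.freq
        return out


@dataclass
class PopulationConfig:
    """Recipe for one synthetic population."""

    name: str
    n: int
    seed: int
    preset: str = "amerindian"
    hla_preset: str | None = None
    ne_schedule: list[int] | None = None  # optional pre-sampling drift

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.ne_schedule is not None and any(ne < 1 for ne in self.ne_schedule):
            raise ValueError("Ne must be >= 1")


@dataclass
class EwensConfig:
    """Neutral Ewens-sampling configuration."""

    theta: float
    n: int
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _v(name, segment, freq, **alleles) -> AlleleVariant:
    packed = tuple(
        (f"KIR{locus[1:]}" if locus.startswith("_") else locus, tuple(v))
        for locus, v in alleles.items()
    )
    return AlleleVariant(name=name, segment=segment, freq=freq, alleles=packed)


def _amerindian_cen() -> list[AlleleVariant]:
    return [
        _v("cA01-a", "cA01", 0.82, KIR3DL3=["00201"], KIR2DL3=["00201"], KIR2DL1=["00302"]),
        _v("cA01-b", "cA01", 0.04, KIR3DL3=["00301"], KIR2DL3=["00101"], KIR2DL1=["00302"]),
        _v("cB02-a", "cB02", 0.11, KIR3DL3=["00201"], KIR2DS2=["00101"], KIR2DL2=["00101"]),
        _v(
            "cB01-a", "cB01", 0.03,
            KIR3DL3=["00201"], KIR2DS2=["00201"], KIR2DL2=["00602"],
            KIR2DL5B=["00601"], KIR2DS3=["00103"], KIR2DL1=["00401"],
        ),
    ]


def _amerindian_tel() -> list[AlleleVariant]:
    return [
        _v("tA01-a", "tA01", 0.40, KIR2DL4=["00102"], KIR3DL1=["01502"], KIR2DS4=["00101"], KIR3DL2=["00201"]),
        _v("tA01-b", "tA01", 0.18, KIR2DL4=["00802"], KIR3DL1=["00401"], KIR2DS4=["00101"], KIR3DL2=["00701"]),
        _v("tA01-c", "tA01", 0.12, KIR2DL4=["00501"], KIR3DL1=["01701"], KIR2DS4=["01001"], KIR3DL2=["00901"]),
        _v(
            "tB01-a", "tB01", 0.22,
            KIR2DL4=["00202"], KIR3DS1=["01301"], KIR2DL5A=["00101"],
            KIR2DS5=["00201"], KIR2DS1=["00201"], KIR3DL2=["00702"],
        ),
        _v(
            "tB01-b", "tB01", 0.08,
            KIR2DL4=["01101"], KIR3DS1=["04901"], KIR2DL5A=["00501"],
            KIR2DS5=["00201"], KIR2DS1=["00202"], KIR3DL2=["01001"],
        ),
    ]


def _cosmopolitan_cen() -> list[AlleleVariant]:
    return [
        _v("cA01-a", "cA01", 0.22, KIR3DL3=["00101"], KIR2DL3=["00101"], KIR2DL1=["00101"]),
        _v("cA01-b", "cA01", 0.12, KIR3DL3=["00901"], KIR2DL3=["00202"], KIR2DL1=["00201"]),
        _v("cA01-c", "cA01", 0.08, KIR3DL3=["00202"], KIR2DL3=["00501"], KIR2DL1=["00302"]),
        _v("cA02-a", "cA02", 0.05, KIR3DL3=["01401"], KIR2DL3=["00301"], KIR2DL1=["00402"]),
        _v("cA03-a", "cA03", 0.03, KIR3DL3=["01501"], KIR2DL3=["00601"]),
        _v(
            "cB01-a", "cB01", 0.14,
            KIR3DL3=["00301"], KIR2DS2=["00101"], KIR2DL2=["00101"],
            KIR2DL5B=["00201"], KIR2DS3=["00103"], KIR2DL1=["00401"],
        ),
        _v(
            "cB01-b", "cB01", 0.06,
            KIR3DL3=["00401"], KIR2DS2=["00201"], KIR2DL2=["00301"],
            KIR2DL5B=["00601"], KIR2DS3=["00201"], KIR2DL1=["00701"],
        ),
        _v("cB02-a", "cB02", 0.17, KIR3DL3=["00501"], KIR2DS2=["00101"], KIR2DL2=["00101"]),
        _v("cB02-b", "cB02", 0.05, KIR3DL3=["00601"], KIR2DS2=["00301"], KIR2DL2=["00202"]),
        _v("cB03-a", "cB03", 0.04, KIR3DL3=["00701"], KIR2DS2=["00101"], KIR2DL3=["00401"], KIR2DL1=["00501"]),
        _v(
            "cB04-a", "cB04", 0.04,
            KIR3DL3=["00801"], KIR2DS2=["00201"], KIR2DL2=["00501"],
            KIR2DL5B=["00801"], KIR2DS3=["00301"],
        ),
    ]


def _cosmopolitan_tel() -> list[AlleleVariant]:
    return [
        _v("tA01-a", "tA01", 0.20, KIR2DL4=["00101"], KIR3DL1=["00101"], KIR2DS4=["00101"], KIR3DL2=["00101"]),
        _v("tA01-b", "tA01", 0.12, KIR2DL4=["00202"], KIR3DL1=["00201"], KIR2DS4=["00101"], KIR3DL2=["00201"]),
        _v("tA01-c", "tA01", 0.08, KIR2DL4=["00501"], KIR3DL1=["01502"], KIR2DS4=["01001"], KIR3DL2=["00301"]),
        _v("tA01-d", "tA01", 0.05, KIR2DL4=["00801"], KIR3DL1=["02001"], KIR2DS4=["00102"], KIR3DL2=["00401"]),
        _v("tA02-a", "tA02", 0.04, KIR2DL4=["00102"], KIR3DL1=["00402N"], KIR3DL2=["00501"]),
        _v(
            "tB01-a", "tB01", 0.14,
            KIR2DL4=["00501"], KIR3DS1=["01301"], KIR2DL5A=["00101"],
            KIR2DS5=["00201"], KIR2DS1=["00201"], KIR3DL2=["00701"],
        ),
        _v(
            "tB01-b", "tB01", 0.08,
            KIR2DL4=["01101"], KIR3DS1=["01401"], KIR2DL5A=["00501"],
            KIR2DS5=["00301"], KIR2DS1=["00202"], KIR3DL2=["01001"],
        ),
        _v(
            "tB02-a", "tB02", 0.07,
            KIR2DL4=["00802"], KIR3DL1=["00501"], KIR2DL5A=["00301"],
            KIR2DS5=["00601"], KIR2DS1=["00301"], KIR3DL2=["00801"],
        ),
        _v("tB03-a", "tB03", 0.06, KIR2DL4=["00901"], KIR3DS1=["01302"], KIR2DS4=["00103"], KIR3DL2=["01101"]),
        _v(
            "tB04-a", "tB04", 0.05,
            KIR2DL4=["01201"], KIR3DL1=["00701"], KIR2DL5A=["01201"],
            KIR2DS5=["00202"], KIR2DS4=["00601"], KIR3DL2=["01201"],
        ),
        _v(
            "tB05-a", "tB05", 0.04,
            KIR2DL4=["01301"], KIR3DS1=["04901"], KIR2DL5A=["00201"],
            KIR2DS5=["00401"], KIR2DS4=["00701"], KIR3DL2=["01301"],
        ),
        _v(
            "tA01-ins4-a", "tA01-ins4", 0.03,
            KIR2DL4=["00101", "01001"], KIR3DL1=["00101"], KIR3DS1=["01301"],
            KIR2DS4=["00101"], KIR3DL2=["00101"],
        ),
        _v(
            "tB01-del6-a", "tB01-del6", 0.04,
            KIR2DL5A=["00101"], KIR2DS5=["00201"], KIR2DS1=["00201"], KIR3DL2=["00701"],
        ),
    ]


HLA_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "amerindian": {
        "A": {"A*02:01": 0.55, "A*31:01": 0.30, "A*24:02": 0.15},
        "B": {"B*35:01": 0.45, "B*39:01": 0.35, "B*15:01": 0.10, "B*51:01": 0.10},
        "C": {"C*07:02": 0.35, "C*04:01": 0.30, "C*03:04": 0.25, "C*15:02": 0.10},
    },
    # no Bw4/A3/A11-bearing HLA-A or -B alleles at all
    "hla_c_only": {
        "A": {"A*02:01": 0.70, "A*31:01": 0.30},
        "B": {"B*35:01": 0.60, "B*39:01": 0.40},
        "C": {"C*07:02": 0.35, "C*04:01": 0.30, "C*03:04": 0.25, "C*15:02": 0.10},
    },
    "cosmopolitan": {
        "A": {
            "A*01:01": 0.18, "A*02:01": 0.25, "A*03:01": 0.14, "A*11:01": 0.08,
            "A*24:02": 0.12, "A*26:01": 0.08, "A*31:01": 0.08, "A*32:01": 0.07,
        },
        "B": {
            "B*07:02": 0.15, "B*08:01": 0.12, "B*44:02": 0.13, "B*51:01": 0.10,
            "B*57:01": 0.06, "B*35:01": 0.14, "B*15:01": 0.10, "B*18:01": 0.08,
            "B*27:05": 0.07, "B*40:01": 0.05,
        },
        "C": {
            "C*01:02": 0.08, "C*02:02": 0.07, "C*03:04": 0.12, "C*04:01": 0.13,
            "C*05:01": 0.08, "C*06:02": 0.09, "C*07:01": 0.15, "C*07:02": 0.12,
            "C*08:02": 0.05, "C*12:03": 0.05, "C*15:02": 0.03, "C*16:01": 0.03,
        },
    },
}


def generate_haplotype_pool(
    preset: str = "amerindian",
    hla_preset: str | None = None,
    catalog: HaplotypeCatalog | None = None,
) -> HaplotypePool:
    """Build the allele-level haplotype pool for a named preset."""
    catalog = catalog or load_catalog()
    if preset == "amerindian":
        cen, tel = _amerindian_cen(), _amerindian_tel()
    elif preset == "cosmopolitan":
        cen, tel = _cosmopolitan_cen(), _cosmopolitan_tel()
    else:
        raise ValueError(f"unknown preset {preset!r}")
    hla_key = hla_preset or preset
    if hla_key not in HLA_PRESETS:
        raise ValueError(f"unknown HLA preset {hla_key!r}")
    return HaplotypePool(
        catalog=catalog,
        centromeric=cen,
        telomeric=tel,
        hla_freqs={k: dict(v) for k, v in HLA_PRESETS[hla_key].items()},
        preset=preset,
    )


@dataclass
class SyntheticPopulation:
    """A sampled population plus the generating truth for recovery tests."""

    sample: PopulationSample
    pool: HaplotypePool
    #: per individual: ((cen variant 1, cen variant 2), (tel variant 1, tel variant 2))
    true_variants: list[tuple[tuple[str, str], tuple[str, str]]]
    #: per individual: same but at catalog-segment (gene-content) level
    true_segments: list[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=list)

    def write_inputs(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_kir_genotype_table(self.sample.kir, d / "kir_genotypes.tsv")
        write_hla_genotype_table(self.sample.hla, d / "hla_genotypes.tsv")


def _genotype_from_variants(
    ind_id: str,
    cen_pair: tuple[AlleleVariant, AlleleVariant],
    tel_pair: tuple[AlleleVariant, AlleleVariant],
    catalog: HaplotypeCatalog,
) -> KirGenotype:
    copy_number: dict[str, int] = {}
    alleles: dict[str, Counter] = {}
    for variant in (*cen_pair, *tel_pair):
        definition = catalog.get(variant.segment)
        for locus, copies in definition.copies.items():
            copy_number[locus] = copy_number.get(locus, 0) + copies
        for locus, adj in definition.boundary_adjust.items():
            copy_number[locus] = copy_number.get(locus, 0) + adj
        for locus, names in variant.allele_map().items():
            bucket = alleles.setdefault(locus, Counter())
            for token in names:
                bucket[AlleleName.parse(token, locus=locus)] += 1
    for locus in list(copy_number):
        if copy_number[locus] == 0:
            del copy_number[locus]
            alleles.pop(locus, None)
    # explicit zeros for framework loci removed by structural variants
    for locus in ("KIR3DP1", "KIR2DL4", "KIR3DL2"):
        copy_number.setdefault(locus, 0)
    return KirGenotype(individual_id=ind_id, copy_number=copy_number, alleles=alleles)


def sample_population(
    pool: HaplotypePool,
    n: int,
    seed: int,
    name: str = "synthetic",
) -> SyntheticPopulation:
    """Draw *n* diploid individuals from the pool under Hardy-Weinberg.

    2n centromeric and 2n telomeric haplotypes are drawn i.i.d. from the
    variant frequencies; HLA alleles are drawn i.i.d. per locus.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    cen_f = np.array([v.freq for v in pool.centromeric])
    tel_f = np.array([v.freq for v in pool.telomeric])
    cen_draw = rng.choice(len(pool.centromeric), size=(n, 2), p=cen_f / cen_f.sum())
    tel_draw = rng.choice(len(pool.telomeric), size=(n, 2), p=tel_f / tel_f.sum())
    records = []
    true_variants = []
    true_segments = []
    for i in range(n):
        ind = f"{name}_{i + 1:04d}"
        cen_pair = (pool.centromeric[cen_draw[i, 0]], pool.centromeric[cen_draw[i, 1]])
        tel_pair = (pool.telomeric[tel_draw[i, 0]], pool.telomeric[tel_draw[i, 1]])
        kir = _genotype_from_variants(ind, cen_pair, tel_pair, pool.catalog)
        hla_alleles = {}
        for locus, freqs in pool.hla_freqs.items():
            names = list(freqs)
            p = np.array([freqs[a] for a in names])
            picks = rng.choice(len(names), size=2, p=p / p.sum())
            hla_alleles[locus] = (names[picks[0]], names[picks[1]])
        hla = HlaGenotype(individual_id=ind, alleles=hla_alleles)
        records.append((kir, hla))
        true_variants.append(
            ((cen_pair[0].name, cen_pair[1].name), (tel_pair[0].name, tel_pair[1].name))
        )
        true_segments.append(
            ((cen_pair[0].segment, cen_pair[1].segment), (tel_pair[0].segment, tel_pair[1].segment))
        )
    sample = PopulationSample(name=name, records=records)
    return SyntheticPopulation(
        sample=sample, pool=pool, true_variants=true_variants, true_segments=true_segments
    )


def simulate_bottleneck(
    pool: HaplotypePool,
    ne_schedule,
    generations: int | None = None,
    seed: int = 0,
) -> tuple[HaplotypePool, dict[str, list[str]]]:
    """Wright-Fisher drift of the pool's haplotype frequencies (no mutation).

    *ne_schedule* is a per-generation list of effective sizes, or a scalar
    Ne combined with *generations*.  ``None``/``inf`` entries leave
    frequencies unchanged (the infinite-population limit).  Returns the
    drifted pool (lost haplotypes removed, frequencies renormalized) and
    the names of lost variants per region.
    """
    if not isinstance(ne_schedule, (list, tuple, np.ndarray)):
        if generations is None:
            raise ValueError("scalar Ne needs a generation count")
        ne_schedule = [ne_schedule] * generations
    rng = np.random.default_rng(seed)
    lost: dict[str, list[str]] = {"centromeric": [], "telomeric": []}
    new_sides = {}
    for side, variants in (("centromeric", pool.centromeric), ("telomeric", pool.telomeric)):
        freqs = np.array([v.freq for v in variants], dtype=float)
        for ne in ne_schedule:
            if ne is None or np.isinf(ne):
                continue
            counts = rng.multinomial(2 * int(ne), freqs / freqs.sum())
            freqs = counts / counts.sum()
        survivors = []
        for v, f in zip(variants, freqs):
            if f > 0:
                survivors.append(AlleleVariant(v.name, v.segment, float(f), v.alleles))
            else:
                lost[side].append(v.name)
        total = sum(v.freq for v in survivors)
        survivors = [
            AlleleVariant(v.name, v.segment, v.freq / total, v.alleles) for v in survivors
        ]
        new_sides[side] = survivors
    drifted = HaplotypePool(
        catalog=pool.catalog,
        centromeric=new_sides["centromeric"],
        telomeric=new_sides["telomeric"],
        hla_freqs={k: dict(v) for k, v in pool.hla_freqs.items()},
        preset=f"{pool.preset}-drifted",
    )
    return drifted, lost


def simulate_ewens_sample(config: EwensConfig):
    """Neutral allele configuration(s) from the Chinese restaurant process."""
    rng = np.random.default_rng(config.seed)
    configs = [crp_sample(config.n, config.theta, rng) for _ in range(config.replicates)]
    return configs[0] if config.replicates == 1 else configs


_NT = "ACGT"
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODE = {}


def _codon_table() -> dict[str, str]:
    if not _CODE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODE[stop] = "*"
    return _CODE


def simulate_codon_alignment(
    n_alleles: int,
    n_codons: int,
    omega: float,
    branch_length: float = 0.02,
    seed: int = 0,
    locus: str = "SIM",
) -> CodonAlignment:
    """Star-tree codon evolution with nonsynonymous/synonymous rate ratio
    *omega*.

    A random stop-free ancestor evolves independently along each of
    *n_alleles* branches; *branch_length* is the expected number of
    attempted substitutions per nucleotide site.  Proposed changes creating
    a stop codon are rejected; synonymous changes are accepted with
    relative rate 1 and nonsynonymous with relative rate omega (rates
    rescaled so neither exceeds 1).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    code = _codon_table()
    rng = np.random.default_rng(seed)
    sense = sorted(set(code) - _STOP_CODONS)
    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    p_syn = min(1.0, 1.0 / omega) if omega > 1 else 1.0
    p_non = min(1.0, omega)
    names = []
    seqs = []
    n_sites = 3 * n_codons
    for a in range(n_alleles):
        codons = list(ancestor)
        n_events = rng.poisson(branch_length * n_sites)
        for _ in range(n_events):
            pos = int(rng.integers(0, n_sites))
            ci, off = divmod(pos, 3)
            old = codons[ci]
            base = _NT[int(rng.integers(0, 4))]
            if base == old[off]:
                continue
            new = old[:off] + base + old[off + 1 :]
            if new in _STOP_CODONS:
                continue
            accept = p_syn if code[new] == code[old] else p_non
            if rng.random() < accept:
                codons[ci] = new
        names.append(f"{locus}*{a + 1:03d}")
        seqs.append("".join(codons))
    return CodonAlignment(locus=locus, names=names, sequences=seqs)


@dataclass
class MarkerPanel:
    """Neutral multiallelic marker panel drifted per population."""

    populations: list[str]
    #: allele counts: population -> list (per locus) of Counter
    counts: dict[str, list[Counter]]

    def expected_heterozygosity(self, population: str) -> list[float]:
        out = []
        for counter in self.counts[population]:
            total = sum(counter.values())
            out.append(1.0 - sum((c / total) ** 2 for c in counter.values()))
        return out

    def fst_per_locus(self) -> list[float]:
        from .popgen import nei_gst

        n_loci = len(next(iter(self.counts.values())))
        return [
            nei_gst([self.counts[p][l] for p in self.populations])
            for l in range(n_loci)
        ]


def generate_marker_panel(
    n_loci: int,
    populations,
    seed: int,
    n_alleles: int = 8,
    ne: int = 50,
    generations: int = 20,
    sample_copies: int = 100,
) -> MarkerPanel:
    """Microsatellite-like neutral panel under the same drift engine.

    Each locus starts from a shared ancestral frequency vector (symmetric
    Dirichlet over *n_alleles* alleles); each population drifts
    independently for *generations* Wright-Fisher generations at size *ne*,
    then *sample_copies* gene copies are sampled per locus.
    """
    if n_loci < 2:
        raise ValueError("need at least 2 loci")
    if isinstance(populations, int):
        populations = [f"pop{i + 1}" for i in range(populations)]
    rng = np.random.default_rng(seed)
    counts: dict[str, list[Counter]] = {p: [] for p in populations}
    for _ in range(n_loci):
        ancestral = rng.dirichlet(np.ones(n_alleles))
        for pop in populations:
            freqs = ancestral.copy()
            for _g in range(generations):
                freqs = rng.multinomial(2 * ne, freqs / freqs.sum()) / (2 * ne)
            drawn = rng.multinomial(sample_copies, freqs / freqs.sum())
            counts[pop].append(Counter({f"a{i}": int(c) for i, c in enumerate(drawn) if c}))
    return MarkerPanel(populations=list(populations), counts=counts)
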