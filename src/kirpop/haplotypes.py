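"""Gene-content haplotype classification and diplotype resolution.

KIR haplotypes decompose into a centromeric segment (KIR3DL3..KIR3DP1) and a
telomeric segment (KIR2DL4..KIR3DL2) joined at a recombination hotspot.
Population haplotypes are combinations of a modest set of named segment
patterns (cA01, cB02, tA01, tB01, ...) each carrying a characteristic set of
present genes.  This module classifies observed copy-number vectors against
a segment catalog, resolves diploid genotypes into ranked haplotype pairs,
and computes multiallelic linkage disequilibrium between loci on phased
haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .genotypes import KirGenotype

__all__ = [
    "CEN_LOCI",
    "TEL_LOCI",
    "CANONICAL_A_CONTENT",
    "HaplotypeDefinition",
    "HaplotypeCatalog",
    "DiplotypeCall",
    "load_catalog",
    "segment_regions",
    "classify_segment",
    "resolve_diplotype",
    "classify_AB",
    "pairwise_ld",
]

#: Centromeric-region loci in genomic order (the region ends at KIR3DP1).
CEN_LOCI: tuple[str, ...] = (
    "KIR3DL3",
    "KIR2DS2",
    "KIR2DL2",
    "KIR2DL3",
    "KIR2DL5B",
    "KIR2DS3",
    "KIR2DP1",
    "KIR2DL1",
    "KIR3DP1",
)

#: Telomeric-region loci in genomic order (KIR2DL4..KIR3DL2).
TEL_LOCI: tuple[str, ...] = (
    "KIR2DL4",
    "KIR3DL1",
    "KIR3DS1",
    "KIR2DL5A",
    "KIR2DS5",
    "KIR2DS1",
    "KIR2DS4",
    "KIR3DL2",
)

ALL_LOCI: tuple[str, ...] = CEN_LOCI + TEL_LOCI

#: Gene content of the canonical A haplotype; anything else is B.
CANONICAL_A_CONTENT: frozenset[str] = frozenset(
    {
        "KIR3DL3",
        "KIR2DL3",
        "KIR2DP1",
        "KIR2DL1",
        "KIR3DP1",
        "KIR2DL4",
        "KIR3DL1",
        "KIR2DS4",
        "KIR3DL2",
    }
)


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named gene-content segment haplotype (single chromosome)."""

    name: str
    region: str  # "centromeric" | "telomeric"
    copies: dict[str, int] = field(hash=False)
    ab_class: str = "B"
    structural_tag: str | None = None
    #: copy adjustment applied to boundary loci of the *other* region
    #: (del6 removes the adjoining KIR3DP1, ins4 duplicates it)
    boundary_adjust: dict[str, int] = field(default_factory=dict, hash=False)

    def copy_of(self, locus: str) -> int:
        return self.copies.get(locus, 0)

    @property
    def region_loci(self) -> tuple[str, ...]:
        return CEN_LOCI if self.region == "centromeric" else TEL_LOCI


@dataclass
class HaplotypeCatalog:
    centromeric: list[HaplotypeDefinition]
    telomeric: list[HaplotypeDefinition]

    def __post_init__(self) -> None:
        for defs in (self.centromeric, self.telomeric):
            seen: dict[tuple, str] = {}
            for d in defs:
                key = (
                    tuple(sorted(d.copies.items())),
                    d.structural_tag,
                    tuple(sorted(d.boundary_adjust.items())),
                )
                if key in seen:
                    raise ValueError(
                        f"catalog entries {seen[key]} and {d.name} share a "
                        "presence vector and structural tag"
                    )
                seen[key] = d.name
        names = [d.name for d in self.centromeric + self.telomeric]
        if len(set(names)) != len(names):
            raise ValueError("duplicate haplotype names in catalog")

    def region(self, region: str) -> list[HaplotypeDefinition]:
        return self.centromeric if region == "centromeric" else self.telomeric

    def get(self, name: str) -> HaplotypeDefinition:
        for d in self.centromeric + self.telomeric:
            if d.name == name:
                return d
        raise KeyError(name)


def load_catalog(path: str | Path | None = None) -> HaplotypeCatalog:
    """Load a segment catalog from YAML (the packaged catalog by default)."""
    if path is None:
        with resources.files("kirpop.data").joinpath("haplotype_catalog.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, list[HaplotypeDefinition]] = {}
    for region in ("centromeric", "telomeric"):
        defs = []
        for name, entry in raw[region].items():
            defs.append(
                HaplotypeDefinition(
                    name=name,
                    region=region,
                    copies=dict(entry["loci"]),
                    ab_class=entry.get("ab_class", "B"),
                    structural_tag=entry.get("structural_tag"),
                    boundary_adjust=dict(entry.get("boundary_adjust", {})),
                )
            )
        out[region] = defs
    return HaplotypeCatalog(centromeric=out["centromeric"], telomeric=out["telomeric"])


def segment_regions(
    genotype: KirGenotype,
) -> tuple[dict[str, int], dict[str, int], list[str]]:
    """Split a genotype's copy-number vector into region vectors.

    Returns ``(centromeric, telomeric, flags)``; the concatenation of the two
    vectors reproduces the genotype's copy vector over all KIR loci.  A
    KIR3DP1 copy total below 2 raises a telomere-adjacent-deletion flag
    (the del6 signature removes the 3DP1 adjoining the telomeric segment).
    """
    cen = {locus: genotype.copies(locus) for locus in CEN_LOCI}
    tel = {locus: genotype.copies(locus) for locus in TEL_LOCI}
    flags: list[str] = []
    if cen["KIR3DP1"] < 2:
        flags.append("telomere-adjacent-deletion")
    for locus in ("KIR3DL3", "KIR2DL4", "KIR3DL2"):
        if genotype.copies(locus) == 0:
            flags.append(f"framework-absent:{locus}")
    return cen, tel, flags


def classify_segment(
    presence_vector: dict[str, int],
    catalog: HaplotypeCatalog,
    region: str,
) -> tuple[HaplotypeDefinition | str, list[tuple[str, int]]]:
    """Match a single-haplotype copy vector against the catalog.

    Returns ``(match, candidates)``: *match* is the unique distance-0
    definition, or the string ``"novel"``.  *candidates* lists ``(name,
    hamming_distance)`` sorted by distance then name; equal-distance exact
    ties are all present in the list (tie flagged by len > 1 at distance 0).

    The vector may include boundary loci of the other region (e.g. KIR3DP1
    for a telomeric vector); these are checked against the definitions'
    boundary adjustments relative to the single-copy baseline.
    """
    defs = catalog.region(region)
    loci = CEN_LOCI if region == "centromeric" else TEL_LOCI
    extra = [l for l in presence_vector if l not in loci]
    scored: list[tuple[str, int]] = []
    for d in defs:
        dist = sum(abs(presence_vector.get(l, 0) - d.copy_of(l)) for l in loci)
        for l in extra:
            baseline = 1 if l == "KIR3DP1" and region == "telomeric" else 0
            expected = baseline + d.boundary_adjust.get(l, 0)
            dist += abs(presence_vector[l] - expected)
        scored.append((d.name, dist))
    scored.sort(key=lambda t: (t[1], t[0]))
    exact = [name for name, dist in scored if dist == 0]
    if len(exact) == 1:
        return catalog.get(exact[0]), scored
    return "novel", scored


@dataclass
class DiplotypeCall:
    """Ranked haplotype-pair explanations of one individual's copy vector."""

    individual_id: str
    #: ranked list of ((cen1, tel1), (cen2, tel2)) name pairs with scores
    pairs: list[tuple[tuple[tuple[str, str], tuple[str, str]], float]]
    resolved: bool

    @property
    def best(self):
        return self.pairs[0][0] if self.pairs else None

    @property
    def best_segments(self) -> tuple[frozenset[str], frozenset[str]] | None:
        """Unordered (cen pair, tel pair) of the top call, as multiset-like keys."""
        if not self.pairs:
            return None
        (h1, h2) = self.pairs[0][0]
        return (frozenset([h1[0], h2[0]]) if h1[0] != h2[0] else frozenset([h1[0]]),
                frozenset([h1[1], h2[1]]) if h1[1] != h2[1] else frozenset([h1[1]]))


class _PairTable:
    """Cache of predicted diploid copy vectors for all catalog haplotype pairs."""

    def __init__(self, catalog: HaplotypeCatalog):
        self.catalog = catalog
        haps = list(itertools.product(catalog.centromeric, catalog.telomeric))
        self.haps = haps
        pairs = list(itertools.combinations_with_replacement(range(len(haps)), 2))
        self.pairs = pairs
        mat = np.zeros((len(pairs), len(ALL_LOCI)), dtype=np.int16)
        locus_idx = {l: i for i, l in enumerate(ALL_LOCI)}
        hap_vecs = np.zeros((len(haps), len(ALL_LOCI)), dtype=np.int16)
        for h, (c, t) in enumerate(haps):
            for d in (c, t):
                for locus, cn in d.copies.items():
                    hap_vecs[h, locus_idx[locus]] += cn
                for locus, adj in d.boundary_adjust.items():
                    hap_vecs[h, locus_idx[locus]] += adj
        for p, (i, j) in enumerate(pairs):
            mat[p] = hap_vecs[i] + hap_vecs[j]
        self.matrix = mat

    def names(self, pair_index: int) -> tuple[tuple[str, str], tuple[str, str]]:
        i, j = self.pairs[pair_index]
        ci, ti = self.haps[i]
        cj, tj = self.haps[j]
        return ((ci.name, ti.name), (cj.name, tj.name))


_PAIR_TABLES: dict[int, _PairTable] = {}


def _pair_table(catalog: HaplotypeCatalog) -> _PairTable:
    key = id(catalog)
    if key not in _PAIR_TABLES:
        _PAIR_TABLES[key] = _PairTable(catalog)
    return _PAIR_TABLES[key]


def resolve_diplotype(
    genotype: KirGenotype,
    catalog: HaplotypeCatalog,
    haplotype_freqs: dict[str, float] | None = None,
) -> DiplotypeCall:
    """Enumerate all catalog haplotype pairs consistent with the copy vector.

    A pair is consistent when its locus-wise copy sums equal the observed
    copy numbers at every KIR locus.  Pairs are ranked by the product of
    segment frequencies (uniform prior when *haplotype_freqs* is None, keyed
    by segment name); ties break lexicographically so calls are
    deterministic.
    """
    table = _pair_table(catalog)
    observed = np.array([genotype.copies(l) for l in ALL_LOCI], dtype=np.int16)
    hits = np.nonzero((table.matrix == observed).all(axis=1))[0]

    # uniform prior without a frequency table; with one, unseen segments
    # score zero and lose to any segment actually present in the population
    def seg_freq(name: str) -> float:
        if haplotype_freqs is None:
            return 1.0
        return haplotype_freqs.get(name, 0.0)

    scored = []
    for p in hits:
        (c1, t1), (c2, t2) = table.names(int(p))
        score = seg_freq(c1) * seg_freq(t1) * seg_freq(c2) * seg_freq(t2)
        scored.append((((c1, t1), (c2, t2)), score))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return DiplotypeCall(
        individual_id=genotype.individual_id, pairs=scored, resolved=bool(scored)
    )


def classify_AB(content: dict[str, int] | HaplotypeDefinition | tuple) -> str:
    """Classify a full (cen+tel) haplotype as A or B by gene content.

    A haplotype is *A* iff its present genes are exactly the canonical A set
    (KIR3DL3, 2DL3, 2DP1, 2DL1, 3DP1, 2DL4, 3DL1, 2DS4, 3DL2); any B-specific
    gene (2DS2, 2DL2, 2DL5, 2DS3/5, 2DS1, 3DS1) or content deviation makes
    it *B*.
    """
    if isinstance(content, tuple):
        merged: dict[str, int] = {}
        for d in content:
            for locus, cn in d.copies.items():
                merged[locus] = merged.get(locus, 0) + cn
        content = merged
    elif isinstance(content, HaplotypeDefinition):
        content = content.copies
    present = frozenset(l for l, cn in content.items() if cn > 0)
    return "A" if present == CANONICAL_A_CONTENT else "B"


def pairwise_ld(
    haplotypes: list[dict[str, object]], locus_i: str, locus_j: str
) -> dict[str, float]:
    """Multiallelic linkage disequilibrium between two loci.

    *haplotypes* is a list of phased single-haplotype allele assignments
    (mapping locus -> allele label).  Returns the frequency-weighted
    multiallelic D' (mean of |D'_ab| weighted by p_a * p_b) and Wn
    (Cramer's-V analog), both in [0, 1].  A monomorphic locus yields NaN.
    """
    pairs = [
        (h[locus_i], h[locus_j])
        for h in haplotypes
        if h.get(locus_i) is not None and h.get(locus_j) is not None
    ]
    if len(pairs) < 2:
        raise ValueError("need at least two phased haplotypes")
    n = len(pairs)
    a_labels = sorted({a for a, _ in pairs}, key=str)
    b_labels = sorted({b for _, b in pairs}, key=str)
    if len(a_labels) < 2 or len(b_labels) < 2:
        return {"d_prime": float("nan"), "wn": float("nan")}
    pa = np.array([sum(1 for a, _ in pairs if a == la) / n for la in a_labels])
    pb = np.array([sum(1 for _, b in pairs if b == lb) / n for lb in b_labels])
    pab = np.array(
        [
            [sum(1 for a, b in pairs if a == la and b == lb) / n for lb in b_labels]
            for la in a_labels
        ]
    )
    D = pab - np.outer(pa, pb)
    dprime_sum = 0.0
    chi2_sum = 0.0
    for i in range(len(a_labels)):
        for j in range(len(b_labels)):
            d = D[i, j]
            if d >= 0:
                dmax = min(pa[i] * (1 - pb[j]), (1 - pa[i]) * pb[j])
            else:
                dmax = min(pa[i] * pb[j], (1 - pa[i]) * (1 - pb[j]))
            if dmax > 0:
                dprime_sum += pa[i] * pb[j] * abs(d) / dmax
            chi2_sum += d * d / (pa[i] * pb[j])
    wn = float(np.sqrt(chi2_sum / (min(len(a_labels), len(b_labels)) - 1)))
    return {"d_prime": float(dprime_sum), "wn": min(wn, 1.0)}
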