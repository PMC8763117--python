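"""Population diversity and differentiation statistics.

All statistics are copy-number aware: a locus carried in three copies
contributes three gene-copy counts to allele frequencies, and genotype-level
statistics (heterozygosity) use an explicit ``absent`` pseudo-allele so that
every diploid individual contributes exactly two units per locus.
Combined allelic series (KIR2DL23, KIR3DL1S1, KIR2DS35, KIR2DL5AB) may be
requested as loci; member-gene counts are then pooled.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotypes import KirGenotype, PopulationSample
from .nomenclature import AlleleName, COMBINED_SERIES, truncate_resolution

__all__ = [
    "ABSENT",
    "FrequencyTable",
    "DiversitySummary",
    "allele_counts",
    "allele_frequencies",
    "common_allele_count",
    "allelic_richness",
    "heterozygosity",
    "allele_sharing",
    "nei_gst",
    "weir_cockerham_theta",
    "fst",
    "exact_test_differentiation",
]

#: Pseudo-allele standing for a missing gene copy at a CNV locus.
ABSENT = "absent"


def _member_genes(locus: str) -> tuple[str, ...]:
    return COMBINED_SERIES.get(locus, (locus,))


@dataclass
class FrequencyTable:
    """Allele counts and frequencies at one locus in one population."""

    locus: str
    population: str
    counts: dict[str, int]
    total: int

    @property
    def freqs(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {a: c / self.total for a, c in self.counts.items()}

    def freq_vector(self) -> np.ndarray:
        return np.array(list(self.freqs.values()))


@dataclass
class DiversitySummary:
    population: str
    locus: str
    n_alleles: int
    common_alleles: int
    allelic_richness: float
    h_obs: float
    h_exp: float
    h_exp_unbiased: float


def allele_counts(
    pop: PopulationSample,
    locus: str,
    resolution: int | None = 3,
    include_absent: bool = False,
) -> Counter:
    """Gene-copy allele counts at a locus (series labels pool member genes).

    With ``include_absent`` every individual contributes exactly two units
    per member gene, missing copies counted as :data:`ABSENT`.
    """
    genes = _member_genes(locus)
    counts: Counter = Counter()
    for kir in pop.kir:
        for gene in genes:
            alleles = kir.allele_list(gene, resolution=resolution)
            counts.update(str(a) for a in alleles)
            if include_absent:
                missing = 2 - len(alleles)
                if missing > 0:
                    counts[ABSENT] += missing
    return counts


def allele_frequencies(
    pop: PopulationSample,
    locus: str,
    resolution: int | None = 3,
    include_absent: bool = False,
) -> FrequencyTable:
    counts = allele_counts(pop, locus, resolution, include_absent)
    total = sum(counts.values())
    return FrequencyTable(
        locus=locus, population=pop.name, counts=dict(counts), total=total
    )


def common_allele_count(freqs, threshold: float = 0.01) -> int:
    """Number of alleles with frequency >= *threshold* (inclusive)."""
    if isinstance(freqs, FrequencyTable):
        freqs = list(freqs.freqs.values())
    elif isinstance(freqs, dict):
        freqs = list(freqs.values())
    return sum(1 for f in freqs if f >= threshold)


def allelic_richness(counts, g: int) -> float:
    """Rarefied allelic richness: expected distinct alleles in a random
    subsample of *g* gene copies, ``sum_i 1 - C(N-N_i, g) / C(N, g)``."""
    if isinstance(counts, FrequencyTable):
        counts = list(counts.counts.values())
    elif isinstance(counts, (dict, Counter)):
        counts = list(counts.values())
    counts = [int(c) for c in counts if c > 0]
    total = sum(counts)
    if g > total:
        raise ValueError(f"rarefaction size {g} exceeds total gene copies {total}")
    if g < 1:
        raise ValueError("rarefaction size must be >= 1")
    log_denom = gammaln(total + 1) - gammaln(g + 1) - gammaln(total - g + 1)
    ar = 0.0
    for n_i in counts:
        rem = total - n_i
        if rem < g:
            ar += 1.0
        else:
            log_num = gammaln(rem + 1) - gammaln(g + 1) - gammaln(rem - g + 1)
            ar += 1.0 - math.exp(log_num - log_denom)
    return ar


def heterozygosity(pop: PopulationSample, locus: str) -> dict[str, float]:
    """Observed and expected heterozygosity at a locus.

    Each individual contributes a two-unit genotype per member gene (missing
    copies as the absent pseudo-allele).  ``h_exp = 1 - sum f_i^2`` on unit
    frequencies; the unbiased variant applies the 2n/(2n-1) small-sample
    correction.  ``h_obs`` is the fraction of two-unit genotypes with
    distinct units.
    """
    if pop.n < 2:
        raise ValueError("heterozygosity needs at least 2 individuals")
    genes = _member_genes(locus)
    counts: Counter = Counter()
    n_genotypes = 0
    n_het = 0
    for kir in pop.kir:
        units: list[str] = []
        for gene in genes:
            gene_units = [str(a) for a in kir.allele_list(gene, resolution=None)]
            while len(gene_units) < 2:
                gene_units.append(ABSENT)
            units.extend(gene_units[:2] if len(gene_units) > 2 else gene_units)
        counts.update(units)
        n_genotypes += 1
        n_het += int(len(set(units)) > 1)
    total = sum(counts.values())
    freqs = np.array([c / total for c in counts.values()])
    h_exp = float(1.0 - np.sum(freqs**2))
    h_unb = h_exp * total / (total - 1) if total > 1 else 0.0
    return {
        "h_obs": n_het / n_genotypes,
        "h_exp": h_exp,
        "h_exp_unbiased": h_unb,
        "n_units": total,
    }


def allele_sharing(
    pop_a: PopulationSample | set,
    pop_b: PopulationSample | set,
    locus: str | None = None,
    resolution: int | None = 3,
) -> dict[str, float | set]:
    """Allele-set sharing between two populations.

    Returns the Jaccard proportion |A∩B|/|A∪B| and both directional
    proportions, plus the intersection listing for set-style tabulation.
    When *locus* is None, allele sets are pooled over all KIR genes.
    """

    def allele_set(pop) -> set:
        if isinstance(pop, (set, frozenset)):
            return set(pop)
        loci = [locus] if locus else sorted({l for k in pop.kir for l in k.alleles})
        out: set[str] = set()
        for l in loci:
            out |= set(allele_counts(pop, l, resolution))
        return out

    a, b = allele_set(pop_a), allele_set(pop_b)
    union = a | b
    inter = a & b
    return {
        "jaccard": len(inter) / len(union) if union else 1.0,
        "share_of_a": len(inter) / len(a) if a else 0.0,
        "share_of_b": len(inter) / len(b) if b else 0.0,
        "intersection": inter,
    }


def _counts_matrix(tables: list[Counter]) -> np.ndarray:
    alleles = sorted({a for t in tables for a in t})
    return np.array([[t.get(a, 0) for a in alleles] for t in tables], dtype=float)


def nei_gst(tables: list[Counter]) -> float:
    """Nei's G_ST from per-population allele counts (unweighted means)."""
    mat = _counts_matrix(tables)
    totals = mat.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a population has no observed gene copies")
    p = mat / totals
    h_s = float(np.mean(1.0 - np.sum(p**2, axis=1)))
    p_bar = p.mean(axis=0)
    h_t = float(1.0 - np.sum(p_bar**2))
    if h_t <= 0:
        return float("nan")
    return (h_t - h_s) / h_t


def weir_cockerham_theta(tables: list[Counter]) -> float:
    """Weir-Cockerham theta for allele-count (gene-copy) data.

    Per-allele among/within mean squares on allele indicators, summed over
    alleles; can be slightly negative around zero differentiation.
    """
    mat = _counts_matrix(tables)
    n_i = mat.sum(axis=1)
    if (n_i == 0).any():
        raise ValueError("a population has no observed gene copies")
    r = mat.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    n_tot = n_i.sum()
    n_c = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)
    p = mat / n_i[:, None]
    p_bar = (mat.sum(axis=0)) / n_tot
    msa = (n_i[:, None] * (p - p_bar) ** 2).sum(axis=0) / (r - 1)
    msw = (n_i[:, None] * p * (1 - p)).sum(axis=0) / (n_tot - r)
    num = (msa - msw).sum()
    den = (msa + (n_c - 1) * msw).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


@dataclass
class DifferentiationResult:
    locus: str
    gst: float
    theta: float
    pairwise_gst: dict[tuple[str, str], float]
    exact_p: float | None = None

    @property
    def gst_truncated(self) -> float:
        return max(0.0, self.gst) if not math.isnan(self.gst) else self.gst


def fst(
    populations: list[PopulationSample],
    locus: str,
    resolution: int | None = 3,
    exact_test: bool = False,
    mc_steps: int = 10000,
    seed: int | None = None,
) -> DifferentiationResult:
    """Multi-population differentiation at one locus.

    Nei's G_ST is the headline estimator; Weir-Cockerham theta is reported as
    a cross-check.  Monomorphic-everywhere loci yield NaN.
    """
    tables = [allele_counts(p, locus, resolution) for p in populations]
    alleles = {a for t in tables for a in t}
    if len(alleles) < 2:
        nan = float("nan")
        return DifferentiationResult(locus, nan, nan, {}, None)
    gst = nei_gst(tables)
    theta = weir_cockerham_theta(tables)
    pairwise = {}
    for i in range(len(populations)):
        for j in range(i + 1, len(populations)):
            pair = [tables[i], tables[j]]
            if len({a for t in pair for a in t}) < 2:
                pairwise[(populations[i].name, populations[j].name)] = float("nan")
            else:
                pairwise[(populations[i].name, populations[j].name)] = nei_gst(pair)
    p_val = None
    if exact_test:
        mat = _counts_matrix(tables).astype(int)
        p_val = exact_test_differentiation(mat, mc_steps=mc_steps, seed=seed)
    return DifferentiationResult(locus, gst, theta, pairwise, p_val)


def _log_table_prob(mat: np.ndarray) -> float:
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    n = mat.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(mat + 1).sum()
    )


def exact_test_differentiation(
    counts_table: np.ndarray,
    mc_steps: int = 10000,
    seed: int | None = None,
) -> float:
    """Monte Carlo exact test of population differentiation.

    Holding the margins of the population x allele count table fixed, the
    P value is the probability of a table at most as likely as the observed
    one under the multivariate hypergeometric null.  The (count+1)/(steps+1)
    estimator keeps P in (0, 1].
    """
    mat = np.asarray(counts_table, dtype=int)
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    if (row > 0).sum() < 2 or (col > 0).sum() < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    obs_logp = _log_table_prob(mat)
    labels = np.repeat(np.arange(mat.shape[1]), col)
    row_edges = np.cumsum(row)[:-1]
    hits = 0
    tol = 1e-9
    for _ in range(mc_steps):
        rng.shuffle(labels)
        sim = np.zeros_like(mat)
        for r_idx, chunk in enumerate(np.split(labels, row_edges)):
            np.add.at(sim[r_idx], chunk, 1)
        if _log_table_prob(sim) <= obs_logp + tol:
            hits += 1
    return (hits + 1) / (mc_steps + 1)
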