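"""Region and neutral-marker contrasts of selection statistics.

The centromeric KIR region (KIR3DL3..KIR2DL1) encodes the strongest NK-cell
educator receptors; purifying selection there is expected to depress
per-gene dN-dS, push observed homozygosity above its neutral expectation,
and lower heterozygosity relative to neutral genomic markers while the
telomeric region (KIR2DL4..KIR3DL2) behaves neutrally.  These contrasts are
tested with label permutations: genes (or loci) are shuffled between the
two groups and the difference of group means is recomputed, exhaustively
when the label space is small and by seeded Monte Carlo otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RegionContrast", "region_contrast", "neutral_marker_contrast", "DEFAULT_REGION_MAP"]

#: Default gene -> region assignment for allele-bearing KIR genes.
DEFAULT_REGION_MAP: dict[str, str] = {
    "KIR3DL3": "centromeric",
    "KIR2DS2": "centromeric",
    "KIR2DL2": "centromeric",
    "KIR2DL3": "centromeric",
    "KIR2DL5B": "centromeric",
    "KIR2DS3": "centromeric",
    "KIR2DL1": "centromeric",
    "KIR2DL4": "telomeric",
    "KIR3DL1": "telomeric",
    "KIR3DS1": "telomeric",
    "KIR2DL5A": "telomeric",
    "KIR2DS5": "telomeric",
    "KIR2DS1": "telomeric",
    "KIR2DS4": "telomeric",
    "KIR3DL2": "telomeric",
}


@dataclass
class RegionContrast:
    """Permutation contrast of a per-gene statistic between two regions."""

    region_means: dict[str, float]
    difference: float  # centromeric mean - telomeric mean
    p_value: float
    method: str  # "exact" | "montecarlo"
    permutations: int
    gene_values: dict[str, float]


def _collapse(per_gene: dict) -> dict[str, float]:
    """Average per-population values into one value per gene if nested."""
    out: dict[str, float] = {}
    for gene, val in per_gene.items():
        if isinstance(val, dict):
            vals = [v for v in val.values() if v is not None and not math.isnan(v)]
            if vals:
                out[gene] = float(np.mean(vals))
        elif val is not None and not math.isnan(val):
            out[gene] = float(val)
    return out


def _two_group_permutation(
    x: np.ndarray,
    y: np.ndarray,
    permutations: int,
    seed: int | None,
    exhaustive_limit: int = 200000,
) -> tuple[float, float, str, int]:
    """Two-sided permutation test on the difference of means."""
    obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    total = math.comb(n, nx)
    tol = 1e-12
    if total <= min(exhaustive_limit, max(permutations, 20000)):
        hits = 0
        idx = range(n)
        for combo in itertools.combinations(idx, nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            diff = pooled[mask].mean() - pooled[~mask].mean()
            if abs(diff) >= abs(obs) - tol:
                hits += 1
        return obs, hits / total, "exact", total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(pooled)
        diff = perm[:nx].mean() - perm[nx:].mean()
        if abs(diff) >= abs(obs) - tol:
            hits += 1
    return obs, (hits + 1) / (permutations + 1), "montecarlo", permutations


def region_contrast(
    per_gene_stats: dict,
    region_map: dict[str, str] | None = None,
    permutations: int = 10000,
    seed: int | None = None,
) -> RegionContrast:
    """Centromeric-vs-telomeric contrast of a per-gene statistic.

    *per_gene_stats* maps gene -> value, or gene -> {population: value}
    (population values are averaged, unweighted, before the gene-label
    permutation).  The region aggregate is the unweighted mean over genes.
    """
    region_map = region_map or DEFAULT_REGION_MAP
    gene_values = _collapse(per_gene_stats)
    cen = np.array(
        [v for g, v in gene_values.items() if region_map.get(g) == "centromeric"]
    )
    tel = np.array(
        [v for g, v in gene_values.items() if region_map.get(g) == "telomeric"]
    )
    if cen.size == 0 or tel.size == 0:
        raise ValueError("each region needs at least one gene with a value")
    obs, p, method, nperm = _two_group_permutation(cen, tel, permutations, seed)
    return RegionContrast(
        region_means={"centromeric": float(cen.mean()), "telomeric": float(tel.mean())},
        difference=obs,
        p_value=p,
        method=method,
        permutations=nperm,
        gene_values=gene_values,
    )


def neutral_marker_contrast(
    focal_values,
    background_values,
    permutations: int = 10000,
    seed: int | None = None,
) -> dict[str, float | str]:
    """Contrast a focal set of per-locus statistics against a neutral panel.

    Used for Cen-vs-Msat, Tel-vs-Msat and Cen-vs-Tel heterozygosity or FST
    comparisons: the difference of means is referenced to the permutation
    distribution obtained by shuffling loci between the two sets.
    """
    x = np.asarray(list(focal_values), dtype=float)
    y = np.asarray(list(background_values), dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 loci in each set")
    obs, p, method, nperm = _two_group_permutation(x, y, permutations, seed)
    return {
        "difference": obs,
        "focal_mean": float(x.mean()),
        "background_mean": float(y.mean()),
        "p_value": p,
        "method": method,
        "permutations": nperm,
    }
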