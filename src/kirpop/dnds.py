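"""Nei-Gojobori synonymous/nonsynonymous substitution analysis.

Site counting follows the unweighted Nei-Gojobori method: at each codon
position the synonymous site fraction is the share of the three possible
single-nucleotide changes that preserve the amino acid (changes creating a
stop codon count as nonsynonymous), and per-codon fractions are averaged
over the two sequences being compared.  Codons differing at more than one
position are resolved by averaging synonymous/nonsynonymous step counts
over all minimal mutational pathways that avoid stop-codon intermediates.
Proportions are corrected for multiple hits with the Jukes-Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``, and the selection Z-test uses codon-
bootstrap variances: ``Z = (dN - dS) / sqrt(Var(dS) + Var(dN))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .genotypes import CodonAlignment

__all__ = [
    "SaturationError",
    "DnDsResult",
    "jukes_cantor",
    "nei_gojobori",
    "dn_ds_z_test",
]

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}

_GENETIC_CODE = {
    c: aa
    for c, aa in zip(
        _CODONS,
        "FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR" "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG",
    )
}
_STOPS = {c for c, aa in _GENETIC_CODE.items() if aa == "*"}


class SaturationError(ValueError):
    """Jukes-Cantor correction undefined (p >= 3/4)."""

    def __init__(self, p: float):
        super().__init__(f"proportion {p:.4f} >= 3/4; Jukes-Cantor correction undefined")
        self.raw_p = p


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance ``-(3/4) ln(1 - (4/3) p)``."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(p)
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=1)
def _site_table() -> np.ndarray:
    """Synonymous site count per codon (stop codons get NaN)."""
    syn = np.full(64, np.nan)
    for c in _CODONS:
        if c in _STOPS:
            continue
        total = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == c[pos]:
                    continue
                mutant = c[:pos] + b + c[pos + 1 :]
                if mutant not in _STOPS and _GENETIC_CODE[mutant] == _GENETIC_CODE[c]:
                    total += 1.0 / 3.0
        syn[_CODON_INDEX[c]] = total
    return syn


def _path_steps(c1: str, c2: str) -> tuple[float, float]:
    """Average (nonsyn, syn) step counts over minimal mutational paths."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        nd = sd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and len(order) > 1 and nxt != c2:
                return None
            if _GENETIC_CODE.get(cur) == _GENETIC_CODE.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:  # every path crosses a stop; count stop steps as nonsynonymous
        for order in itertools.permutations(diff_pos):
            cur = c1
            nd = sd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                aa_cur, aa_nxt = _GENETIC_CODE[cur], _GENETIC_CODE[nxt]
                if aa_cur == aa_nxt and "*" not in (aa_cur, aa_nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((nd, sd))
    nd = float(np.mean([v[0] for v in valid]))
    sd = float(np.mean([v[1] for v in valid]))
    return nd, sd


@lru_cache(maxsize=1)
def _diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 tables of average nonsynonymous and synonymous differences."""
    nd = np.zeros((64, 64))
    sd = np.zeros((64, 64))
    for i, c1 in enumerate(_CODONS):
        if c1 in _STOPS:
            continue
        for j, c2 in enumerate(_CODONS):
            if c2 in _STOPS or i == j:
                continue
            nd[i, j], sd[i, j] = _path_steps(c1, c2)
    return nd, sd


def _encode(seq: str) -> np.ndarray:
    """Codon indices of a sequence; -1 marks gapped/invalid codons."""
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int32)
    for i in range(n):
        codon = seq[3 * i : 3 * i + 3]
        idx = _CODON_INDEX.get(codon, -1)
        if idx >= 0 and codon not in _STOPS:
            out[i] = idx
    return out


def nei_gojobori(seq_a: str, seq_b: str) -> dict[str, float]:
    """Pairwise Nei-Gojobori estimates for two equal-length coding sequences.

    Returns nd/sd (difference counts), n_sites/s_sites, the proportions
    pN/pS, and the Jukes-Cantor distances dN/dS (NaN where the correction is
    undefined, with the raw proportion still reported).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        raise ValueError("no comparable codons")
    nd_t, sd_t = _diff_tables()
    syn = _site_table()
    av, bv = a[valid], b[valid]
    nd = float(nd_t[av, bv].sum())
    sd = float(sd_t[av, bv].sum())
    s_sites = float(((syn[av] + syn[bv]) / 2).sum())
    n_sites = 3.0 * av.size - s_sites
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    out = {
        "nd": nd,
        "sd": sd,
        "n_sites": n_sites,
        "s_sites": s_sites,
        "pn": pn,
        "ps": ps,
    }
    for key, p in (("dn", pn), ("ds", ps)):
        try:
            out[key] = jukes_cantor(p)
        except SaturationError:
            out[key] = float("nan")
    return out


@dataclass
class DnDsResult:
    """Mean pairwise dN/dS with codon-bootstrap Z-test of selection."""

    locus: str | None
    dn: float
    ds: float
    var_dn: float
    var_ds: float
    z: float
    p_value: float
    bootstrap: int
    pn: float
    ps: float

    @property
    def dn_minus_ds(self) -> float:
        return self.dn - self.ds


def _jc_array(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = (p >= 0) & (p < 0.75)
    out[ok] = -0.75 * np.log(1.0 - 4.0 * p[ok] / 3.0)
    return out


def dn_ds_z_test(
    alignment: CodonAlignment,
    bootstrap: int = 1000,
    seed: int | None = None,
    weighted: bool = False,
) -> DnDsResult:
    """Codon-bootstrap Z-test of selection on a multi-allele alignment.

    dN and dS are means of the pairwise Nei-Gojobori distances (weighted by
    products of allele frequencies when *weighted* and the alignment carries
    weights); variances come from resampling codon columns with replacement
    *bootstrap* times.  Identical sequences throughout give an undefined Z
    (NaN).
    """
    seqs = [s.upper() for s in alignment.sequences]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    enc = np.array([_encode(s) for s in seqs])
    n_codons = enc.shape[1]
    nd_t, sd_t = _diff_tables()
    syn_t = _site_table()
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    if weighted and alignment.weights is not None:
        w = np.array([alignment.weights[i] * alignment.weights[j] for i, j in pairs])
    else:
        w = np.ones(len(pairs))
    w = w / w.sum()

    nd_mat = np.zeros((len(pairs), n_codons))
    sd_mat = np.zeros((len(pairs), n_codons))
    ns_mat = np.zeros((len(pairs), n_codons))
    ss_mat = np.zeros((len(pairs), n_codons))
    for p_idx, (i, j) in enumerate(pairs):
        a, b = enc[i], enc[j]
        valid = (a >= 0) & (b >= 0)
        av = np.where(valid, a, 0)
        bv = np.where(valid, b, 0)
        nd_mat[p_idx] = np.where(valid, nd_t[av, bv], 0.0)
        sd_mat[p_idx] = np.where(valid, sd_t[av, bv], 0.0)
        s_sites = np.where(valid, (syn_t[av] + syn_t[bv]) / 2.0, 0.0)
        ss_mat[p_idx] = s_sites
        ns_mat[p_idx] = np.where(valid, 3.0 - s_sites, 0.0)

    def point_estimates(col_weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(dN, dS) per bootstrap column-weight vector set (cols x B)."""
        nd = nd_mat @ col_weights
        sd = sd_mat @ col_weights
        ns = ns_mat @ col_weights
        ss = ss_mat @ col_weights
        with np.errstate(divide="ignore", invalid="ignore"):
            pn = np.where(ns > 0, nd / ns, 0.0)
            ps = np.where(ss > 0, sd / ss, 0.0)
        dn = _jc_array(pn)
        ds = _jc_array(ps)
        # weighted mean over pairs, ignoring saturated (NaN) pairs
        dn_wsum = np.nansum(np.where(np.isnan(dn), 0.0, w[:, None]), axis=0)
        ds_wsum = np.nansum(np.where(np.isnan(ds), 0.0, w[:, None]), axis=0)
        return (
            np.nansum(np.where(np.isnan(dn), 0.0, dn) * w[:, None], axis=0) / dn_wsum,
            np.nansum(np.where(np.isnan(ds), 0.0, ds) * w[:, None], axis=0) / ds_wsum,
        )

    ones = np.ones((n_codons, 1))
    dn_point, ds_point = point_estimates(ones)
    dn_hat, ds_hat = float(dn_point[0]), float(ds_point[0])

    # overall proportions for reporting
    tot_nd, tot_sd = float((nd_mat @ ones).sum()), float((sd_mat @ ones).sum())
    tot_ns, tot_ss = float((ns_mat @ ones).sum()), float((ss_mat @ ones).sum())
    pn_hat = tot_nd / tot_ns if tot_ns else 0.0
    ps_hat = tot_sd / tot_ss if tot_ss else 0.0

    if tot_nd + tot_sd == 0:
        return DnDsResult(alignment.locus, 0.0, 0.0, 0.0, 0.0, float("nan"), float("nan"), bootstrap, 0.0, 0.0)

    rng = np.random.default_rng(seed)
    boot_w = rng.multinomial(n_codons, np.full(n_codons, 1.0 / n_codons), size=bootstrap).T.astype(float)
    dn_b, ds_b = point_estimates(boot_w)
    var_dn = float(np.nanvar(dn_b, ddof=1))
    var_ds = float(np.nanvar(ds_b, ddof=1))
    denom = math.sqrt(var_dn + var_ds)
    if denom == 0 or math.isnan(dn_hat) or math.isnan(ds_hat):
        z = float("nan")
        p = float("nan")
    else:
        z = (dn_hat - ds_hat) / denom
        p = float(2.0 * norm.sf(abs(z)))
    return DnDsResult(
        locus=alignment.locus,
        dn=dn_hat,
        ds=ds_hat,
        var_dn=var_dn,
        var_ds=var_ds,
        z=z,
        p_value=p,
        bootstrap=bootstrap,
        pn=pn_hat,
        ps=ps_hat,
    )
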