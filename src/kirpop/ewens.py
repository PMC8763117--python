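"""Ewens-Watterson homozygosity test with exact (Slatkin-style) tail
probabilities under the Ewens sampling formula.

The neutral null for an allele configuration of ``n`` gene copies in ``k``
distinct alleles is the Ewens sampling formula conditioned on (n, k), which
is free of the mutation parameter theta: for a partition of n with part
multiplicities ``a_j`` (a_j parts of size j),

    P(partition | n, k)  proportional to  n! / (prod_j j^a_j * a_j!),

the normalizer being the unsigned Stirling number of the first kind.  The
test compares the observed homozygosity ``F = sum p_i^2`` with its
conditional distribution: the reported lower-tail P is Pr(F <= F_obs)
(heterozygote excess gives P near 0, homozygote excess P near 1; two-tailed
significance at P < 0.025 or P > 0.975).

Small samples are handled by exact enumeration over integer partitions;
larger ones by conditional rejection sampling from the Chinese restaurant
process with theta matched to the expected allele count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "EwensResult",
    "watterson_F",
    "ewens_conditional_distribution",
    "sample_ewens_conditional",
    "ewens_expected_F",
    "ewens_watterson_test",
    "crp_sample",
    "theta_for_expected_k",
    "expected_k",
]

#: exact enumeration is used at or below this sample size by default
ENUMERATION_LIMIT = 60

_F_TOL = 1e-9


def watterson_F(freqs) -> float:
    """Observed homozygosity ``F = sum f_i^2`` of a frequency vector."""
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency vector")
    return float(np.sum(freqs**2))


def _partitions_exact_k(n: int, k: int, max_part: int | None = None):
    """Yield partitions of *n* into exactly *k* parts (non-increasing)."""
    if max_part is None:
        max_part = n
    if k == 0:
        if n == 0:
            yield ()
        return
    if n < k:
        return
    for first in range(min(max_part, n - k + 1), 0, -1):
        for rest in _partitions_exact_k(n - first, k - 1, first):
            yield (first,) + rest


@lru_cache(maxsize=512)
def ewens_conditional_distribution(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of F given (n, k).

    Returns ``(f_values, probabilities)`` sorted by F ascending, one entry
    per integer partition of n into k parts.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    log_weights = []
    f_values = []
    for part in _partitions_exact_k(n, k):
        mult: dict[int, int] = {}
        for j in part:
            mult[j] = mult.get(j, 0) + 1
        lw = -sum(a * math.log(j) + math.lgamma(a + 1) for j, a in mult.items())
        log_weights.append(lw)
        f_values.append(sum((j / n) ** 2 for j in part))
    lw_arr = np.array(log_weights)
    probs = np.exp(lw_arr - lw_arr.max())
    probs /= probs.sum()
    f_arr = np.array(f_values)
    order = np.argsort(f_arr)
    return f_arr[order], probs[order]


def expected_k(n: int, theta: float) -> float:
    """E[number of alleles] in a CRP sample of size n at mutation rate theta."""
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def theta_for_expected_k(n: int, k: int) -> float:
    """Solve E[K_n(theta)] = k by bisection on log(theta)."""
    if k <= 1:
        return 1e-9
    if k >= n:
        return 1e9
    lo, hi = -12.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_k(n, math.exp(mid)) < k:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def crp_sample(n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """One Chinese-restaurant-process allele configuration of n gene copies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    counts: list[int] = []
    for i in range(n):
        if i == 0 or rng.random() < theta / (theta + i):
            counts.append(1)
        else:
            u = rng.random() * i
            acc = 0.0
            for idx, c in enumerate(counts):
                acc += c
                if u < acc:
                    counts[idx] += 1
                    break
    return np.array(sorted(counts, reverse=True))


def _crp_batch(
    n: int, theta: float, batch: int, kmax: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized CRP: returns (counts matrix batch x kmax, allele counts)."""
    counts = np.zeros((batch, kmax), dtype=np.int32)
    counts[:, 0] = 1
    k_count = np.ones(batch, dtype=np.int32)
    for i in range(1, n):
        new = rng.random(batch) < theta / (theta + i)
        u = rng.random(batch) * i
        cum = np.cumsum(counts, axis=1)
        old_idx = (cum <= u[:, None]).sum(axis=1)
        new_idx = np.minimum(k_count, kmax - 1)
        idx = np.where(new, new_idx, old_idx.astype(np.int32))
        counts[np.arange(batch), idx] += 1
        k_count += new.astype(np.int32)
    return counts, k_count


def sample_ewens_conditional(
    n: int, k: int, replicates: int, seed: int | None = None
) -> np.ndarray:
    """Sample allele configurations from the ESF conditional on (n, k).

    Rejection sampling from the CRP at theta matched so E[K] = k; the
    conditional law given K = k does not depend on theta, so accepted
    samples follow the exact conditional distribution.  Returns a
    ``replicates x k`` count matrix (rows sum to n).
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    if k == n:
        return np.ones((replicates, k), dtype=np.int32)
    if k == 1:
        return np.full((replicates, 1), n, dtype=np.int32)
    rng = np.random.default_rng(seed)
    theta = theta_for_expected_k(n, k)
    kmax = min(n, max(3 * k + 16, 24))
    out = np.empty((replicates, k), dtype=np.int32)
    got = 0
    attempts = 0
    while got < replicates:
        attempts += 1
        if attempts > 4000:
            raise RuntimeError(
                f"conditional sampler failed to accept enough draws (n={n}, k={k})"
            )
        batch = max(256, int(1.5 * (replicates - got)))
        counts, k_count = _crp_batch(n, theta, batch, kmax, rng)
        ok = counts[k_count == k]
        if ok.size:
            take = min(replicates - got, ok.shape[0])
            cols = np.sort(ok[:take], axis=1)[:, ::-1][:, :k]
            out[got : got + take] = cols
            got += take
    return out


def ewens_expected_F(
    n: int,
    k: int,
    replicates: int = 1000,
    seed: int | None = None,
    method: str = "auto",
) -> float:
    """Expected homozygosity under the ESF conditional on (n, k)."""
    if method == "auto":
        method = "enumerate" if n <= ENUMERATION_LIMIT else "montecarlo"
    if method == "enumerate":
        f_vals, probs = ewens_conditional_distribution(n, k)
        return float(np.dot(f_vals, probs))
    if method == "montecarlo":
        configs = sample_ewens_conditional(n, k, replicates, seed)
        f = np.sum((configs / n) ** 2, axis=1)
        return float(f.mean())
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EwensResult:
    """Ewens-Watterson test outcome for one locus."""

    locus: str | None
    n: int
    k: int
    f_obs: float
    f_exp: float
    p_lower: float  # Pr(F <= F_obs) under the conditional null
    p_upper: float
    method: str
    replicates: int

    @property
    def slatkin_p(self) -> float:
        return self.p_lower

    @property
    def significant(self) -> bool:
        return self.p_lower < 0.025 or self.p_lower > 0.975

    @property
    def direction(self) -> str:
        if self.p_lower > 0.975:
            return "homozygosity-excess"
        if self.p_lower < 0.025:
            return "heterozygosity-excess"
        return "neutral"


def ewens_watterson_test(
    counts,
    replicates: int = 1000,
    seed: int | None = None,
    method: str = "auto",
    locus: str | None = None,
    null_f: np.ndarray | None = None,
) -> EwensResult:
    """Ewens-Watterson neutrality test on an allele count configuration.

    ``p_lower = Pr(F <= F_obs)`` including the point mass at F_obs; Monte
    Carlo tails use the (hits+1)/(replicates+1) estimator.  A precomputed
    null sample of F values (*null_f*, from the same (n, k)) may be supplied
    to share work across loci.  k = 1 is degenerate (P undefined, NaN).
    """
    counts = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
    counts = counts[counts > 0]
    n = int(counts.sum())
    k = int(counts.size)
    f_obs = watterson_F(counts / n)
    if k < 2:
        return EwensResult(locus, n, k, f_obs, 1.0, float("nan"), float("nan"), "degenerate", 0)
    if method == "auto":
        method = "enumerate" if n <= ENUMERATION_LIMIT else "montecarlo"
    if null_f is not None:
        f_exp = float(null_f.mean())
        p_lo = (np.sum(null_f <= f_obs + _F_TOL) + 1) / (null_f.size + 1)
        p_hi = (np.sum(null_f >= f_obs - _F_TOL) + 1) / (null_f.size + 1)
        return EwensResult(locus, n, k, f_obs, f_exp, float(p_lo), float(p_hi), "montecarlo", int(null_f.size))
    if method == "enumerate":
        f_vals, probs = ewens_conditional_distribution(n, k)
        f_exp = float(np.dot(f_vals, probs))
        p_lo = float(probs[f_vals <= f_obs + _F_TOL].sum())
        p_hi = float(probs[f_vals >= f_obs - _F_TOL].sum())
        return EwensResult(locus, n, k, f_obs, f_exp, p_lo, p_hi, "enumerate", 0)
    configs = sample_ewens_conditional(n, k, replicates, seed)
    f = np.sum((configs / n) ** 2, axis=1)
    f_exp = float(f.mean())
    p_lo = float((np.sum(f <= f_obs + _F_TOL) + 1) / (replicates + 1))
    p_hi = float((np.sum(f >= f_obs - _F_TOL) + 1) / (replicates + 1))
    return EwensResult(locus, n, k, f_obs, f_exp, p_lo, p_hi, "montecarlo", replicates)
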