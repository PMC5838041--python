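"""Allele counts and the Reich–Patterson F_ST estimator.

The estimator works from per-population allele counts ``(a, n)`` — the
alternate-allele count and the number of called chromosomes.  Per site::

    h_i = a_i (n_i - a_i) / (n_i (n_i - 1))          (within-pop het term)
    N   = (a_1/n_1 - a_2/n_2)^2 - h_1/n_1 - h_2/n_2  (numerator)
    D   = N + h_1 + h_2                              (denominator)

and the ratio-of-sums ``F_ST = sum(N) / sum(D)`` over usable sites.  The
small-sample corrections make the estimator unbiased in N and D, so it
behaves well with few diploids per population; under panmixia it
scatters around zero and individual estimates can be negative.

Uncertainty comes from a delete-one block jackknife whose unit is the
RAD contig (all SNPs of a contig leave together, respecting physical
linkage).  Both a normal-approximation interval and the percentile
interval of the delete-one estimates are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeDataset, PopulationMap


@dataclass
class AlleleCountTable:
    """Per population x site alternate-allele counts.

    ``a[p, s]`` alternate alleles, ``n[p, s]`` called chromosomes
    (2 x called diploid genotypes; ``n = 0`` means the population is
    entirely uncalled at the site).
    """

    populations: list[str]
    a: np.ndarray
    n: np.ndarray
    contig: np.ndarray
    pos: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.a.shape[1])

    def row(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(
                f"population {population!r} not in table "
                f"(have {self.populations})"
            ) from None

    def pair(self, pop1: str, pop2: str):
        i, j = self.row(pop1), self.row(pop2)
        return self.a[i], self.n[i], self.a[j], self.n[j]


def allele_counts(
    dataset: GenotypeDataset, popmap: PopulationMap
) -> AlleleCountTable:
    """Tally (a, n) per population per site from diploid dosages."""
    unmapped = [s for s in dataset.sample_ids if s not in popmap.table.index]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped}")
    pops = [
        p
        for p in popmap.populations
        if any(s in dataset.sample_ids for s in popmap.samples_for(p))
    ]
    col_of = {s: i for i, s in enumerate(dataset.sample_ids)}
    S = dataset.n_sites
    a = np.zeros((len(pops), S), dtype=np.int64)
    n = np.zeros((len(pops), S), dtype=np.int64)
    for pi, pop in enumerate(pops):
        cols = [col_of[s] for s in popmap.samples_for(pop) if s in col_of]
        d = dataset.dosage[:, cols]
        called = d >= 0
        a[pi] = np.where(called, d, 0).sum(axis=1)
        n[pi] = 2 * called.sum(axis=1)
    return AlleleCountTable(
        populations=pops, a=a, n=n, contig=dataset.contig, pos=dataset.pos
    )


@dataclass
class FstResult:
    estimate: float
    ci_low: float
    ci_high: float
    percentile_low: float
    percentile_high: float
    se: float
    n_sites_used: int
    n_sites_skipped: int
    n_blocks: int
    block_numerators: np.ndarray
    block_denominators: np.ndarray

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "percentile_low": self.percentile_low,
            "percentile_high": self.percentile_high,
            "se": self.se,
            "n_sites_used": self.n_sites_used,
            "n_sites_skipped": self.n_sites_skipped,
            "n_blocks": self.n_blocks,
        }


def _site_terms(a1, n1, a2, n2):
    """Vectorized per-site (N, D, usable) under the Reich index."""
    usable = (n1 >= 2) & (n2 >= 2)
    # skip sites monomorphic across both populations (contribute 0/0)
    mono = ((a1 == 0) & (a2 == 0)) | ((a1 == n1) & (a2 == n2))
    usable &= ~mono
    a1f, n1f = a1[usable].astype(float), n1[usable].astype(float)
    a2f, n2f = a2[usable].astype(float), n2[usable].astype(float)
    h1 = a1f * (n1f - a1f) / (n1f * (n1f - 1.0))
    h2 = a2f * (n2f - a2f) / (n2f * (n2f - 1.0))
    num = (a1f / n1f - a2f / n2f) ** 2 - h1 / n1f - h2 / n2f
    den = num + h1 + h2
    return num, den, usable


def jackknife_ci(
    block_numerators: np.ndarray,
    block_denominators: np.ndarray,
    confidence: float = 0.95,
) -> tuple[float, float, float, float, float, int]:
    """Delete-one jackknife for a ratio-of-sums over blocks.

    Returns ``(ci_low, ci_high, pct_low, pct_high, se, n_blocks_used)``.
    The normal interval is ``theta_hat +/- z * SE_jack``; the percentile
    interval is taken over the delete-one estimates themselves.  Blocks
    whose removal makes the denominator non-positive are skipped with a
    warning.
    """
    bn = np.asarray(block_numerators, dtype=float)
    bd = np.asarray(block_denominators, dtype=float)
    if bn.shape != bd.shape or bn.ndim != 1:
        raise ValueError("block sums must be matching 1-d arrays")
    tn, td = bn.sum(), bd.sum()
    if td <= 0:
        raise ValueError("total denominator is non-positive")
    theta = tn / td
    denom_minus = td - bd
    ok = denom_minus > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} jackknife block(s) skipped "
            "(delete-one denominator <= 0)"
        )
    g = int(ok.sum())
    if g < 2:
        raise ValueError("need at least 2 usable jackknife blocks")
    theta_minus = (tn - bn[ok]) / denom_minus[ok]
    se = float(np.sqrt((g - 1) / g * np.sum((theta_minus - theta_minus.mean()) ** 2)))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    lo, hi = theta - z * se, theta + z * se
    alpha = (1.0 - confidence) / 2.0
    plo, phi = np.quantile(theta_minus, [alpha, 1.0 - alpha])
    return float(lo), float(hi), float(plo), float(phi), se, g


def reich_fst(
    counts: AlleleCountTable,
    pop1: str,
    pop2: str,
    confidence: float = 0.95,
) -> FstResult:
    """Reich–Patterson F_ST between two populations with a contig jackknife.

    Sites with fewer than 2 called chromosomes in either population (and
    sites monomorphic across the pair) are skipped and counted in
    ``n_sites_skipped``.  Symmetric in its two population arguments.
    """
    a1, n1, a2, n2 = counts.pair(pop1, pop2)
    num, den, usable = _site_terms(a1, n1, a2, n2)
    if num.size == 0 or den.sum() <= 0:
        raise ValueError(
            f"no usable sites for F_ST between {pop1!r} and {pop2!r}"
        )
    estimate = float(num.sum() / den.sum())

    codes, _ = pd.factorize(counts.contig[usable])
    n_blocks = int(codes.max()) + 1
    bn = np.bincount(codes, weights=num, minlength=n_blocks)
    bd = np.bincount(codes, weights=den, minlength=n_blocks)
    if n_blocks >= 2:
        lo, hi, plo, phi, se, g = jackknife_ci(bn, bd, confidence)
    else:  # single block: no resampling uncertainty available
        lo = hi = plo = phi = estimate
        se, g = 0.0, n_blocks
    return FstResult(
        estimate=estimate,
        ci_low=lo,
        ci_high=hi,
        percentile_low=plo,
        percentile_high=phi,
        se=se,
        n_sites_used=int(usable.sum()),
        n_sites_skipped=int((~usable).sum()),
        n_blocks=g,
        block_numerators=bn,
        block_denominators=bd,
    )
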