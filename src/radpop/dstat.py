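"""Four-taxon ABBA-BABA D-statistics with subsampling reliability.

For a topology (((P1, P2), P3), O) and per-population alternate-allele
frequencies ``p_i = a_i / n_i`` the site-pattern weights are the
symmetric frequency forms::

    ABBA = (1-p1) p2 p3 (1-p4)  +  p1 (1-p2) (1-p3) p4
    BABA = p1 (1-p2) p3 (1-p4)  +  (1-p1) p2 (1-p3) p4

    D = sum(ABBA - BABA) / sum(ABBA + BABA)

Including the outgroup frequency in both orientations makes D exactly
invariant to which allele is labeled REF at a site, so genotype dosages
can be used directly without polarizing against the outgroup first.
D > 0 indicates excess allele sharing between P2 and P3 (gene flow, if
the four-taxon tree is correct); swapping P1 and P2 negates D.

With anonymous RAD contigs there is no linkage map for the usual block
jackknife, so reliability is assessed by recomputing D on many random
subsamples of the informative sites at several retention levels
(99/95/90/80/70% by default, 1,000 replicates each) and reporting the
mean and SD of the subsampled D at each level.  The subsampling SD at
retention level ``l`` measures only the leave-out noise, which is
``sqrt((1-l)/l)`` times the sampling standard error of D over the full
site set; :func:`call_significance` rescales it by ``sqrt(l/(1-l))`` to
recover a full-data standard-error estimate before applying the |Z|
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import AlleleCountTable

RETENTION_LEVELS: tuple[float, ...] = (0.99, 0.95, 0.90, 0.80, 0.70)


@dataclass
class SubsampleSummary:
    """Mean/SD of D over subsample replicates at one retention level."""

    level: float
    mean: float
    sd: float
    n_reps: int
    n_sites: int


@dataclass
class DstatResult:
    topology: tuple[str, str, str, str]  # (P1, P2, P3, outgroup)
    D: float
    abba_sum: float
    baba_sum: float
    n_sites_used: int
    subsampling: dict[float, SubsampleSummary] = field(default_factory=dict)
    significant: bool | None = None
    z_threshold: float = 3.0
    z_scores: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "topology": list(self.topology),
            "D": self.D,
            "abba_sum": self.abba_sum,
            "baba_sum": self.baba_sum,
            "n_sites_used": self.n_sites_used,
            "subsampling": {
                f"{lvl:g}": {"mean": s.mean, "sd": s.sd, "n_reps": s.n_reps}
                for lvl, s in self.subsampling.items()
            },
            "significant": self.significant,
            "z_threshold": self.z_threshold,
            "z_scores": {f"{l:g}": z for l, z in self.z_scores.items()},
        }


def _pattern_sums(
    counts: AlleleCountTable, p1: str, p2: str, p3: str, outgroup: str
):
    """Per-site (abba, baba) weights over sites called in all four groups."""
    rows = [counts.row(p) for p in (p1, p2, p3, outgroup)]
    n = counts.n[rows]
    ok = (n >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts.a[rows][:, ok] / n[:, ok]
    q = 1.0 - f
    abba = q[0] * f[1] * f[2] * q[3] + f[0] * q[1] * q[2] * f[3]
    baba = f[0] * q[1] * f[2] * q[3] + q[0] * f[1] * q[2] * f[3]
    return abba, baba, ok


def d_statistic(
    counts: AlleleCountTable, p1: str, p2: str, p3: str, outgroup: str
) -> DstatResult:
    """Nominal D for one four-taxon topology (no subsampling)."""
    abba, baba, ok = _pattern_sums(counts, p1, p2, p3, outgroup)
    total = abba.sum() + baba.sum()
    if not ok.any() or total <= 0:
        raise ValueError(
            f"no informative sites for topology ({p1},{p2},{p3};{outgroup})"
        )
    return DstatResult(
        topology=(p1, p2, p3, outgroup),
        D=float((abba.sum() - baba.sum()) / total),
        abba_sum=float(abba.sum()),
        baba_sum=float(baba.sum()),
        n_sites_used=int(ok.sum()),
    )


def subsample_reliability(
    counts: AlleleCountTable,
    topology: tuple[str, str, str, str],
    levels: tuple[float, ...] = RETENTION_LEVELS,
    n_reps: int = 1000,
    seed: int | None = None,
    unit: str = "site",
) -> dict[float, SubsampleSummary]:
    """Mean/SD of D over random subsamples at each retention level.

    ``unit="site"`` subsamples SNP sites (the default); ``unit="contig"``
    subsamples whole contigs, which is the conservative choice when
    within-contig linkage matters.  Deterministic under a fixed seed.
    """
    p1, p2, p3, og = topology
    abba, baba, ok = _pattern_sums(counts, p1, p2, p3, og)
    diff, tot = abba - baba, abba + baba
    informative = tot > 0
    diff, tot = diff[informative], tot[informative]
    if unit == "contig":
        codes, _ = pd.factorize(counts.contig[ok][informative])
        n_groups = int(codes.max()) + 1
        diff = np.bincount(codes, weights=diff, minlength=n_groups)
        tot = np.bincount(codes, weights=tot, minlength=n_groups)
    elif unit != "site":
        raise ValueError(f"unknown subsampling unit {unit!r}")
    S = diff.shape[0]
    if S == 0:
        raise ValueError("no informative sites to subsample")

    rng = np.random.default_rng(seed)
    out: dict[float, SubsampleSummary] = {}
    for level in levels:
        m = int(np.floor(level * S))
        if m < 1:
            raise ValueError(
                f"retention level {level} leaves no {unit}s (universe {S})"
            )
        if m == S:  # degenerate: every subsample is the full set
            d_full = float(diff.sum() / tot.sum())
            out[level] = SubsampleSummary(level, d_full, 0.0, n_reps, m)
            continue
        ds = np.empty(n_reps)
        for r in range(n_reps):
            idx = rng.permutation(S)[:m]
            ds[r] = diff[idx].sum() / tot[idx].sum()
        out[level] = SubsampleSummary(
            level, float(ds.mean()), float(ds.std(ddof=1)), n_reps, m
        )
    return out


def call_significance(
    result: DstatResult, z_threshold: float = 3.0
) -> bool:
    """Flag admixture from the subsampling spread at the 99% level.

    The subsampling SD at retention ``l`` is converted to a full-data
    standard-error estimate via the finite-population factor
    ``sqrt(l / (1 - l))``; the call is ``|mean| > z_threshold * SE`` at
    the most stringent (largest < 1) retention level.  Per-level Z
    scores are stored on the result.  A zero SD with a non-zero mean is
    flagged significant with a degeneracy warning.
    """
    if not result.subsampling:
        raise ValueError("subsampling results not populated")
    result.z_threshold = z_threshold
    result.z_scores = {}
    usable = [l for l in result.subsampling if l < 1.0]
    for level, s in sorted(result.subsampling.items(), reverse=True):
        if level >= 1.0:
            continue
        se = s.sd * np.sqrt(level / (1.0 - level))
        result.z_scores[level] = float(np.inf if se == 0 else abs(s.mean) / se)
    if not usable:
        raise ValueError("need a retention level below 1.0 to call significance")
    top = max(usable)
    s = result.subsampling[top]
    if s.sd == 0.0:
        if s.mean != 0.0:
            warnings.warn(
                "zero subsampling SD with non-zero mean D; "
                "flagging significant (degenerate spread)"
            )
            result.significant = True
        else:
            result.significant = False
        return result.significant
    result.significant = bool(result.z_scores[top] > z_threshold)
    return result.significant


def dstat_analysis(
    counts: AlleleCountTable,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    levels: tuple[float, ...] = RETENTION_LEVELS,
    n_reps: int = 1000,
    seed: int | None = None,
    unit: str = "site",
    z_threshold: float = 3.0,
) -> DstatResult:
    """Nominal D + subsampling reliability + significance call."""
    result = d_statistic(counts, p1, p2, p3, outgroup)
    result.subsampling = subsample_reliability(
        counts, (p1, p2, p3, outgroup), levels, n_reps, seed, unit
    )
    call_significance(result, z_threshold)
    return result


def dstat_table(results: list[DstatResult]) -> pd.DataFrame:
    """Results as a table: one row per topology, mean±SD per level."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "P1": r.topology[0],
            "P2": r.topology[1],
            "P3": r.topology[2],
            "outgroup": r.topology[3],
            "D": r.D,
            "n_sites": r.n_sites_used,
            "significant": r.significant,
        }
        for level in sorted(r.subsampling, reverse=True):
            s = r.subsampling[level]
            row[f"mean_{level:g}"] = s.mean
            row[f"sd_{level:g}"] = s.sd
        rows.append(row)
    return pd.DataFrame(rows)
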