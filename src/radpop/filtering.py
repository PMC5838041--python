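"""Hard-filter cascade, thinning, and EBSP locus selection.

The cascade applies, in fixed order:

1. drop non-biallelic sites;
2. drop sites with QUAL below ``min_site_qual``;
3. drop sites with mapping quality below ``min_mapping_quality``;
4. set genotypes with GQ below ``min_genotype_quality`` to missing;
5. set genotypes with depth below ``min_depth`` to missing
   (``site_level_depth=True`` instead drops sites whose mean called
   depth is below the threshold);
6. drop sites whose total called depth exceeds the
   ``excess_coverage_quantile`` of the post-(1–5) site depth
   distribution (a guard against collapsed repeats/transposons);
7. drop sites called in fewer than ``min_individuals_present``
   individuals.

Annotations recorded as absent (NaN QUAL/MQ, -1 DP/GQ) pass the
corresponding rule: absence of evidence does not fail a call.  The
report accounts for every site (input = retained + sum removed) and for
every genotype masked, and carries the per-individual called-site
counts used to flag failed samples.

The order of rules 6 and 7 matters (the coverage quantile is computed
before low-call sites are dropped); the shipped order is part of the
contract and is pinned by a regression fixture in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MISSING, GenotypeDataset

RULE_NAMES = (
    "non_biallelic",
    "low_site_qual",
    "low_mapping_quality",
    "excess_coverage",
    "low_individual_presence",
)
MASK_RULES = ("low_genotype_quality", "low_depth")


@dataclass
class FilterConfig:
    min_site_qual: float = 30.0
    min_genotype_quality: float = 20.0
    min_mapping_quality: float = 20.0
    min_depth: float = 5.0
    excess_coverage_quantile: float = 0.95
    min_individuals_present: int = 2
    site_level_depth: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.excess_coverage_quantile < 1.0:
            raise ValueError("excess_coverage_quantile must be in (0, 1)")
        for name in (
            "min_site_qual",
            "min_genotype_quality",
            "min_mapping_quality",
            "min_depth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_individuals_present < 0:
            raise ValueError("min_individuals_present must be >= 0")


@dataclass
class FilterReport:
    sites_in: int = 0
    sites_out: int = 0
    sites_removed: dict[str, int] = field(default_factory=dict)
    genotypes_masked: dict[str, int] = field(default_factory=dict)
    per_sample_called: dict[str, int] = field(default_factory=dict)
    flagged_individuals: list[str] = field(default_factory=list)

    def check_accounting(self) -> None:
        total = self.sites_out + sum(self.sites_removed.values())
        if total != self.sites_in:
            raise AssertionError(
                f"filter accounting broken: {self.sites_in} in, "
                f"{self.sites_out} out + {sum(self.sites_removed.values())} removed"
            )

    def to_dict(self) -> dict:
        return {
            "sites_in": self.sites_in,
            "sites_out": self.sites_out,
            "sites_removed": dict(self.sites_removed),
            "genotypes_masked": dict(self.genotypes_masked),
            "per_sample_called": dict(self.per_sample_called),
            "flagged_individuals": list(self.flagged_individuals),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        lines = [f"sites in: {self.sites_in}", f"sites retained: {self.sites_out}"]
        for rule, n in self.sites_removed.items():
            lines.append(f"  removed by {rule}: {n}")
        for rule, n in self.genotypes_masked.items():
            lines.append(f"  genotypes masked by {rule}: {n}")
        if self.flagged_individuals:
            lines.append(f"flagged individuals: {', '.join(self.flagged_individuals)}")
        return "\n".join(lines) + "\n"


def apply_filters(
    dataset: GenotypeDataset, config: FilterConfig | None = None
) -> tuple[GenotypeDataset, FilterReport]:
    """Run the hard-filter cascade; returns (filtered dataset, report)."""
    config = config or FilterConfig()
    report = FilterReport(sites_in=dataset.n_sites)
    report.sites_removed = {r: 0 for r in RULE_NAMES}
    report.genotypes_masked = {r: 0 for r in MASK_RULES}
    if dataset.n_sites == 0:
        report.per_sample_called = {s: 0 for s in dataset.sample_ids}
        return dataset, report

    alive = np.ones(dataset.n_sites, dtype=bool)

    # (1) biallelic only
    bad = alive & (dataset.n_alt_alleles != 1)
    report.sites_removed["non_biallelic"] = int(bad.sum())
    alive &= ~bad

    # (2) site QUAL  (absent QUAL passes)
    with np.errstate(invalid="ignore"):
        bad = alive & (dataset.qual < config.min_site_qual)
    report.sites_removed["low_site_qual"] = int(bad.sum())
    alive &= ~bad

    # (3) mapping quality  (absent MQ passes)
    with np.errstate(invalid="ignore"):
        bad = alive & (dataset.mq < config.min_mapping_quality)
    report.sites_removed["low_mapping_quality"] = int(bad.sum())
    alive &= ~bad

    # (4) genotype quality mask
    dosage = dataset.dosage.copy()
    called = dosage >= 0
    gq_known = dataset.gq >= 0
    mask = called & gq_known & (dataset.gq < config.min_genotype_quality)
    mask[~alive] = False
    report.genotypes_masked["low_genotype_quality"] = int(mask.sum())
    dosage[mask] = MISSING
    called = dosage >= 0

    # (5) depth: genotype-level mask (default) or site-level drop
    dp_known = dataset.depth >= 0
    if config.site_level_depth:
        with np.errstate(invalid="ignore"):
            site_mean = np.where(
                (called & dp_known).sum(axis=1) > 0,
                np.where(called & dp_known, dataset.depth, 0).sum(axis=1)
                / np.maximum((called & dp_known).sum(axis=1), 1),
                np.nan,
            )
        bad = alive & (site_mean < config.min_depth)
        report.sites_removed.setdefault("low_site_depth", 0)
        report.sites_removed["low_site_depth"] = int(bad.sum())
        alive &= ~bad
    else:
        mask = called & dp_known & (dataset.depth < config.min_depth)
        mask[~alive] = False
        report.genotypes_masked["low_depth"] = int(mask.sum())
        dosage[mask] = MISSING
        called = dosage >= 0

    # (6) excess coverage: upper tail of the post-(1-5) site-depth
    # distribution, total called depth across samples
    site_depth = np.where(called & dp_known, dataset.depth, 0).sum(axis=1)
    if alive.any():
        cutoff = np.quantile(
            site_depth[alive], config.excess_coverage_quantile
        )
        bad = alive & (site_depth > cutoff)
    else:
        bad = np.zeros_like(alive)
    report.sites_removed["excess_coverage"] = int(bad.sum())
    alive &= ~bad

    # (7) presence in >= min_individuals_present individuals
    n_called = called.sum(axis=1)
    bad = alive & (n_called < config.min_individuals_present)
    report.sites_removed["low_individual_presence"] = int(bad.sum())
    alive &= ~bad

    out = dataset.subset_sites(np.flatnonzero(alive))
    out.dosage = dosage[alive]
    report.sites_out = out.n_sites
    report.per_sample_called = {
        s: int((out.dosage[:, j] >= 0).sum())
        for j, s in enumerate(out.sample_ids)
    }
    report.check_accounting()
    return out, report


def flag_low_call_individuals(
    report: FilterReport, min_fraction_of_median: float = 0.25
) -> list[str]:
    """Samples whose called-site count falls far below the cohort median.

    A sample is flagged when its count is strictly below
    ``min_fraction_of_median`` times the median count across samples
    (threshold 0 therefore never flags).  The flagged list is also
    recorded on the report.
    """
    counts = report.per_sample_called
    if len(counts) < 2:
        return []
    median = float(np.median(list(counts.values())))
    flagged = [
        s for s, c in counts.items() if c < min_fraction_of_median * median
    ]
    report.flagged_individuals = flagged
    return flagged


def thin_one_snp_per_contig(
    dataset: GenotypeDataset, mode: str = "first", seed: int | None = None
) -> GenotypeDataset:
    """Keep one SNP per contig (unlinked-marker datasets).

    ``mode="first"`` (default) keeps the lowest-position SNP — a
    deterministic, idempotent choice; ``mode="random"`` draws one SNP
    per contig with the given seed.
    """
    rng = np.random.default_rng(seed) if mode == "random" else None
    keep: list[int] = []
    for _, idx in dataset.contig_index().items():
        if mode == "first":
            keep.append(int(idx[np.argmin(dataset.pos[idx])]))
        elif mode == "random":
            keep.append(int(rng.choice(idx)))
        else:
            raise ValueError(f"unknown thinning mode {mode!r}")
    return dataset.subset_sites(np.sort(np.asarray(keep, dtype=np.intp)))


def subset_no_missing(dataset: GenotypeDataset) -> GenotypeDataset:
    """Retain only sites called in every sample (complete cases)."""
    complete = (dataset.dosage >= 0).all(axis=1)
    return dataset.subset_sites(np.flatnonzero(complete))


# ---------------------------------------------------------------------------
# EBSP locus selection / export
# ---------------------------------------------------------------------------

_IUPAC = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


@dataclass
class EbspSelection:
    """Replicate locus draws plus per-locus SNP alignments."""

    replicates: list[list[str]]  # contig ids per replicate
    candidates: list[str]
    alignments: dict[str, dict[str, str]]  # contig -> sample -> SNP string


def _site_base(ref: str, alt: str, dosage: int) -> str:
    if dosage < 0:
        return "N"
    if dosage == 0:
        return ref
    if dosage == 2:
        return alt
    return _IUPAC.get(frozenset((ref.upper(), alt.upper())), "N")


def select_ebsp_loci(
    dataset: GenotypeDataset,
    n_loci: int = 50,
    snps_per_locus: int = 4,
    min_individuals: int | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
    forward_read_length: int = 95,
) -> EbspSelection:
    """Select loci for skyline-plot analyses and build their alignments.

    Candidate loci are contigs carrying exactly ``snps_per_locus`` SNPs
    at positions within the forward read, with every such SNP called in
    at least ``min_individuals`` individuals (default: all samples).
    Each of ``n_replicates`` replicates draws ``n_loci`` candidates
    without replacement; replicates are independent and may overlap.
    """
    if min_individuals is None:
        min_individuals = dataset.n_samples
    candidates: list[str] = []
    aln: dict[str, dict[str, str]] = {}
    for contig, idx in dataset.contig_index().items():
        fwd = idx[dataset.pos[idx] <= forward_read_length]
        if len(fwd) != snps_per_locus:
            continue
        calls = (dataset.dosage[fwd] >= 0).sum(axis=1)
        if np.any(calls < min_individuals):
            continue
        candidates.append(contig)
        aln[contig] = {
            s: "".join(
                _site_base(
                    str(dataset.ref[i]), str(dataset.alt[i]),
                    int(dataset.dosage[i, j]),
                )
                for i in fwd
            )
            for j, s in enumerate(dataset.sample_ids)
        }
    if len(candidates) < n_loci:
        raise ValueError(
            f"only {len(candidates)} candidate loci with {snps_per_locus} "
            f"forward-read SNPs in >= {min_individuals} individuals; "
            f"{n_loci} requested"
        )
    rng = np.random.default_rng(seed)
    replicates = [
        sorted(rng.choice(candidates, size=n_loci, replace=False).tolist())
        for _ in range(n_replicates)
    ]
    return EbspSelection(replicates=replicates, candidates=candidates, alignments=aln)


def write_ebsp_exports(
    selection: EbspSelection, out_dir: str | Path
) -> list[Path]:
    """Write each replicate's loci as per-locus FASTA plus one NEXUS.

    The NEXUS holds every locus of the replicate as its own charset so
    downstream coalescent software can model loci independently.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for r, loci in enumerate(selection.replicates, start=1):
        rep_dir = out_dir / f"replicate_{r}"
        rep_dir.mkdir(exist_ok=True)
        samples = list(next(iter(selection.alignments.values())))
        concat = {s: [] for s in samples}
        charsets = []
        offset = 0
        for locus in loci:
            seqs = selection.alignments[locus]
            records = [
                SeqRecord(Seq(seqs[s]), id=s, description="") for s in samples
            ]
            fasta = rep_dir / f"{locus}.fasta"
            SeqIO.write(records, str(fasta), "fasta")
            written.append(fasta)
            L = len(seqs[samples[0]])
            charsets.append((locus, offset + 1, offset + L))
            offset += L
            for s in samples:
                concat[s].append(seqs[s])
        nexus = rep_dir / "loci.nex"
        with open(nexus, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(
                f"  DIMENSIONS NTAX={len(samples)} NCHAR={offset};\n"
                "  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n"
            )
            for s in samples:
                fh.write(f"    {s}  {''.join(concat[s])}\n")
            fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
            for name, lo, hi in charsets:
                fh.write(f"  CHARSET {name} = {lo}-{hi};\n")
            fh.write("END;\n")
        written.append(nexus)
    return written
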