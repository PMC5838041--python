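"""Core containers and file I/O.

The in-memory representation of a multi-sample SNP call set is a
:class:`GenotypeDataset`: dense numpy arrays of allele dosages (0/1/2,
-1 = uncalled) plus the per-site (QUAL, MQ) and per-genotype (DP, GQ)
annotations that the hard-filter cascade consumes.  Sites are grouped by
the RAD contig they were assembled on; within-contig linkage is what the
contig-level jackknife and the one-SNP-per-contig thinning care about.

VCF reading goes through cyvcf2, writing through pysam, so the on-disk
format is ordinary VCF 4.2 with ``GT:DP:GQ`` genotype fields and an
``INFO/MQ`` tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for uncalled genotypes / absent annotations


@dataclass
class GenotypeDataset:
    """Samples x sites allele-dosage matrix with quality metadata.

    Attributes
    ----------
    sample_ids
        Ordered sample labels (VCF column order).
    contig, pos
        Per-site contig id and 1-based position. Sites belonging to one
        contig are stored contiguously, positions strictly increasing
        within a contig.
    ref, alt
        Reference and (first) alternate allele per site.
    qual, mq
        Site QUAL and RMS mapping quality; ``nan`` when absent.
    dosage
        (n_sites, n_samples) int8; number of alternate alleles, -1 missing.
    depth, gq
        (n_sites, n_samples) int32/int16 per-genotype DP and GQ; -1 absent.
    n_alt_alleles
        Number of ALT alleles in the source record; >1 flags a
        multi-allelic site (removed by the biallelic filter rule).
    contig_lengths
        Optional contig -> length map used for VCF headers and for
        deciding what counts as the forward read.
    """

    sample_ids: list[str]
    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    mq: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    n_alt_alleles: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def called(self) -> np.ndarray:
        """Boolean (n_sites, n_samples) mask of called genotypes."""
        return self.dosage >= 0

    def contig_index(self) -> dict[str, np.ndarray]:
        """Map contig id -> array of site indices (in storage order)."""
        index: dict[str, list[int]] = {}
        for i, c in enumerate(self.contig):
            index.setdefault(str(c), []).append(i)
        return {c: np.asarray(ix, dtype=np.intp) for c, ix in index.items()}

    def subset_sites(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            contig=self.contig[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            mq=self.mq[idx],
            dosage=self.dosage[idx],
            depth=self.depth[idx],
            gq=self.gq[idx],
            n_alt_alleles=self.n_alt_alleles[idx],
            contig_lengths=dict(self.contig_lengths),
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeDataset":
        pos_of = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos_of]
        if missing:
            raise KeyError(f"samples not in dataset: {missing}")
        cols = np.asarray([pos_of[s] for s in keep], dtype=np.intp)
        return GenotypeDataset(
            sample_ids=list(keep),
            contig=self.contig,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            qual=self.qual,
            mq=self.mq,
            dosage=self.dosage[:, cols],
            depth=self.depth[:, cols],
            gq=self.gq[:, cols],
            n_alt_alleles=self.n_alt_alleles,
            contig_lengths=dict(self.contig_lengths),
        )

    def validate(self) -> None:
        """Check container invariants; raise ValueError on violation."""
        S, N = self.dosage.shape
        if S != self.n_sites or N != self.n_samples:
            raise ValueError("dosage shape does not match sites/samples")
        for c, ix in self.contig_index().items():
            p = self.pos[ix]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing in {c}")


@dataclass
class PopulationMap:
    """Sample -> population assignment with locality coordinates.

    Backed by a DataFrame indexed by sample id with columns
    ``population``, ``lat``, ``lon`` (decimal degrees).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"population", "lat", "lon"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"popmap table needs columns {sorted(need)}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: list[str] = []
        for p in self.table["population"]:
            if p not in seen:
                seen.append(p)
        return seen

    def population_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "population"])

    def samples_for(self, population: str) -> list[str]:
        mask = self.table["population"] == population
        return list(self.table.index[mask])

    def locality_coords(self) -> pd.DataFrame:
        """Per-population (lat, lon): the mean of its samples' coordinates."""
        g = self.table.groupby("population", sort=False)[["lat", "lon"]].mean()
        return g.loc[self.populations]

    @classmethod
    def from_assignments(
        cls,
        assignment: dict[str, str],
        coords: dict[str, tuple[float, float]],
    ) -> "PopulationMap":
        rows = []
        for sample, pop in assignment.items():
            lat, lon = coords[pop]
            rows.append((sample, pop, lat, lon))
        df = pd.DataFrame(rows, columns=["sample", "population", "lat", "lon"])
        return cls(df.set_index("sample"))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
        return cls(df.set_index("sample"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.reset_index().rename(columns={"index": "sample"}).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeDataset:
    """Load a multi-sample VCF into a :class:`GenotypeDataset`.

    Multi-allelic records are retained and flagged via ``n_alt_alleles``
    (the biallelic filter rule removes them later).  Absent annotations
    (no QUAL, no INFO/MQ, no FORMAT DP/GQ) are stored as absent (``nan``
    or -1), never as zero.  A malformed file raises ``ValueError`` naming
    the offending position where the parser can identify one.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare Exception on bad files
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    contigs: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    qual: list[float] = []
    mq: list[float] = []
    nalt: list[int] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []

    warned_fmt: set[str] = set()
    n = len(samples)
    for var in vcf:
        try:
            contigs.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0] if var.ALT else ".")
            qual.append(float(var.QUAL) if var.QUAL is not None else np.nan)
            info_mq = var.INFO.get("MQ")
            mq.append(float(info_mq) if info_mq is not None else np.nan)
            nalt.append(len(var.ALT))

            gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3=unknown
            gt[gt == 3] = MISSING
            dosage_rows.append(gt)

            for name, rows, dtype, store in (
                ("DP", depth_rows, np.int32, None),
                ("GQ", gq_rows, np.int16, None),
            ):
                try:
                    arr = var.format(name)
                except KeyError:  # field not declared in the header
                    arr = None
                if arr is None:
                    if name not in warned_fmt:
                        warnings.warn(
                            f"FORMAT/{name} absent in {path!r}; stored as absent"
                        )
                        warned_fmt.add(name)
                    rows.append(np.full(n, MISSING, dtype=dtype))
                else:
                    vals = np.asarray(arr, dtype=np.int64).reshape(n, -1)[:, 0]
                    vals[vals < 0] = MISSING  # htslib missing sentinels
                    rows.append(vals.astype(dtype))
        except ValueError:
            raise
        except Exception as exc:
            raise ValueError(
                f"malformed VCF record near {var.CHROM}:{var.POS} in {path!r}: {exc}"
            ) from exc

    contig_lengths = {}
    for name in vcf.seqnames:
        try:
            contig_lengths[name] = vcf.seqlens[vcf.seqnames.index(name)]
        except Exception:
            pass

    S = len(pos)
    return GenotypeDataset(
        sample_ids=samples,
        contig=np.asarray(contigs, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        qual=np.asarray(qual, dtype=float),
        mq=np.asarray(mq, dtype=float),
        dosage=(
            np.vstack(dosage_rows) if S else np.empty((0, n), dtype=np.int8)
        ),
        depth=(
            np.vstack(depth_rows) if S else np.empty((0, n), dtype=np.int32)
        ),
        gq=np.vstack(gq_rows) if S else np.empty((0, n), dtype=np.int16),
        n_alt_alleles=np.asarray(nalt, dtype=np.int16),
        contig_lengths=contig_lengths,
    )


_GT_FOR_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write a dataset as uncompressed VCF 4.2 (GT:DP:GQ, INFO/MQ).

    An empty variant list yields a header-only file.  Output is
    deterministic: identical datasets produce byte-identical files.
    """
    import pysam

    header = pysam.VariantHeader()
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")

    lengths = dict(dataset.contig_lengths)
    seen: list[str] = []
    for c in dataset.contig:
        c = str(c)
        if c not in seen:
            seen.append(c)
    for c in seen:
        if c not in lengths:
            idx = dataset.contig == c
            lengths[c] = int(dataset.pos[idx].max())
    # contigs not carrying sites still go in the header if lengths known
    ordered = seen + [c for c in dataset.contig_lengths if c not in seen]
    for c in ordered:
        header.contigs.add(c, length=lengths[c])
    for s in dataset.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(dataset.n_sites):
            rec = out.new_record(
                contig=str(dataset.contig[i]),
                start=int(dataset.pos[i]) - 1,
                alleles=(str(dataset.ref[i]), str(dataset.alt[i])),
            )
            q = dataset.qual[i]
            rec.qual = None if np.isnan(q) else float(q)
            if not np.isnan(dataset.mq[i]):
                rec.info["MQ"] = float(dataset.mq[i])
            for j, s in enumerate(dataset.sample_ids):
                d = int(dataset.dosage[i, j])
                rec.samples[s]["GT"] = _GT_FOR_DOSAGE.get(d, (None, None))
                rec.samples[s].phased = False
                if dataset.depth[i, j] >= 0:
                    rec.samples[s]["DP"] = int(dataset.depth[i, j])
                if dataset.gq[i, j] >= 0:
                    rec.samples[s]["GQ"] = int(dataset.gq[i, j])
            out.write(rec)
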