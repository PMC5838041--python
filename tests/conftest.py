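"""Shared fixtures: hand-built datasets with known filter outcomes."""

from __future__ import annotations

import numpy as np
import pytest

from radpop.io import GenotypeDataset


def make_dataset(
    dosage,
    contig=None,
    pos=None,
    qual=None,
    mq=None,
    depth=None,
    gq=None,
    n_alt=None,
    sample_ids=None,
    contig_lengths=None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from plain lists with benign defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    S, N = dosage.shape
    if contig is None:
        contig = [f"contig_{i + 1:05d}" for i in range(S)]
        pos = [1] * S
    if pos is None:
        pos = list(range(1, S + 1))
    return GenotypeDataset(
        sample_ids=sample_ids or [f"s{j + 1}" for j in range(N)],
        contig=np.asarray(contig, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * S, dtype=object),
        alt=np.asarray(["G"] * S, dtype=object),
        qual=np.asarray(qual if qual is not None else [50.0] * S, dtype=float),
        mq=np.asarray(mq if mq is not None else [55.0] * S, dtype=float),
        dosage=dosage,
        depth=np.asarray(
            depth if depth is not None else np.full((S, N), 20), dtype=np.int32
        ),
        gq=np.asarray(
            gq if gq is not None else np.full((S, N), 60), dtype=np.int16
        ),
        n_alt_alleles=np.asarray(
            n_alt if n_alt is not None else [1] * S, dtype=np.int16
        ),
        contig_lengths=dict(contig_lengths or {}),
    )


@pytest.fixture
def audited_filter_dataset():
    """20-site, 4-sample dataset with a fully hand-audited filter outcome.

    Composition (site indices):
      0-2   triallelic                      -> removed by non_biallelic
      3-4   QUAL 29.9 / 25                  -> removed by low_site_qual
      5     MQ 19                           -> removed by low_mapping_quality
      6-9   GQ/DP masking leaves <2 called  -> removed by low_individual_presence
      10    total called depth 500          -> removed by excess_coverage
      11-19 clean (QUAL 40, MQ 55, GQ 60, DP 20, all called)  -> retained

    Audit (by hand): after rules 1-3 14 sites remain with called-depth
    totals {site6: 20, site7: 0, site8: 20, site9: 20, site10: 500,
    sites11-19: 80 each}; the 0.95 quantile (linear interpolation over
    14 values) is 80 + 0.35*(500-80) = 227, so only site 10 exceeds it;
    rule 7 then drops sites 6-9.  Expected: 9 sites retained; removals
    {3, 2, 1, 1, 4}; genotype masks {low_genotype_quality: 7, low_depth: 4}.
    """
    S, N = 20, 4
    dosage = np.ones((S, N), dtype=np.int8)
    qual = np.full(S, 40.0)
    mq = np.full(S, 55.0)
    depth = np.full((S, N), 20, dtype=np.int32)
    gq = np.full((S, N), 60, dtype=np.int16)
    n_alt = np.ones(S, dtype=np.int16)

    n_alt[0:3] = 2
    qual[3], qual[4] = 29.9, 25.0
    mq[5] = 19.0
    gq[6] = [10, 10, 10, 50]
    depth[7] = [2, 2, 2, 2]
    gq[8] = [50, 10, 10, 10]
    dosage[9] = [-1, -1, 0, 0]
    gq[9] = [50, 50, 10, 50]
    depth[10] = [200, 100, 100, 100]
    # vary retained-site dosages so downstream stats see polymorphism
    dosage[11:20] = np.array(
        [[0, 1, 2, 1]] * 5 + [[2, 1, 0, 0]] * 4, dtype=np.int8
    )

    expected = {
        "sites_out": 9,
        "sites_removed": {
            "non_biallelic": 3,
            "low_site_qual": 2,
            "low_mapping_quality": 1,
            "excess_coverage": 1,
            "low_individual_presence": 4,
        },
        "genotypes_masked": {"low_genotype_quality": 7, "low_depth": 4},
        "retained_positions": list(range(12, 21)),  # pos = index + 1
    }
    ds = make_dataset(
        dosage,
        contig=[f"contig_{i + 1:05d}" for i in range(S)],
        pos=list(range(1, S + 1)),
        qual=qual,
        mq=mq,
        depth=depth,
        gq=gq,
        n_alt=n_alt,
    )
    return ds, expected
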