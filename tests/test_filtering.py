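"""Filter cascade, thinning, complete-case subsetting, EBSP selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radpop as rp
from radpop.filtering import FilterConfig, select_ebsp_loci, write_ebsp_exports
from conftest import make_dataset


class TestCascade:
    def test_hand_audited_fixture(self, audited_filter_dataset):
        ds, expected = audited_filter_dataset
        out, report = rp.apply_filters(ds, FilterConfig())
        assert report.sites_out == expected["sites_out"]
        for rule, n in expected["sites_removed"].items():
            assert report.sites_removed[rule] == n, rule
        for rule, n in expected["genotypes_masked"].items():
            assert report.genotypes_masked[rule] == n, rule
        assert out.pos.tolist() == expected["retained_positions"]
        report.check_accounting()

    def test_qual_threshold_boundary(self):
        ds = make_dataset([[1, 1], [1, 1]], qual=[29.0, 30.0])
        out, report = rp.apply_filters(ds, FilterConfig(min_individuals_present=1))
        assert report.sites_removed["low_site_qual"] == 1
        assert out.qual.tolist() == [30.0]

    def test_min_present_one_keeps_everything_with_a_call(self):
        # equal called-depth totals so the coverage rule stays quiet
        ds = make_dataset(
            [[1, -1], [-1, 2], [0, 1]],
            depth=[[20, 20], [20, 20], [10, 10]],
        )
        cfg = FilterConfig(min_individuals_present=1)
        out, report = rp.apply_filters(ds, cfg)
        assert report.sites_removed["low_individual_presence"] == 0
        # dosage 0 counts as called, so site 3 stays too
        assert out.n_sites == 3

    def test_absent_annotations_pass(self):
        ds = make_dataset(
            [[1, 1]], qual=[np.nan], mq=[np.nan],
            depth=[[-1, -1]], gq=[[-1, -1]],
        )
        out, report = rp.apply_filters(ds, FilterConfig())
        assert out.n_sites == 1
        assert sum(report.genotypes_masked.values()) == 0

    def test_empty_dataset_is_a_noop(self):
        ds = make_dataset(np.empty((0, 3), dtype=np.int8), contig=[], pos=[])
        out, report = rp.apply_filters(ds, FilterConfig())
        assert out.n_sites == 0 and report.sites_in == 0
        report.check_accounting()

    def test_site_level_depth_mode_drops_sites(self):
        ds = make_dataset([[1, 1], [1, 1]], depth=[[2, 2], [30, 30]])
        cfg = FilterConfig(site_level_depth=True, min_individuals_present=1)
        out, report = rp.apply_filters(ds, cfg)
        assert report.sites_removed["low_site_depth"] == 1
        assert out.n_sites == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_accounting_invariant_on_random_data(self, seed):
        """sites_in == sites_out + sum(removed) on arbitrary input."""
        rng = np.random.default_rng(seed)
        S, N = 120, 6
        ds = make_dataset(
            rng.integers(-1, 3, (S, N)),
            contig=[f"c{i // 4}" for i in range(S)],
            pos=[(i % 4) + 1 for i in range(S)],
            qual=rng.uniform(0, 80, S),
            mq=rng.uniform(0, 60, S),
            depth=rng.integers(0, 60, (S, N)),
            gq=rng.integers(0, 99, (S, N)),
            n_alt=rng.integers(1, 3, S),
        )
        _, report = rp.apply_filters(ds, FilterConfig())
        report.check_accounting()  # raises on violation

    def test_excess_coverage_bound(self):
        """Rule 6 removes at most ceil((1-q) * S) of the surviving sites."""
        rng = np.random.default_rng(0)
        S = 200
        ds = make_dataset(
            np.ones((S, 4), dtype=np.int8),
            depth=rng.integers(5, 400, (S, 4)),
        )
        _, report = rp.apply_filters(ds, FilterConfig())
        assert 0 <= report.sites_removed["excess_coverage"] <= int(np.ceil(0.05 * S))


class TestLowCallIndividuals:
    def _report(self, counts):
        r = rp.FilterReport(per_sample_called=counts)
        return r

    def test_equal_counts_flag_nothing(self):
        assert rp.flag_low_call_individuals(self._report({"a": 5, "b": 5})) == []

    def test_one_failed_sample_is_flagged(self):
        counts = {"a": 100, "b": 100, "c": 100, "d": 10}
        assert rp.flag_low_call_individuals(self._report(counts)) == ["d"]

    def test_zero_threshold_never_flags(self):
        counts = {"a": 100, "b": 0}
        assert rp.flag_low_call_individuals(self._report(counts), 0.0) == []

    def test_single_sample_returns_empty(self):
        assert rp.flag_low_call_individuals(self._report({"a": 3})) == []


class TestThinningAndSubsetting:
    def test_keeps_first_snp_per_contig(self):
        ds = make_dataset(
            [[1], [1], [1], [1], [0]],
            contig=["c1", "c1", "c1", "c1", "c2"],
            pos=[10, 20, 30, 40, 5],
        )
        out = rp.thin_one_snp_per_contig(ds)
        assert out.n_sites == 2
        assert out.pos.tolist() == [10, 5]

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(
            rng.integers(0, 3, (30, 3)),
            contig=[f"c{i // 3}" for i in range(30)],
            pos=[(i % 3) + 1 for i in range(30)],
        )
        once = rp.thin_one_snp_per_contig(ds)
        twice = rp.thin_one_snp_per_contig(once)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert once.pos.tolist() == twice.pos.tolist()

    def test_one_site_per_informative_contig(self):
        cfg = rp.SimulationConfig(seed=2, engine="beta", n_contigs=400,
                                  samples_per_deme=3, outgroup_samples=2)
        ds, _, _ = rp.simulate_dataset(cfg)
        out = rp.thin_one_snp_per_contig(ds)
        n_contigs_with_data = len(set(ds.contig))
        assert out.n_sites == n_contigs_with_data
        assert len(set(out.contig)) == out.n_sites

    def test_random_mode_is_seeded(self):
        ds = make_dataset(
            [[1], [1], [1]], contig=["c1"] * 3, pos=[1, 2, 3]
        )
        a = rp.thin_one_snp_per_contig(ds, mode="random", seed=7)
        b = rp.thin_one_snp_per_contig(ds, mode="random", seed=7)
        assert a.pos.tolist() == b.pos.tolist()

    def test_subset_no_missing_matches_brute_force(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(-1, 3, (200, 5))
        ds = make_dataset(dosage)
        out = rp.subset_no_missing(ds)
        expected = int(sum((row >= 0).all() for row in dosage))
        assert out.n_sites == expected
        assert (out.dosage >= 0).all()

    def test_subset_no_missing_is_identity_without_missingness(self):
        ds = make_dataset([[0, 1], [2, 1]])
        out = rp.subset_no_missing(ds)
        np.testing.assert_array_equal(out.dosage, ds.dosage)


def _ebsp_dataset(n_candidates, n_samples=4, extra=0):
    """Contigs with exactly 4 forward-read SNPs, plus decoys."""
    contig, pos, rows = [], [], []
    for c in range(n_candidates):
        for k in range(4):
            contig.append(f"cand{c:03d}")
            pos.append(10 + 20 * k)  # all <= 95
            rows.append([1] * n_samples)
    for c in range(extra):
        # 4 SNPs but one beyond the forward read: not a candidate
        for k, p in enumerate([10, 30, 50, 200]):
            contig.append(f"far{c:03d}")
            pos.append(p)
            rows.append([1] * n_samples)
    return make_dataset(rows, contig=contig, pos=pos)


class TestEbspSelection:
    def test_snp_beyond_forward_read_disqualifies(self):
        ds = _ebsp_dataset(n_candidates=6, extra=3)
        sel = select_ebsp_loci(ds, n_loci=5, seed=0)
        assert len(sel.candidates) == 6
        assert all(c.startswith("cand") for c in sel.candidates)

    def test_too_few_candidates_reports_count(self):
        ds = _ebsp_dataset(n_candidates=49)
        with pytest.raises(ValueError, match="only 49 candidate"):
            select_ebsp_loci(ds, n_loci=50, seed=0)

    def test_min_individuals_rule(self):
        ds = _ebsp_dataset(n_candidates=3)
        ds.dosage[0, 0] = -1  # first SNP of cand000 missing in one sample
        assert len(select_ebsp_loci(ds, n_loci=2, seed=0).candidates) == 2
        sel = select_ebsp_loci(ds, n_loci=3, min_individuals=3, seed=0)
        assert len(sel.candidates) == 3

    def test_replicates_deterministic_and_sized(self):
        ds = _ebsp_dataset(n_candidates=20)
        a = select_ebsp_loci(ds, n_loci=10, n_replicates=3, seed=42)
        b = select_ebsp_loci(ds, n_loci=10, n_replicates=3, seed=42)
        assert a.replicates == b.replicates
        assert all(len(r) == 10 for r in a.replicates)
        assert all(len(set(r)) == 10 for r in a.replicates)

    def test_exports_parse_as_fasta_and_nexus(self, tmp_path):
        from Bio import AlignIO, SeqIO

        ds = _ebsp_dataset(n_candidates=8)
        ds.dosage[0] = [0, 1, 2, -1]  # ref / het / alt / missing codes
        sel = select_ebsp_loci(ds, n_loci=4, min_individuals=3, seed=1)
        files = write_ebsp_exports(sel, tmp_path)
        fastas = [f for f in files if f.suffix == ".fasta"]
        recs = list(SeqIO.parse(str(fastas[0]), "fasta"))
        assert len(recs) == 4 and len(recs[0].seq) == 4
        nexus = [f for f in files if f.suffix == ".nex"][0]
        aln = AlignIO.read(str(nexus), "nexus")
        assert len(aln) == 4 and aln.get_alignment_length() == 16


@given(
    st.integers(min_value=0, max_value=2**32 - 1),
    st.integers(min_value=1, max_value=3),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_thinning_output_is_subset_and_idempotent(seed, snps_per_contig):
    """Property: thinning is monotone (subset) and idempotent."""
    rng = np.random.default_rng(seed)
    n_contigs = int(rng.integers(1, 20))
    contig, pos = [], []
    for c in range(n_contigs):
        for k in range(snps_per_contig):
            contig.append(f"c{c}")
            pos.append(k + 1)
    ds = make_dataset(
        rng.integers(-1, 3, (len(pos), 3)), contig=contig, pos=pos
    )
    out = rp.thin_one_snp_per_contig(ds)
    assert out.n_sites == n_contigs
    pairs = set(zip(ds.contig, ds.pos))
    assert set(zip(out.contig, out.pos)) <= pairs
    again = rp.thin_one_snp_per_contig(out)
    assert again.pos.tolist() == out.pos.tolist()
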