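"""Footprint processing: trimming, filtering, mapping, regions, densities."""

import numpy as np
import pytest

from tcrkit import (
    FootprintRead,
    SyntheticSpec,
    assign_region,
    assign_regions,
    build_region_scheme,
    compare_isr_vs_utr,
    compute_densities,
    filter_reads,
    make_transcript,
    map_exact,
    process_library,
    simulate_footprints,
    trim_adapter,
)
from tcrkit.riboprofile import (
    CDS_BODY,
    FIVE_UTR,
    ISR_WINDOW,
    REGIONS,
    THREE_UTR_REST,
    RegionSchemeError,
)
from tcrkit.transcripts import TranscriptModel, find_downstream_inframe_stop

ADAPTER = "AGATCGGAAGAG"


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        read = FootprintRead("r1", "ACGTACGT" + ADAPTER)
        assert trim_adapter(read, ADAPTER).seq == "ACGTACGT"

    def test_read_without_adapter_unchanged(self):
        read = FootprintRead("r1", "ACGTACGTACGT")
        assert trim_adapter(read, ADAPTER).seq == read.seq

    def test_partial_adapter_at_three_prime_end(self):
        read = FootprintRead("r1", "ACGTACGT" + ADAPTER[:5])
        assert trim_adapter(read, ADAPTER, min_overlap=3).seq == "ACGTACGT"

    def test_short_suffix_below_min_overlap_kept(self):
        read = FootprintRead("r1", "ACGTACGT" + ADAPTER[:2])
        assert trim_adapter(read, ADAPTER, min_overlap=3).seq == read.seq

    def test_known_cut_points_recovered(self):
        """500 reads with the adapter appended at recorded cut points."""
        rng = np.random.default_rng(42)
        for i in range(500):
            cut = int(rng.integers(20, 35))
            insert = "".join(rng.choice(list("ACGT"), size=cut))
            tail_len = int(rng.integers(3, len(ADAPTER) + 1))
            trimmed = trim_adapter(
                FootprintRead(f"r{i}", insert + ADAPTER[:tail_len]), ADAPTER, min_overlap=3
            )
            # never cut later than the true insert boundary; an earlier cut is
            # only legitimate when the random insert itself ends in (or
            # contains) an adapter prefix of >= min_overlap nt
            assert trimmed.length <= cut
            insert_mimics_adapter = any(
                insert.endswith(ADAPTER[:k]) for k in range(1, cut + 1)
            )
            if not insert_mimics_adapter:
                assert trimmed.length == cut


class TestFilterReads:
    def test_length_boundary_inclusive(self):
        reads = [FootprintRead(f"r{n}", "A" * n) for n in (23, 24, 25)]
        kept, stats = filter_reads(reads, min_len=24)
        assert [r.length for r in kept] == [24, 25]
        assert stats.n_too_short == 1

    def test_n_containing_read_removed(self):
        reads = [FootprintRead("r1", "ACGT" * 7), FootprintRead("r2", "ACGTN" + "A" * 25)]
        kept, stats = filter_reads(reads)
        assert len(kept) == 1
        assert stats.n_with_n == 1

    def test_retained_count_matches_direct_tally(self):
        rng = np.random.default_rng(3)
        lengths = rng.integers(15, 40, size=10_000)
        reads = [FootprintRead(f"r{i}", "A" * int(n)) for i, n in enumerate(lengths)]
        kept, stats = filter_reads(reads, min_len=24)
        assert len(kept) == int((lengths >= 24).sum())
        assert stats.n_input == 10_000
        assert stats.n_removed + len(kept) == 10_000


@pytest.fixture(scope="module")
def transcript():
    t, _ = make_transcript(SyntheticSpec(seed=9))
    return t


@pytest.fixture(scope="module")
def scheme():
    t, a = make_transcript(SyntheticSpec(seed=6))
    return build_region_scheme(t, a)


class TestMapExact:
    def test_unique_substring_maps_at_source(self, transcript):
        read = FootprintRead("r1", transcript.seq[10:40])
        placement = map_exact(read, transcript)
        assert placement.mapped and placement.position == 10

    def test_one_mismatch_is_unmapped(self, transcript):
        seq = transcript.seq[10:40]
        flipped = ("A" if seq[15] != "A" else "C")
        read = FootprintRead("r1", seq[:15] + flipped + seq[16:])
        assert map_exact(read, transcript).status == "unmapped"

    def test_repeated_substring_is_ambiguous(self):
        t = TranscriptModel(
            id="rep",
            seq="ACGTACGTACGTACGTACGTACGTACGT" + "ATGAAATGA" + "TAA" + "ACGT",
            cds_start=28,
            cds_end=37,
        )
        read = FootprintRead("r1", "ACGTACGTACGT")
        assert map_exact(read, t).status == "ambiguous"


class TestRegionScheme:
    def test_offsets_arithmetic(self):
        from tcrkit.riboprofile import RegionScheme

        scheme = RegionScheme(
            transcript_length=400, cds_start=50, stop1_start=150, stop2_start=300,
            upstream_offset=12, downstream_offset=22,
        )
        assert scheme.intervals() == {
            FIVE_UTR: (0, 50),
            CDS_BODY: (50, 138),
            ISR_WINDOW: (138, 278),
            THREE_UTR_REST: (278, 400),
        }

    def test_built_scheme_places_window_by_offsets(self):
        # 51 + 102-nt CDS puts stop1 at 150; 147-nt ISR puts stop2 at 300
        t = TranscriptModel(
            id="toy",
            seq="A" * 51 + "ATG" + "GCA" * 32 + "TGA" + "GCA" * 49 + "TAA" + "A" * 97,
            cds_start=51,
            cds_end=153,
        )
        a = find_downstream_inframe_stop(t)
        assert t.stop1_start == 150 and a.stop2_start == 300 and len(t.seq) == 400
        scheme = build_region_scheme(t, a, 12, 22)
        assert scheme.intervals()[ISR_WINDOW] == (138, 278)
        assert scheme.intervals()[CDS_BODY] == (51, 138)
        assert scheme.intervals()[THREE_UTR_REST] == (278, 400)

    def test_zero_offsets_window_is_exact_isr_plus_stop1(self):
        t, a = make_transcript(SyntheticSpec(seed=2))
        scheme = build_region_scheme(t, a, 0, 0)
        assert scheme.intervals()[ISR_WINDOW] == (t.stop1_start, a.stop2_start)

    def test_intervals_partition_transcript(self):
        for seed in range(10):
            t, a = make_transcript(SyntheticSpec(seed=seed))
            scheme = build_region_scheme(t, a)
            total = sum(scheme.region_length(r) for r in REGIONS)
            assert total == len(t.seq)

    def test_short_isr_degenerate_window_rejected(self):
        t, a = make_transcript(SyntheticSpec(seed=4, isr_len=6))
        with pytest.raises(RegionSchemeError, match="requires length > 7"):
            build_region_scheme(t, a, 12, 22)

    def test_no_isr_rejected(self):
        t, a = make_transcript(SyntheticSpec(seed=4))
        flagged = find_downstream_inframe_stop(
            TranscriptModel(id="x", seq="ATGAAATGA" + "GCA" * 3, cds_start=0, cds_end=9)
        )
        with pytest.raises(RegionSchemeError, match="no ISR"):
            build_region_scheme(t, flagged)


class TestAssignRegion:
    def test_window_start_is_isr(self, scheme):
        assert assign_region(scheme.intervals()[ISR_WINDOW][0], scheme) == ISR_WINDOW

    def test_window_end_is_distal_utr(self, scheme):
        assert assign_region(scheme.intervals()[ISR_WINDOW][1], scheme) == THREE_UTR_REST

    def test_matches_interval_membership_oracle(self, scheme):
        rng = np.random.default_rng(8)
        positions = rng.integers(0, scheme.transcript_length, size=2000)
        vectorized = assign_regions(positions, scheme)
        for pos, label in zip(positions, vectorized):
            oracle = next(
                region
                for region, (lo, hi) in scheme.intervals().items()
                if lo <= pos < hi
            )
            assert assign_region(int(pos), scheme) == oracle == label

    def test_majority_rule_uses_overlap(self, scheme):
        lo = scheme.intervals()[ISR_WINDOW][0]
        # 5' end 2 nt before the window, 30-nt read: 28 nt in ISR wins
        assert assign_region(lo - 2, scheme, read_length=30, rule="majority") == ISR_WINDOW
        assert assign_region(lo - 2, scheme, read_length=30) == CDS_BODY


class TestDensities:
    def test_direct_division(self, scheme):
        labels = [ISR_WINDOW] * 10
        table = compute_densities(labels, scheme, "d0")
        assert table.densities[ISR_WINDOW] == pytest.approx(10 / scheme.region_length(ISR_WINDOW))

    def test_empty_input_zero_densities(self, scheme):
        table = compute_densities([], scheme, "d0")
        assert all(v == 0.0 for v in table.densities.values())

    def test_counts_match_direct_tally(self, scheme):
        rng = np.random.default_rng(10)
        labels = list(rng.choice(list(REGIONS), size=5000))
        table = compute_densities(labels, scheme, "d0", n_unmapped=7, n_ambiguous=3, n_filtered=11)
        for region in REGIONS:
            assert table.counts[region] == labels.count(region)
        assert table.total_reads == 5000 + 7 + 3 + 11

    def test_recovered_densities_within_sampling_error(self):
        """Simulated library densities land within 3 binomial SEs of truth."""
        spec = SyntheticSpec(seed=14, n_reads=50_000)
        t, a = make_transcript(spec)
        reads, truth = simulate_footprints(t, a, spec)
        table = process_library(reads, t, a, dataset_id="d0")
        for region in (CDS_BODY, ISR_WINDOW):
            expected = truth.expected_counts[region]
            se = np.sqrt(expected)
            assert abs(table.counts[region] - expected) < 3 * se


class TestAccounting:
    def test_no_reads_lost_unexplained(self):
        """Region counts + unmapped + ambiguous + filtered = input reads."""
        for seed in range(5):
            spec = SyntheticSpec(seed=seed, n_reads=5000)
            t, a = make_transcript(spec)
            reads, _ = simulate_footprints(
                t, a, spec, mismatch_rate=0.05, adapter=ADAPTER, adapter_fraction=0.1
            )
            table = process_library(reads, t, a, dataset_id=f"d{seed}", adapter=ADAPTER)
            assert table.total_reads == len(reads)


class TestComparison:
    def _tables(self, isr_values, utr_values, scheme):
        tables = []
        for i, (isr_n, utr_n) in enumerate(zip(isr_values, utr_values)):
            labels = [ISR_WINDOW] * isr_n + [THREE_UTR_REST] * utr_n
            tables.append(compute_densities(labels, scheme, f"d{i}"))
        return tables

    def test_identical_vectors_give_t0_p1(self):
        t, a = make_transcript(SyntheticSpec(seed=6))
        scheme = build_region_scheme(t, a)
        # equal counts scaled so ISR and UTR densities coincide exactly
        iso = scheme.region_length(ISR_WINDOW)
        utr = scheme.region_length(THREE_UTR_REST)
        tables = self._tables([iso, 2 * iso, 3 * iso], [utr, 2 * utr, 3 * utr], scheme)
        result = compare_isr_vs_utr(tables)
        assert result.t_statistic == 0.0
        assert result.p_value == 1.0

    def test_single_dataset_rejected(self):
        t, a = make_transcript(SyntheticSpec(seed=6))
        scheme = build_region_scheme(t, a)
        with pytest.raises(ValueError):
            compare_isr_vs_utr(self._tables([10], [10], scheme))

    def test_strong_signal_detected(self):
        """15 libraries simulated with ISR mean 10x the background."""
        rng = np.random.default_rng(99)
        tables = []
        spec = SyntheticSpec(seed=0)
        t, a = make_transcript(spec)
        scheme = build_region_scheme(t, a)
        for i in range(15):
            isr_n = int(rng.poisson(500))
            utr_n = int(rng.poisson(50 * scheme.region_length(THREE_UTR_REST) / scheme.region_length(ISR_WINDOW)))
            tables.append(
                compute_densities(
                    [ISR_WINDOW] * isr_n + [THREE_UTR_REST] * utr_n, scheme, f"d{i}"
                )
            )
        result = compare_isr_vs_utr(tables)
        assert result.p_value < 0.01
        assert (result.isr_densities > result.utr_densities).all()
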