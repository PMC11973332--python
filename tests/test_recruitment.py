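import numpy as np
import pytest

import recruitplot as rp
from recruitplot.errors import DataError, InsufficientDepthError
from recruitplot.recruitment import summarize_ratios


@pytest.fixture
def cfg():
    return rp.FilterConfig(tie_seed=42)


def _meta_ref(*genomes):
    return rp.ReferenceDB([rp.Genome(gid, sp, sub, length=length)
                           for gid, sp, sub, length in genomes])


class TestHostRemoval:
    def test_high_identity_high_coverage_excluded(self, cfg, hit_factory):
        hit = hit_factory(query_id="r1", percent_identity=75.0,
                          alignment_length=160, query_length=200)  # qcov 80
        assert rp.remove_host_hits([hit], cfg) == {"r1"}

    def test_exactly_60_identity_kept(self, cfg, hit_factory):
        # removal requires strictly "higher than" 60
        hit = hit_factory(query_id="r1", percent_identity=60.0,
                          alignment_length=180, query_length=200)
        assert rp.remove_host_hits([hit], cfg) == set()

    def test_high_identity_low_coverage_kept(self, cfg, hit_factory):
        hit = hit_factory(query_id="r1", percent_identity=90.0,
                          alignment_length=100, query_length=200)  # qcov 50
        assert rp.remove_host_hits([hit], cfg) == set()

    def test_missing_query_length_errors(self, cfg, hit_factory):
        hit = hit_factory(query_length=None, percent_identity=90.0)
        with pytest.raises(DataError):
            rp.remove_host_hits([hit], cfg)

    def test_simulated_host_reads_removed_with_no_false_exclusions(self, cfg):
        # Community with a host decoy; align every read against the host
        # genome only and check truth labels.
        sim_cfg = rp.default_community(11, depth_bases=800_000, genome_length=20_000,
                                       with_host=True)
        ref, truth = rp.make_reference(sim_cfg)
        short_reads, _, truth = rp.fragment_and_read(ref, sim_cfg, truth)
        from recruitplot.simulate import host_reference

        host_ref = host_reference(truth)
        host_name = truth.host_genome.species
        hits = rp.toy_align(short_reads, host_ref, k=15, min_seed_hits=2, stride=4)
        excluded = rp.remove_host_hits(hits, cfg)
        host_ids = {r.id for r in short_reads
                    if truth.source_species(r.id) == host_name and len(r.sequence) >= 100}
        community_ids = {r.id for r in short_reads
                         if truth.source_species(r.id) != host_name}
        assert len(host_ids) > 50
        assert len(excluded & host_ids) >= 0.95 * len(host_ids)
        assert not excluded & community_ids  # zero false exclusions


class TestFilterHits:
    def test_short_thresholds_are_inclusive(self, cfg, hit_factory):
        hits = [
            hit_factory(query_id="a", percent_identity=59.9, alignment_length=100),
            hit_factory(query_id="b", percent_identity=60.0, alignment_length=49),
            hit_factory(query_id="c", percent_identity=60.0, alignment_length=50),
        ]
        kept = rp.filter_hits(hits, "short", cfg)
        assert [h.query_id for h in kept] == ["c"]

    def test_long_identity_boundary(self, cfg, hit_factory):
        low = hit_factory(query_id="a", percent_identity=69.9, query_length=5000)
        ok = hit_factory(query_id="b", percent_identity=70.0, query_length=5000)
        short_read = hit_factory(query_id="c", percent_identity=95.0, query_length=499,
                                 query_end=199)
        kept = rp.filter_hits([low, ok, short_read], "long", cfg)
        assert [h.query_id for h in kept] == ["b"]

    def test_empty_input(self, cfg):
        assert rp.filter_hits([], "short", cfg) == []

    def test_idempotent(self, cfg, hit_factory):
        rng = np.random.default_rng(0)
        hits = [
            hit_factory(query_id=f"r{i}", percent_identity=float(rng.uniform(40, 100)),
                        alignment_length=int(rng.integers(20, 200)))
            for i in range(100)
        ]
        once = rp.filter_hits(hits, "short", cfg)
        assert rp.filter_hits(once, "short", cfg) == once

    def test_unknown_platform(self, cfg, hit_factory):
        with pytest.raises(DataError):
            rp.filter_hits([hit_factory()], "nanopore", cfg)


class TestBestHit:
    def test_highest_bitscore_wins(self, cfg, hit_factory):
        hits = [
            hit_factory(query_id="q", subject_id="gA", bitscore=300.0),
            hit_factory(query_id="q", subject_id="gB", bitscore=250.0),
        ]
        (best,) = rp.select_best_hits(hits, cfg)
        assert best.subject_id == "gA"

    def test_single_hit_identity(self, cfg, hit_factory):
        hit = hit_factory(query_id="q")
        assert rp.select_best_hits([hit], cfg) == [hit]

    def test_two_way_ties_split_evenly(self, cfg, hit_factory):
        # 10,000 independent two-way ties: each side 5,000 +- 3*sqrt(2500).
        hits = []
        for i in range(10_000):
            hits.append(hit_factory(query_id=f"q{i}", subject_id="gA", bitscore=100.0))
            hits.append(hit_factory(query_id=f"q{i}", subject_id="gB", bitscore=100.0))
        best = rp.select_best_hits(hits, cfg)
        n_a = sum(1 for h in best if h.subject_id == "gA")
        assert abs(n_a - 5000) <= 3 * 50

    def test_deterministic_and_order_independent(self, cfg, hit_factory):
        hits = [
            hit_factory(query_id=f"q{i}", subject_id=s, bitscore=100.0)
            for i in range(50)
            for s in ("gA", "gB", "gC")
        ]
        first = rp.select_best_hits(hits, cfg)
        again = rp.select_best_hits(list(reversed(hits)), cfg)
        assert {h.query_id: h.subject_id for h in first} == \
               {h.query_id: h.subject_id for h in again}

    def test_changing_seed_touches_only_tied_queries(self, hit_factory):
        hits = [hit_factory(query_id="untied", subject_id="gA", bitscore=200.0),
                hit_factory(query_id="untied", subject_id="gB", bitscore=100.0)]
        for i in range(30):
            hits.append(hit_factory(query_id=f"t{i}", subject_id="gA", bitscore=100.0))
            hits.append(hit_factory(query_id=f"t{i}", subject_id="gB", bitscore=100.0))
        pick1 = {h.query_id: h.subject_id
                 for h in rp.select_best_hits(hits, rp.FilterConfig(tie_seed=1))}
        pick2 = {h.query_id: h.subject_id
                 for h in rp.select_best_hits(hits, rp.FilterConfig(tie_seed=2))}
        assert pick1["untied"] == pick2["untied"] == "gA"
        assert any(pick1[f"t{i}"] != pick2[f"t{i}"] for i in range(30))

    def test_matches_brute_force_on_random_tables(self, cfg, hit_factory):
        # Exhaustive per-read argmax oracle; exact agreement for non-tied reads.
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(1, 200))
            hits = [
                hit_factory(
                    query_id=f"q{int(rng.integers(0, 40))}",
                    subject_id=f"g{int(rng.integers(0, 5))}",
                    percent_identity=float(rng.uniform(40, 100)),
                    alignment_length=int(rng.integers(30, 200)),
                    bitscore=float(rng.integers(50, 120)),
                )
                for _ in range(n)
            ]
            kept = rp.filter_hits(hits, "short", cfg)
            best = {h.query_id: h for h in rp.select_best_hits(kept, cfg)}
            # brute force: enumerate all hits per read, apply thresholds, argmax
            oracle: dict[str, list] = {}
            for h in hits:
                if h.percent_identity >= 60.0 and h.alignment_length >= 50:
                    oracle.setdefault(h.query_id, []).append(h)
            assert set(best) == set(oracle)
            for qid, group in oracle.items():
                top = max(h.bitscore for h in group)
                tied = [h for h in group if h.bitscore == top]
                if len(tied) == 1:
                    assert best[qid] is tied[0]
                else:
                    assert best[qid] in tied


class TestProfiles:
    def test_midpoint_binning_and_counts(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        # midpoints 500, 600 (bin 1) and 49,600 (bin 50) on a 100 kb genome
        hits = [
            hit_factory(query_id="r1", subject_start=401, subject_end=599),
            hit_factory(query_id="r2", subject_start=501, subject_end=699),
            hit_factory(query_id="r3", subject_start=49_501, subject_end=49_699),
        ]
        prof = rp.build_profiles(hits, ref, cfg)["gA"]
        assert prof.read_count == 3
        assert prof.bin_coverage[0] == 2
        assert prof.bin_coverage[49] == 1
        assert prof.bin_coverage.sum() == prof.read_count

    def test_base_count_sums_query_lengths(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        hits = [
            hit_factory(query_id="r1", query_length=200, query_end=200),
            hit_factory(query_id="r2", query_length=300, query_end=300),
        ]
        prof = rp.build_profiles(hits, ref, cfg)["gA"]
        assert prof.base_count == 500

    def test_unknown_subject_dropped(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        hits = [hit_factory(query_id="r1"), hit_factory(query_id="r2", subject_id="mystery")]
        prof = rp.build_profiles(hits, ref, cfg)["gA"]
        assert prof.read_count == 1

    def test_uniform_recruitment_fills_bins(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        rng = np.random.default_rng(3)
        hits = []
        for i, start in enumerate(rng.integers(1, 99_800, 10_000)):
            hits.append(hit_factory(query_id=f"r{i}", subject_start=int(start),
                                    subject_end=int(start) + 199))
        prof = rp.build_profiles(hits, ref, cfg)["gA"]
        expect = 10_000 / cfg.spread_bins
        sigma = np.sqrt(10_000 * (1 / cfg.spread_bins) * (1 - 1 / cfg.spread_bins))
        assert np.all(np.abs(prof.bin_coverage - expect) <= 5 * sigma)


def _uniform_hits(factory, n, genome="gA", glen=100_000, seed=0, prefix="r"):
    rng = np.random.default_rng(seed)
    hits = []
    for i, start in enumerate(rng.integers(1, glen - 300, n)):
        hits.append(factory(query_id=f"{prefix}{i}", subject_id=genome,
                            subject_start=int(start), subject_end=int(start) + 199))
    return hits


class TestRetention:
    def test_exactly_300_reads_rejected(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        profiles = rp.build_profiles(_uniform_hits(hit_factory, 300), ref, cfg)
        verdict = rp.retain_species(profiles, cfg)["A"]
        assert not verdict.retained
        assert "300" in verdict.reason

    def test_301_reads_well_spread_retained(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        profiles = rp.build_profiles(_uniform_hits(hit_factory, 301), ref, cfg)
        verdict = rp.retain_species(profiles, cfg)["A"]
        assert verdict.retained

    def test_clustered_coverage_rejected_for_spread(self, cfg, hit_factory):
        # 5,000 reads confined to 3 of 100 bins: breadth 0.03 < 0.5
        ref = _meta_ref(("gA", "A", None, 100_000))
        rng = np.random.default_rng(4)
        hits = []
        for i, start in enumerate(rng.integers(1, 2800, 5000)):
            hits.append(hit_factory(query_id=f"r{i}", subject_start=int(start),
                                    subject_end=int(start) + 199))
        profiles = rp.build_profiles(hits, ref, cfg)
        verdict = rp.retain_species(profiles, cfg)["A"]
        assert not verdict.retained
        assert verdict.breadth <= 0.03
        assert "breadth" in verdict.reason

    def test_counts_pooled_across_subspecies_breadth_on_best(self, cfg, hit_factory):
        ref = _meta_ref(("gA1", "A", "subsp1", 100_000), ("gA2", "A", "subsp2", 100_000))
        hits = _uniform_hits(hit_factory, 200, genome="gA1", seed=1, prefix="p")
        hits += _uniform_hits(hit_factory, 200, genome="gA2", seed=2, prefix="q")
        profiles = rp.build_profiles(hits, ref, cfg)
        verdict = rp.retain_species(profiles, cfg)["A"]
        assert verdict.read_count == 400  # pooled over genomes
        assert verdict.retained


class TestGaps:
    def test_uniform_deep_coverage_has_no_gaps(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        profiles = rp.build_profiles(_uniform_hits(hit_factory, 10_000, seed=5), ref, cfg)
        gp = rp.detect_coverage_gaps(profiles["gA"], cfg)
        assert gp.gap_bins == set()

    def test_masked_region_reported_as_gap(self, cfg, hit_factory):
        # no reads generated in bins 40-45 of a 100-bin genome
        ref = _meta_ref(("gA", "A", None, 100_000))
        rng = np.random.default_rng(6)
        hits = []
        i = 0
        while i < 5000:
            start = int(rng.integers(1, 99_700))
            # bins 40-45 hold read midpoints from starts 38,902..44,901
            if 38_900 <= start <= 44_904:
                continue
            hits.append(hit_factory(query_id=f"r{i}", subject_start=start,
                                    subject_end=start + 199))
            i += 1
        gp = rp.detect_coverage_gaps(rp.build_profiles(hits, ref, cfg)["gA"], cfg)
        assert gp.gap_bins == {40, 41, 42, 43, 44, 45}

    def test_under_recruited_profile_errors(self, cfg, hit_factory):
        ref = _meta_ref(("gA", "A", None, 100_000))
        profiles = rp.build_profiles(_uniform_hits(hit_factory, 10), ref, cfg)
        with pytest.raises(InsufficientDepthError):
            rp.detect_coverage_gaps(profiles["gA"], cfg)


class TestGapConcordance:
    def test_identical_sets(self):
        a = rp.GapProfile("gA", set(range(40, 46)), 100)
        b = rp.GapProfile("gA", set(range(40, 46)), 100)
        assert rp.gap_concordance(a, b) == 1.0

    def test_partial_overlap(self):
        a = rp.GapProfile("gA", set(range(40, 46)), 100)
        b = rp.GapProfile("gA", set(range(44, 50)), 100)
        assert rp.gap_concordance(a, b) == pytest.approx(0.2)  # 2 shared / 10 union

    def test_both_empty_is_one(self):
        a = rp.GapProfile("gA", set(), 100)
        b = rp.GapProfile("gA", set(), 100)
        assert rp.gap_concordance(a, b) == 1.0

    def test_mismatched_genome_or_binning_errors(self):
        a = rp.GapProfile("gA", {1}, 100)
        with pytest.raises(DataError):
            rp.gap_concordance(a, rp.GapProfile("gB", {1}, 100))
        with pytest.raises(DataError):
            rp.gap_concordance(a, rp.GapProfile("gA", {1}, 50))


class TestSubspeciesRatios:
    def _profiles(self, cfg, factory, counts):
        ref = _meta_ref(*[(gid, "A", gid, 100_000) for gid in counts])
        hits = []
        for gid, n in counts.items():
            hits += _uniform_hits(factory, n, genome=gid, seed=sum(map(ord, gid)), prefix=gid)
        return rp.build_profiles(hits, ref, cfg), ref

    def test_five_fold_ratio(self, cfg, hit_factory):
        profiles, ref = self._profiles(cfg, hit_factory, {"g1": 500, "g2": 100})
        rep = rp.subspecies_ratios(profiles, ref)["A"]
        assert rep.ratios[("g1", "g2")] == pytest.approx(5.0)

    def test_near_unity_ratio(self, cfg, hit_factory):
        profiles, ref = self._profiles(cfg, hit_factory, {"g1": 91, "g2": 100})
        rep = rp.subspecies_ratios(profiles, ref)["A"]
        assert rep.ratios[("g1", "g2")] == pytest.approx(0.91)

    def test_zero_denominator_is_undefined(self, cfg, hit_factory):
        profiles, ref = self._profiles(cfg, hit_factory, {"g1": 100, "g2": 0})
        rep = rp.subspecies_ratios(profiles, ref)["A"]
        assert rep.ratios[("g1", "g2")] is None
        assert rep.ratios[("g2", "g1")] == 0.0

    def test_single_genome_species_skipped(self, cfg, hit_factory):
        ref = _meta_ref(("g1", "A", None, 100_000))
        profiles = rp.build_profiles(_uniform_hits(hit_factory, 50, genome="g1"), ref, cfg)
        assert rp.subspecies_ratios(profiles, ref) == {}

    def test_summary_across_samples(self, cfg, hit_factory):
        samples = []
        for counts in ({"g1": 500, "g2": 100}, {"g1": 480, "g2": 120}):
            profiles, ref = self._profiles(cfg, hit_factory, counts)
            samples.append(rp.subspecies_ratios(profiles, ref))
        rows = summarize_ratios(samples)
        row = next(r for r in rows if (r["genome_a"], r["genome_b"]) == ("g1", "g2"))
        assert row["n_samples"] == 2
        assert row["mean_ratio"] == pytest.approx((5.0 + 4.0) / 2)
        assert row["sd_ratio"] > 0


class TestGenusSelection:
    def test_strictly_above_cutoff(self):
        table = {"A": 0.5, "B": 0.001, "C": 0.0009}
        assert rp.select_reference_genera(table) == ["A"]

    def test_just_above_cutoff(self):
        assert rp.select_reference_genera({"A": 0.0011}) == ["A"]

    def test_empty_table(self):
        assert rp.select_reference_genera({}) == []

    def test_negative_fraction_errors(self):
        with pytest.raises(DataError):
            rp.select_reference_genera({"A": -0.1})
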