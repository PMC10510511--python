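import dataclasses
from collections import Counter

import numpy as np
import pandas as pd
import pytest

import deldrop as d
from deldrop.deconvolution import DecodeResult, _CycleDecoder
from conftest import run_two_dose_screen


def fake_sort(members):
    return d.SortResult(
        hits=pd.DataFrame(),
        hit_bead_member=np.asarray(members, dtype=int),
        thresholds=pd.DataFrame(),
        n_sigma=4.5,
        n_droplets=len(members),
        beads_screened=len(members),
    )


class TestReadsFromHits:
    def test_error_free_reads_equal_member_tags(self, small_catalog):
        members = [0, 5, 17, 95]
        reads = d.reads_from_hits(fake_sort(members), small_catalog, error_rate=0.0, seed=1)
        tags = small_catalog.tags.to_numpy()
        assert [r.sequence for r in reads] == [tags[m] for m in members]

    def test_same_seed_identical_reads(self, small_catalog):
        sort = fake_sort([3, 3, 40])
        a = d.reads_from_hits(sort, small_catalog, 0.05, seed=9)
        b = d.reads_from_hits(sort, small_catalog, 0.05, seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_mean_mismatch_count_matches_binomial(self, small_catalog):
        e = 0.05
        sort = fake_sort(np.zeros(2000, dtype=int))
        reads = d.reads_from_hits(sort, small_catalog, e, seed=2)
        tag = small_catalog.tags.iloc[0]
        mism = np.mean([sum(a != b for a, b in zip(r.sequence, tag)) for r in reads])
        expect = e * len(tag)
        assert mism == pytest.approx(expect, rel=0.15)

    def test_error_rate_validated(self, small_catalog):
        with pytest.raises(ValueError):
            d.reads_from_hits(fake_sort([0]), small_catalog, error_rate=0.5, seed=0)

    def test_fastq_roundtrip(self, small_catalog, tmp_path):
        reads = d.reads_from_hits(fake_sort([1, 2, 3]), small_catalog, 0.0, seed=0)
        d.write_fastq(reads, tmp_path / "r.fastq")
        back = d.read_fastq(tmp_path / "r.fastq")
        assert [r.sequence for r in back] == [r.sequence for r in reads]


class TestDecodeReads:
    def test_exact_match_counted_once(self, small_catalog):
        res = d.decode_reads([d.TagRead("r1", small_catalog.tags.iloc[42])], small_catalog)
        assert dict(res.counts) == {42: 1}
        assert res.n_decoded == 1 and not res.discards

    def test_single_substitution_recovered(self, small_catalog):
        """Tags have pairwise distance >= 3, so any 1-substitution read maps
        back to its true member; verified against a nearest-tag oracle."""
        tags = small_catalog.tags.to_numpy()
        aa_len = len(small_catalog.aa["tag"].iloc[0])
        rng = np.random.default_rng(0)
        for member in rng.integers(0, small_catalog.n_members, 20):
            tag = tags[member]
            pos = int(rng.integers(0, aa_len))  # corrupt the AA segment
            base = "ACGT"[("ACGT".index(tag[pos]) + 1) % 4]
            read = d.TagRead("r", tag[:pos] + base + tag[pos + 1 :])
            res = d.decode_reads([read], small_catalog)
            assert dict(res.counts) == {int(member): 1}
            # oracle: the claimed member is the unique nearest full tag
            dists = np.array([sum(a != b for a, b in zip(read.sequence, t)) for t in tags])
            assert dists.argmin() == member and (dists == dists.min()).sum() == 1

    def test_many_ns_discarded_as_ambiguous(self, small_catalog):
        tag = small_catalog.tags.iloc[0]
        smeared = "N" * 5 + tag[5:]
        res = d.decode_reads([d.TagRead("r", smeared)], small_catalog)
        assert res.n_decoded == 0
        assert res.discards["ambiguous"] == 1

    def test_single_n_treated_as_mismatch(self, small_catalog):
        tag = small_catalog.tags.iloc[10]
        res = d.decode_reads([d.TagRead("r", "N" + tag[1:])], small_catalog)
        assert dict(res.counts) == {10: 1}

    def test_wrong_length_discarded(self, small_catalog):
        res = d.decode_reads([d.TagRead("r", "ACGT")], small_catalog)
        assert res.discards["bad_length"] == 1

    def test_garbage_segment_discarded_with_reason(self, small_catalog):
        tag = small_catalog.tags.iloc[0]
        aa_len = len(small_catalog.aa["tag"].iloc[0])
        garbled = "ACGTACGTACGT"[:aa_len]
        while garbled in set(small_catalog.aa["tag"]):
            garbled = garbled[:-1] + "A"
        res = d.decode_reads([d.TagRead("r", garbled + tag[aa_len:])], small_catalog)
        assert res.n_decoded + sum(res.discards.values()) == 1

    def test_ambiguous_catalog_rejected_at_load(self, small_catalog):
        tags = small_catalog.aa["tag"].copy()
        tags.iloc[1] = tags.iloc[0]
        with pytest.raises(ValueError, match="ambiguous"):
            _CycleDecoder(tags, cycle=1)

    def test_roundtrip_identity_on_simulator_reads(self, small_catalog):
        """decode(reads(hits, error_rate=0)) recovers the hit list exactly."""
        members = np.array([4, 4, 9, 63, 63, 63])
        reads = d.reads_from_hits(fake_sort(members), small_catalog, 0.0, seed=5)
        res = d.decode_reads(reads, small_catalog)
        assert res.n_decoded == len(members)
        assert dict(res.counts) == dict(Counter(members.tolist()))


class TestKClass:
    def _decoded(self, counts):
        return DecodeResult(
            counts=pd.Series(counts, dtype=int).sort_index(),
            n_reads=sum(counts.values()),
            discards=Counter(),
        )

    def test_single_member_propagates_to_both_blocks(self, small_catalog):
        pos = small_catalog.member_position(np.array([0]), np.array([0]))[0]
        kt = d.k_class_table(self._decoded({pos: 5}), small_catalog, "uv1")
        aa_id = small_catalog.aa["bb_id"].iloc[0]
        ca_id = small_catalog.ca["bb_id"].iloc[0]
        assert kt.members["k"].iloc[0] == 5
        assert kt.cumulative_k(aa_id) == 5 and kt.cumulative_k(ca_id) == 5

    def test_shared_block_sums(self, small_catalog):
        p1 = small_catalog.member_position(np.array([1]), np.array([0]))[0]
        p2 = small_catalog.member_position(np.array([1]), np.array([2]))[0]
        kt = d.k_class_table(self._decoded({p1: 3, p2: 4}), small_catalog, "uv1")
        assert kt.cumulative_k(small_catalog.aa["bb_id"].iloc[1]) == 7

    def test_cumulative_matches_brute_force_double_loop(self, small_catalog, rng):
        pos = rng.choice(small_catalog.n_members, 30, replace=False)
        counts = {int(p): int(k) for p, k in zip(pos, rng.integers(1, 9, 30))}
        kt = d.k_class_table(self._decoded(counts), small_catalog, "uv1")
        members = small_catalog.members
        for _, row in kt.bb.iterrows():
            col = "aa_id" if row["cycle"] == 1 else "ca_id"
            brute = sum(
                k for p, k in counts.items() if members[col].iloc[p] == row["bb_id"]
            )
            assert row["cumulative_k"] == brute

    def test_total_k_conserves_decoded_reads(self, small_catalog, rng):
        members = rng.integers(0, small_catalog.n_members, 200)
        reads = d.reads_from_hits(fake_sort(members), small_catalog, 0.01, seed=3)
        decoded = d.decode_reads(reads, small_catalog)
        kt = d.k_class_table(decoded, small_catalog, "uv1")
        assert kt.total_k == decoded.n_decoded == decoded.n_reads - sum(decoded.discards.values())


class TestDoseCompare:
    def _ktab(self, catalog, bb_counts, label):
        """Build a k-class table whose AA cumulative k values match bb_counts."""
        counts = {}
        for aa_idx, (k_total, spread) in bb_counts.items():
            for j in range(spread):
                pos = catalog.member_position(np.array([aa_idx]), np.array([j]))[0]
                counts[int(pos)] = k_total // spread
        dec = DecodeResult(
            counts=pd.Series(counts, dtype=int).sort_index(),
            n_reads=sum(counts.values()),
            discards=Counter(),
        )
        return d.k_class_table(dec, catalog, label)

    def test_tier_rules(self, small_catalog):
        hi = self._ktab(small_catalog, {0: (20, 4), 1: (30, 3), 2: (3, 3)}, "uv1")
        lo = self._ktab(small_catalog, {0: (15, 3), 2: (2, 2)}, "uv0.3")
        rep = d.dose_compare(hi, lo, min_k=4, noise_k=3)
        aa = small_catalog.aa["bb_id"]
        assert rep.tier_of(aa.iloc[0]) == "high_priority"  # enriched at both doses
        assert rep.tier_of(aa.iloc[1]) == "dose_limited"  # high dose only
        assert rep.tier_of(aa.iloc[2]) == "noise"  # k = 3/2, bordering on noise
        assert rep.tier_of(aa.iloc[5]) == "unobserved"

    def test_report_sorted_by_combined_k(self, small_catalog):
        hi = self._ktab(small_catalog, {0: (10, 2), 1: (40, 4)}, "uv1")
        lo = self._ktab(small_catalog, {0: (8, 2), 1: (20, 4)}, "uv0.3")
        rep = d.dose_compare(hi, lo)
        assert rep.bb["combined_k"].is_monotonic_decreasing

    def test_each_observed_bb_once(self, small_catalog):
        hi = self._ktab(small_catalog, {0: (6, 2), 3: (4, 2)}, "uv1")
        lo = self._ktab(small_catalog, {0: (6, 2)}, "uv0.3")
        rep = d.dose_compare(hi, lo)
        assert rep.bb["bb_id"].is_unique

    def test_disynthons_require_k_of_two(self, small_catalog):
        hi = self._ktab(small_catalog, {0: (8, 2), 1: (3, 3)}, "uv1")  # members k=4 and k=1
        lo = self._ktab(small_catalog, {}, "uv0.3")
        rep = d.dose_compare(hi, lo)
        assert (rep.disynthons[["k_high", "k_low"]].max(axis=1) >= 2).all()

    def test_mismatched_catalogs_error(self, small_catalog, rng):
        other = d.enumerate_library(
            d.make_building_blocks(4, 1, rng), d.make_building_blocks(4, 2, rng)
        )
        hi = self._ktab(small_catalog, {0: (6, 2)}, "uv1")
        lo = self._ktab(other, {0: (6, 2)}, "uv0.3")
        with pytest.raises(ValueError, match="catalog"):
            d.dose_compare(hi, lo)


class TestEndToEndRecovery:
    def test_strong_series_tops_cumulative_k(self, full_catalog, calibration):
        """A potent planted AA series (IC50 << released dose) attains the top
        cumulative k and the high-priority tier, across seeds."""
        spec = d.SeriesSpec(
            n_aa_series=1, n_ca_series=0, potency_range=(2.0, 2.0), jitter_sd=0.1,
            background_rate=5e-4,
        )
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            amap = d.plant_actives(full_catalog, spec, seed=400 + s)
            screens = run_two_dose_screen(
                full_catalog, amap, calibration, epsilon=3.0, seed=500 + s
            )
            rep = d.dose_compare(screens[1.0]["ktab"], screens[0.3]["ktab"])
            warm = amap.series["bb_id"].iloc[0]
            aa_rows = rep.bb[rep.bb["cycle"] == 1]
            if len(aa_rows) and aa_rows.iloc[0]["bb_id"] == warm and rep.tier_of(warm) == "high_priority":
                wins += 1
        assert wins / n_seeds >= 0.95

    def test_weak_series_is_dose_limited(self, full_catalog, calibration):
        """A series planted in the potency window detectable only at the high
        dose is tiered dose_limited in the majority of seeds."""
        spec = d.SeriesSpec(
            n_aa_series=1, n_ca_series=0, potency_range=(500.0, 500.0), jitter_sd=0.05,
            background_rate=0.0, truncate_rate=0.0,
        )
        tiers = []
        for s in range(11):
            amap = d.plant_actives(full_catalog, spec, seed=700 + s)
            screens = run_two_dose_screen(
                full_catalog, amap, calibration, epsilon=3.0, seed=800 + s
            )
            rep = d.dose_compare(screens[1.0]["ktab"], screens[0.3]["ktab"])
            tiers.append(rep.tier_of(amap.series["bb_id"].iloc[0]))
        assert sum(t == "dose_limited" for t in tiers) > len(tiers) / 2
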