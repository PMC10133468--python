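"""Frequency allocation tables: construction, rule set, mismatch."""

import numpy as np
import pytest

from cifit.fat import (
    GLOBAL_MAX_HZ,
    GLOBAL_MIN_HZ,
    RuleSet,
    build_tonotopic_fat,
    cohort_mismatch_summary,
    mismatch_profile,
    standard_fat,
    validate_fat,
)
from cifit.tonotopy import place_frequencies


def _random_place_freqs(rng, n=16):
    """Strictly increasing place frequencies from a random plausible geometry."""
    cdl = np.clip(rng.normal(35, 2), 28, 42)
    apical = np.clip(rng.normal(22, 2), 16, min(cdl - 1, 26))
    depths = apical - 0.95 * np.arange(n)
    x = (cdl - depths) / cdl  # may exceed 1 for basal contacts: out of range
    return 165.4 * (10 ** (2.1 * x) - 0.88)


class TestStandardFat:
    def test_default_spans_processor_range(self):
        fat = standard_fat()
        enabled = fat.enabled_channels
        assert len(enabled) == 16
        assert not fat.has_virtual_channel
        assert enabled[0].lower_bound == pytest.approx(GLOBAL_MIN_HZ)
        assert enabled[-1].upper_bound == pytest.approx(GLOBAL_MAX_HZ)

    def test_log_spaced_lower_bounds(self):
        fat = standard_fat()
        for k, c in enumerate(fat.enabled_channels, start=1):
            expected = 238.0 * (8598.0 / 238.0) ** ((k - 1) / 16)
            assert c.lower_bound == pytest.approx(expected, rel=1e-12)
        assert fat.channel(9).lower_bound == pytest.approx(1430.5, rel=1e-4)

    def test_default_satisfies_rule_set(self):
        assert validate_fat(standard_fat(), RuleSet()) == []

    def test_custom_table_round_bounds(self):
        lows = [250.0 * 1.25**k for k in range(16)]
        fat = standard_fat(lower_bounds=lows, global_min=250.0)
        assert [c.lower_bound for c in fat.enabled_channels] == pytest.approx(lows)

    def test_invalid_custom_table_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            standard_fat(lower_bounds=[238.0] * 2 + [5000.0] * 14)


class TestBuildTonotopicFat:
    def test_rule_satisfying_places_kept_exactly(self):
        place = np.geomspace(700, 8000, 16)  # 2 below 1k, 5 below 2k, 9 below 4k
        place = np.concatenate([[500, 600], np.geomspace(700, 8000, 14)])
        fat = build_tonotopic_fat(place)
        phys = [c for c in fat.enabled_channels if c.channel_index > 0]
        assert [c.lower_bound for c in phys] == pytest.approx(list(place))
        v = fat.channel(0)
        assert (v.lower_bound, v.upper_bound) == (GLOBAL_MIN_HZ, 500.0)

    def test_out_of_range_basal_contact_disabled(self):
        place = np.concatenate([np.geomspace(500, 7000, 15), [12000.0]])
        fat = build_tonotopic_fat(place)
        assert not fat.channel(16).enabled
        assert fat.channel(15).enabled
        assert fat.channel(15).upper_bound == pytest.approx(GLOBAL_MAX_HZ)

    def test_shallow_insertion_virtual_channel_counts_toward_rules(self):
        # apical place 957 Hz: the virtual channel 238-957 Hz is the only
        # channel below 1,000 Hz besides channel 1 -> rule "2 below 1 kHz" met
        place = np.geomspace(957, 9500, 16)
        fat = build_tonotopic_fat(place)
        v = fat.channel(0)
        assert v.enabled
        assert (v.lower_bound, v.upper_bound) == pytest.approx((238.0, 957.0))
        lows = fat.lower_bounds()
        assert np.sum(lows < 1000) >= 2
        assert validate_fat(fat) == []

    def test_repair_moves_only_offending_channels(self):
        # all 16 contacts basal of 2 kHz: rules at 1 and 2 kHz must repair
        place = np.geomspace(2500, 8000, 16)
        fat = build_tonotopic_fat(place)
        assert validate_fat(fat) == []
        lows = fat.lower_bounds()
        # channels beyond the largest repaired rank keep tonotopic bounds
        assert lows[4:] == pytest.approx(place[3:])

    def test_non_monotone_places_rejected(self):
        with pytest.raises(ValueError, match="strictly increase"):
            build_tonotopic_fat([500.0, 400.0, 600.0])

    def test_unsatisfiable_when_too_few_usable_channels(self):
        with pytest.raises(ValueError, match="usable channels"):
            build_tonotopic_fat(np.geomspace(8600, 20000, 16))

    def test_fuzzed_fats_always_validate(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            fat = build_tonotopic_fat(_random_place_freqs(rng))
            assert validate_fat(fat) == []

    def test_contiguity_tiles_range_without_gaps(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            fat = build_tonotopic_fat(_random_place_freqs(rng))
            enabled = fat.enabled_channels
            for a, b in zip(enabled, enabled[1:]):
                assert a.upper_bound == pytest.approx(b.lower_bound, rel=1e-12)
            assert enabled[0].lower_bound == GLOBAL_MIN_HZ
            assert enabled[-1].upper_bound <= GLOBAL_MAX_HZ * (1 + 1e-12)

    def test_raising_basal_place_never_reenables(self):
        base = _random_place_freqs(np.random.default_rng(3))
        fat0 = build_tonotopic_fat(base)
        enabled0 = {c.channel_index for c in fat0.enabled_channels}
        bumped = base.copy()
        bumped[-1] = max(bumped[-1] * 1.5, 9000.0)  # push last contact out of range
        fat1 = build_tonotopic_fat(bumped)
        enabled1 = {c.channel_index for c in fat1.enabled_channels}
        assert enabled1 <= enabled0


class TestValidateFat:
    def test_reports_count_shortfall(self):
        # built directly: only one enabled channel below 1 kHz
        lows = np.concatenate([[900.0], np.geomspace(1100, 8000, 15)])
        from cifit.fat import Channel, FrequencyAllocationTable

        chans = [
            Channel(i + 1, lo, hi)
            for i, (lo, hi) in enumerate(zip(lows, list(lows[1:]) + [8598.0]))
        ]
        fat = FrequencyAllocationTable(chans, global_min=900.0)
        v = [x for x in validate_fat(fat) if x.rule == "min_channels_below"]
        assert (v[0].threshold, v[0].required, v[0].observed) == (1000.0, 2, 1)

    def test_reports_basal_ceiling_violation(self):
        from cifit.fat import Channel, FrequencyAllocationTable

        lows = np.geomspace(238, 9000, 16)
        chans = [
            Channel(i + 1, lo, hi)
            for i, (lo, hi) in enumerate(zip(lows, list(lows[1:]) + [9500.0]))
        ]
        fat = FrequencyAllocationTable(chans, global_max=9500.0)
        rules = [x.rule for x in validate_fat(fat)]
        assert "basal_max" in rules


class TestMismatch:
    def test_zero_when_assigned_equals_place(self):
        place = np.geomspace(500, 8000, 16)
        fat = build_tonotopic_fat(place)
        prof = mismatch_profile(fat, place, representative="lower_bound")
        enabled_phys = [c.channel_index for c in fat.enabled_channels if c.channel_index]
        exact = [
            i for i in enabled_phys
            if fat.channel(i).lower_bound == pytest.approx(place[i - 1])
        ]
        assert exact  # construction keeps most bounds tonotopic
        got = dict(zip(prof.contact_indices, prof.per_contact_octaves))
        for i in exact:
            assert got[i] == pytest.approx(0.0, abs=1e-12)

    def test_octave_arithmetic(self):
        from cifit.fat import Channel, FrequencyAllocationTable

        fat = FrequencyAllocationTable(
            [Channel(1, 238.0, 8598.0)], global_min=238.0
        )
        prof = mismatch_profile(fat, [1710.3], representative="lower_bound")
        assert prof.per_contact_octaves[0] == pytest.approx(2.845, abs=1e-3)
        assert prof.median == pytest.approx(2.845, abs=1e-3)

    def test_imaging_mismatch_below_standard_on_random_subjects(self):
        rng = np.random.default_rng(19)
        std = standard_fat()
        for _ in range(50):
            place = _random_place_freqs(rng)
            tono = build_tonotopic_fat(place)
            m_t = mismatch_profile(tono, place).median_absolute
            m_s = mismatch_profile(std, place).median_absolute
            assert m_t <= m_s

    def test_contact_count_mismatch_raises(self):
        fat = standard_fat()
        with pytest.raises(ValueError, match="place frequencies"):
            mismatch_profile(fat, np.geomspace(500, 8000, 12))

    def test_cohort_summary_pools_enabled_contacts(self, small_cohort):
        profs = [
            mismatch_profile(small_cohort["tonotopic_fats"][sid], place)
            for sid, place in small_cohort["place_frequencies"].items()
        ]
        per_contact, pooled = cohort_mismatch_summary(profs)
        assert pooled[2] == sum(n for _, _, n in per_contact.values())
        assert set(per_contact) <= set(range(1, 17))
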