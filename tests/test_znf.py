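"""Finger-to-triplet mapping, chimera/truncation design, binding classes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from znfbind.synthetic import make_target_site
from znfbind.znf import (
    DEFAULT_CHIMERA_INTERVALS,
    BindingClass,
    TargetSite,
    ZnFArray,
    binding_score,
    classify_binding,
    contacted_fingers,
    finger_triplet_map,
    generate_chimeras,
    generate_truncations,
)

# the chimera panel: retained interval -> (full fingers, partial fingers,
# expected class), transcribed from the observed panel annotations
PANEL = {
    (1, 31): (set(range(2, 12)), set(), BindingClass.COMPARABLE),
    (6, 31): (set(range(4, 12)), {3}, BindingClass.COMPARABLE),
    (1, 26): (set(range(2, 10)), {10}, BindingClass.COMPARABLE),
    (11, 31): (set(range(5, 12)), set(), BindingClass.REDUCED),
    (16, 31): ({7, 8, 9, 10, 11}, {6}, BindingClass.REDUCED),
    (1, 21): ({2, 3, 4, 5, 6, 7}, {8}, BindingClass.REDUCED),
    (1, 16): ({2, 3, 4, 5, 6}, set(), BindingClass.REDUCED),
    (21, 31): ({9, 10, 11}, {8}, BindingClass.STRONGLY_REDUCED),
    (1, 11): ({2, 3, 4}, {5}, BindingClass.STRONGLY_REDUCED),
    (6, 15): ({4, 5}, {3, 6}, BindingClass.STRONGLY_REDUCED),
    (6, 20): ({4, 5, 6, 7}, {3, 8}, BindingClass.REDUCED),
    (6, 10): ({4}, {3}, BindingClass.STRONGLY_REDUCED),
}


class TestTripletMap:
    def test_closed_form(self):
        m = finger_triplet_map()
        assert m[2] == (2, 4)
        assert m[7] == (17, 19)
        assert m[11] == (29, 31)
        assert m[0] is None
        assert m[1] == (-1, 1)  # degenerate finger straddles the site start

    def test_specific_fingers_tile_positions_2_to_31(self):
        m = finger_triplet_map()
        covered = set()
        for k in range(2, 12):
            a, b = m[k]
            assert b - a == 2
            covered |= set(range(a, b + 1))
        assert covered == set(range(2, 32))  # 30 of the 31 site positions

    def test_array_invariants(self):
        arr = ZnFArray.default()
        assert len(arr.fingers) == 12
        assert len(arr.specific_fingers) == 10
        with pytest.raises(ValueError):
            ZnFArray(fingers=(arr.fingers[1], arr.fingers[0]))


class TestContactedFingers:
    @pytest.mark.parametrize("retained", sorted(PANEL))
    def test_panel_annotations(self, retained):
        """Exhaustive check of all 12 chimera finger annotations."""
        full, partial = contacted_fingers(retained)
        exp_full, exp_partial, _ = PANEL[retained]
        assert set(full) == exp_full
        assert set(partial) == exp_partial

    def test_half_sites_each_contact_five_full_fingers(self):
        for retained in ((1, 16), (16, 31)):
            full, _ = contacted_fingers(retained)
            assert len(full) == 5

    def test_empty_interval_gives_empty_sets(self):
        full, partial = contacted_fingers(None)
        assert full == frozenset() and partial == frozenset()

    def test_out_of_site_interval_rejected(self):
        with pytest.raises(ValueError):
            contacted_fingers((0, 10))
        with pytest.raises(ValueError):
            contacted_fingers((1, 32))

    def test_degenerate_finger_reported_only_on_request(self):
        full, partial = contacted_fingers((1, 31), include_nonspecific=True)
        assert 1 in partial  # only position 1 of its triplet is in the site
        full2, partial2 = contacted_fingers((1, 31))
        assert 1 not in partial2

    @given(
        a=st.integers(min_value=1, max_value=31),
        b=st.integers(min_value=1, max_value=31),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_membership_count(self, a, b):
        """Interval intersection equals per-position membership counting."""
        if b < a:
            a, b = b, a
        retained_positions = set(range(a, b + 1))
        full, partial = contacted_fingers((a, b))
        m = finger_triplet_map()
        for k in range(2, 12):
            triplet = set(range(m[k][0], m[k][1] + 1))
            n = len(triplet & retained_positions)
            if n == 3:
                assert k in full and k not in partial
            elif n > 0:
                assert k in partial and k not in full
            else:
                assert k not in full and k not in partial


class TestClassification:
    @pytest.mark.parametrize("retained", sorted(PANEL))
    def test_three_way_classes_reproduced(self, retained):
        full, partial = contacted_fingers(retained)
        assert classify_binding(full, partial) == PANEL[retained][2]

    @pytest.mark.parametrize(
        "retained, score",
        [((1, 31), 10.0), ((16, 31), 5.5), ((6, 10), 1.5)],
    )
    def test_scores(self, retained, score):
        full, partial = contacted_fingers(retained)
        assert binding_score(full, partial) == score


@pytest.fixture(scope="module")
def site_and_donor():
    return make_target_site(seed=11)


class TestChimeras:
    def test_default_panel_geometry(self, site_and_donor):
        site, donor = site_and_donor
        designs = generate_chimeras(site, donor)
        assert len(designs) == 12
        assert len({d.sequence for d in designs}) == 12
        for d in designs:
            assert len(d.sequence) == len(site.full_sequence)

    def test_donor_outside_retained_interval(self, site_and_donor):
        """Chimera equals the donor everywhere except the retained site
        positions, which carry the site's bases."""
        site, donor = site_and_donor
        off = site.site_offset
        for d in generate_chimeras(site, donor):
            a, b = d.retained
            for i, base in enumerate(d.sequence):
                pos = i - off + 1  # 1-based site coordinate
                if a <= pos <= b:
                    assert base == site.sequence[pos - 1]
                else:
                    assert base == donor[i]

    def test_pairwise_differences_follow_interval_set_arithmetic(self, site_and_donor):
        site, donor = site_and_donor
        designs = {d.retained: d for d in generate_chimeras(site, donor)}
        off = site.site_offset

        def diff_positions(s1, s2):
            return {
                i - off + 1 for i, (x, y) in enumerate(zip(s1, s2)) if x != y
            }

        d1, d2 = designs[(1, 16)], designs[(16, 31)]
        sym = set(range(1, 16)) ^ set(range(16, 32))
        observed = diff_positions(d1.sequence, d2.sequence)
        # differences occur exactly where site and donor disagree within the
        # symmetric difference of the retained intervals
        assert observed <= sym
        expected = {
            p for p in sym if site.sequence[p - 1] != donor[off + p - 1]
        }
        assert observed == expected

    def test_full_site_chimera_on_identical_donor_is_identity(self):
        site = TargetSite("A" * 31, flank5="C" * 5, flank3="C" * 5)
        donor = site.full_sequence
        d = generate_chimeras(site, donor, intervals=[(1, 31)])[0]
        assert d.sequence == donor

    def test_invalid_interval_rejected(self, site_and_donor):
        site, donor = site_and_donor
        with pytest.raises(ValueError):
            generate_chimeras(site, donor, intervals=[(0, 31)])


class TestTruncations:
    def test_lengths_and_finger_sets(self, site_and_donor):
        site, _ = site_and_donor
        panel = {t.name: t for t in generate_truncations(site)}
        assert {t.length for t in panel.values()} == {75, 39, 34, 31, 28}
        assert panel["28 bp-u"].contacted_full == frozenset(range(3, 12))
        assert panel["28 bp-d"].contacted_full == frozenset(range(2, 11))
        # 31 and 34 bp keep the identical specific finger set: the
        # degenerate first finger adds nothing
        assert panel["31 bp"].contacted_full == panel["34 bp"].contacted_full
        assert panel["31 bp"].contacted_full == frozenset(range(2, 12))

    def test_sequences_are_substrings_of_context(self, site_and_donor):
        site, _ = site_and_donor
        for t in generate_truncations(site):
            assert t.sequence in site.full_sequence

    def test_insufficient_context_rejected(self):
        site = TargetSite("A" * 31)  # no flanks
        with pytest.raises(ValueError):
            generate_truncations(site, names=["75 bp"])
        with pytest.raises(ValueError):
            generate_truncations(site, names=["39 bp"])
        ok = generate_truncations(site, names=["31 bp", "28 bp-u", "28 bp-d"])
        assert len(ok) == 3
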