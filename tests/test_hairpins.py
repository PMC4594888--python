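"""Cut-site bookkeeping and processing-mode classification."""

from __future__ import annotations

import numpy as np
import pytest

from degradome_kit.hairpins import (
    arm_simultaneity,
    classify_mode,
    detect_mid_duplex,
    locate_cut_sites,
    process_hairpins,
    profile_hairpin,
)
from degradome_kit.models import Hairpin, SignalProfile
from degradome_kit.simulate import (
    SimConfig,
    gen_hairpin_tags,
    gen_mirna_set,
    simulate_dataset,
)


def _hairpin(n=140, a=(39, 59), b=(80, 100), arm="three_prime"):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), n))
    mir_iv, star_iv = (b, a) if arm == "three_prime" else (a, b)
    return Hairpin("hp", seq, mir_interval=mir_iv, star_interval=star_iv,
                   mir_arm=arm)


def _profile(h, spec):
    arr = np.zeros(len(h.sequence))
    for pos, mass in spec.items():
        arr[pos - 1] = mass
    return SignalProfile(h.hairpin_id, arr)


class TestCutSites:
    def test_three_prime_arm_sites(self):
        sites = locate_cut_sites(_hairpin(b=(80, 100)))
        assert sites.proximal_pos == 80
        assert sites.distal_pos == 101

    def test_sites_defined_by_duplex_not_mature_strand(self):
        s3 = locate_cut_sites(_hairpin(arm="three_prime"))
        s5 = locate_cut_sites(_hairpin(arm="five_prime"))
        assert (s3.proximal_pos, s3.distal_pos) == (s5.proximal_pos,
                                                    s5.distal_pos)

    def test_all_sites_in_bounds(self):
        h = _hairpin(n=140, a=(39, 59), b=(80, 100))
        sites = locate_cut_sites(h)
        for p in (sites.proximal_pos, sites.distal_pos,
                  sites.arm5_distal_pos, sites.arm5_proximal_pos):
            assert 1 <= p <= len(h.sequence)

    def test_inconsistent_interval_rejected(self):
        h = _hairpin(n=101, b=(80, 101))  # distal cut would fall outside
        with pytest.raises(ValueError, match="cut site"):
            locate_cut_sites(h)


class TestClassifyMode:
    def test_distal_dominance_is_loop_last(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        call = classify_mode(
            _profile(h, {sites.distal_pos: 20, sites.proximal_pos: 1,
                         10: 1}), sites)
        assert call.mode == "loop_last"
        assert call.distal_mass == 20 and call.proximal_mass == 1

    def test_proximal_dominance_is_loop_first(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        call = classify_mode(
            _profile(h, {sites.proximal_pos: 20, sites.distal_pos: 1,
                         10: 1}), sites)
        assert call.mode == "loop_first"

    def test_tie_is_ambiguous(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        call = classify_mode(
            _profile(h, {sites.distal_pos: 10, sites.proximal_pos: 10}), sites)
        assert call.mode == "ambiguous"

    def test_low_total_is_no_signal(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        call = classify_mode(_profile(h, {sites.distal_pos: 3}), sites,
                             min_total=5)
        assert call.mode == "no_signal"

    def test_spread_signal_is_dispersed(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        spec = {p: 1.0 for p in range(5, 75)}
        call = classify_mode(_profile(h, spec), sites)
        assert call.mode == "dispersed"

    def test_window_aggregates_neighbouring_mass(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        call = classify_mode(
            _profile(h, {sites.distal_pos - 1: 10, sites.distal_pos: 10,
                         sites.proximal_pos: 2}),
            sites, window=1)
        assert call.distal_mass == 20

    def test_dominance_monotonicity(self):
        """Raising the dominance threshold never turns ambiguous into a
        directional call."""
        h = _hairpin()
        sites = locate_cut_sites(h)
        prof = _profile(h, {sites.distal_pos: 15, sites.proximal_pos: 10})
        modes = [classify_mode(prof, sites, dominance=d).mode
                 for d in (1.2, 1.5, 2.0, 3.0, 5.0)]
        seen_ambiguous = False
        for m in modes:
            if m == "ambiguous":
                seen_ambiguous = True
            if seen_ambiguous:
                assert m == "ambiguous"

    def test_mass_bookkeeping(self):
        h = _hairpin()
        sites = locate_cut_sites(h)
        spec = {sites.distal_pos: 12, sites.proximal_pos: 3, 10: 4, 70: 6}
        call = classify_mode(_profile(h, spec), sites, window=0)
        other = sum(spec.values()) - call.distal_mass - call.proximal_mass
        assert call.distal_mass + call.proximal_mass + other == pytest.approx(
            call.total_mass
        )


class TestArmAndMidDuplex:
    def test_all_mass_on_three_prime_arm(self):
        h = _hairpin()
        frac, verdict = arm_simultaneity(_profile(h, {90: 10, 101: 20}), h)
        assert frac == 0.0 and verdict == "simultaneous-compatible"

    def test_half_mass_on_five_prime_arm(self):
        h = _hairpin()
        frac, verdict = arm_simultaneity(_profile(h, {45: 10, 90: 10}), h)
        assert frac == pytest.approx(0.5)
        assert verdict == "non-simultaneous signal"

    def test_empty_profile_no_signal(self):
        h = _hairpin()
        frac, verdict = arm_simultaneity(_profile(h, {}), h)
        assert np.isnan(frac) and verdict == "no_signal"

    def test_mid_duplex_center_flagged(self):
        h = _hairpin()  # mir interval (80, 100)
        flagged, pos = detect_mid_duplex(_profile(h, {90: 10}), h)
        assert flagged and pos == [90]

    def test_boundary_positions_not_flagged(self):
        h = _hairpin()
        flagged, pos = detect_mid_duplex(
            _profile(h, {80: 10, 100: 10, 81: 5}), h, margin=2
        )
        assert not flagged

    def test_empty_profile_not_flagged(self):
        h = _hairpin()
        assert detect_mid_duplex(_profile(h, {}), h) == (False, [])


class TestProfileHairpin:
    def test_exact_match_position(self):
        h = _hairpin()
        tag = h.sequence[100:120]
        profs = profile_hairpin({tag: 4}, [h], max_mismatch=0)
        assert profs["hp"].counts[100] == pytest.approx(4.0)

    def test_split_with_mrna_locus(self):
        from degradome_kit.models import TranscriptModel

        h = _hairpin()
        tag = h.sequence[50:70]
        tr = TranscriptModel("t.1", "t", "ACGT" * 30 + tag + "ACGT" * 30,
                             None, (1, 120), None)
        profs = profile_hairpin({tag: 10}, [h], max_mismatch=0,
                                transcripts=[tr])
        assert profs["hp"].counts[50] == pytest.approx(5.0)

    def test_no_tags_no_signal_mode(self):
        h = _hairpin()
        profs = profile_hairpin({}, [h])
        calls = process_hairpins(profs, [h])
        assert calls[0].mode == "no_signal"


class TestPlantedModeRecovery:
    def test_generator_modes_fully_recovered(self):
        cfg = SimConfig(n_hairpins=30, hairpin_purity=0.8,
                        hairpin_tags_per_hairpin=25, seed=14)
        _, hairpins, truth = gen_mirna_set(cfg)
        from degradome_kit.simulate import TruthTable
        import pandas as pd

        tt = TruthTable(
            pd.DataFrame(columns=["gene_id", "decay_type", "direction"]),
            pd.DataFrame(columns=["mirna_id", "transcript_id", "site_start",
                                  "slice_pos"]),
            truth,
        )
        tags = gen_hairpin_tags(hairpins, tt, cfg)
        profs = profile_hairpin(tags, hairpins, max_mismatch=0)
        calls = process_hairpins(profs, hairpins)
        called = {c.hairpin_id: c for c in calls}
        for hid, row in truth.iterrows():
            assert called[hid].mode == row["mode"], hid

    def test_arm_leakage_verdicts(self, small_dataset):
        profs = profile_hairpin(small_dataset.hairpin_tags,
                                small_dataset.hairpins, max_mismatch=0)
        calls = process_hairpins(profs, small_dataset.hairpins)
        with_signal = [c for c in calls if c.total_mass >= 5]
        ok = sum(c.arm_verdict == "simultaneous-compatible"
                 for c in with_signal)
        assert ok / len(with_signal) >= 0.9

    def test_hairpin_tag_fraction_controls_detection_rate(self):
        cfg = SimConfig(n_hairpins=100, hairpin_tag_fraction=0.4, seed=15)
        _, hairpins, truth = gen_mirna_set(cfg)
        from degradome_kit.simulate import TruthTable
        import pandas as pd

        tt = TruthTable(pd.DataFrame(), pd.DataFrame(), truth)
        tags = gen_hairpin_tags(hairpins, tt, cfg)
        profs = profile_hairpin(tags, hairpins, max_mismatch=0)
        frac = sum(p.total_mass > 0 for p in profs.values()) / len(hairpins)
        # binomial 3-SD band around the planted 40%
        sd = np.sqrt(0.4 * 0.6 / 100)
        assert abs(frac - 0.4) <= 3 * sd + 1e-9
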