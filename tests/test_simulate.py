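"""Generator correctness: construction rules, determinism, sampling laws."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from degradome_kit.models import revcomp
from degradome_kit.simulate import (
    CONDITIONS,
    STOP_CODONS,
    SimConfig,
    TruthTable,
    gen_mirna_set,
    gen_pare_library,
    gen_rnaseq_counts,
    gen_transcriptome,
    plant_targets,
    simulate_dataset,
)


class TestConfigValidation:
    def test_rejects_short_length_range(self):
        with pytest.raises(ValueError, match="length_range"):
            SimConfig(length_range=(100, 300))

    def test_rejects_unnormalised_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(decay_type_fractions={"I": 0.5, "none": 0.4})

    def test_rejects_bad_background(self):
        with pytest.raises(ValueError, match="background_model"):
            SimConfig(background_model="linear")


class TestTranscriptome:
    def test_seed_determinism(self):
        cfg = SimConfig(n_genes=10, seed=1)
        a, truth_a = gen_transcriptome(cfg)
        b, truth_b = gen_transcriptome(cfg)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_gc_matches_target(self):
        cfg = SimConfig(n_genes=200, gc_target=0.5, seed=2)
        transcripts, _ = gen_transcriptome(cfg)
        gcs = [
            (t.sequence.count("G") + t.sequence.count("C")) / len(t.sequence)
            for t in transcripts
        ]
        assert abs(np.mean(gcs) - 0.5) < 0.02

    def test_cds_structure(self):
        cfg = SimConfig(n_genes=30, seed=3)
        transcripts, _ = gen_transcriptome(cfg)
        for t in transcripts:
            cds = t.region_seq("cds")
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in STOP_CODONS
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_directions_mass_balanced(self):
        """Paired up/down assignment keeps planted effects composition-neutral."""
        cfg = SimConfig(n_genes=400, seed=4)
        transcripts, truth = gen_transcriptome(cfg)
        lengths = pd.Series({t.gene_id: len(t.sequence) for t in transcripts})
        for dtype in ("I", "II", "IV"):
            sel = truth[truth["decay_type"] == dtype]
            assert abs(int(sel["direction"].sum())) <= 1
        assert (truth.loc[truth["decay_type"] == "none", "direction"] == 0).all()


class TestMirnaSet:
    def test_mature_lengths_and_geometry(self):
        cfg = SimConfig(n_mirnas=10, n_hairpins=15, seed=5)
        mirnas, hairpins, truth = gen_mirna_set(cfg)
        assert all(len(s) in (20, 21, 22) for s in mirnas.values())
        assert len(hairpins) == 15
        assert set(truth["mode"]) <= {"loop_last", "loop_first", "dispersed"}
        for h in hairpins:
            lo, hi = h.loop_interval
            assert hi - lo + 1 >= 8
            # duplex intervals never overlap the loop
            assert h.mir_interval[1] < lo or h.mir_interval[0] > hi

    def test_star_is_near_reverse_complement(self):
        cfg = SimConfig(n_hairpins=20, seed=6)
        _, hairpins, _ = gen_mirna_set(cfg)
        for h in hairpins:
            mir = h.sequence[h.mir_interval[0] - 1 : h.mir_interval[1]]
            star = h.sequence[h.star_interval[0] - 1 : h.star_interval[1]]
            mism = sum(a != b for a, b in zip(revcomp(mir), star))
            assert mism <= 3


class TestPlantTargets:
    def test_bookkeeping_and_score(self):
        from degradome_kit.targets import score_alignment

        cfg = SimConfig(n_genes=40, n_mirnas=5, n_planted_targets=12, seed=7)
        transcripts, _ = gen_transcriptome(cfg)
        mirnas, _, _ = gen_mirna_set(cfg)
        planted, truth, skipped = plant_targets(transcripts, mirnas, cfg)
        assert len(truth) + skipped >= 12
        tmap = {t.transcript_id: t for t in planted}
        for _, row in truth.iterrows():
            mseq = mirnas[row["mirna_id"]]
            L = len(mseq)
            assert row["slice_pos"] == row["site_start"] + L - 10
            site = tmap[row["transcript_id"]].sequence[
                row["site_start"] - 1 : row["site_start"] - 1 + L
            ]
            score, mism, gu = score_alignment(mseq, site)
            assert score == 0.0 and mism == 0 and gu == 0

    def test_slice_positions_inside_transcripts(self, small_dataset):
        tmap = {t.transcript_id: t for t in small_dataset.transcripts}
        for _, row in small_dataset.truth.targets.iterrows():
            assert 1 <= row["slice_pos"] <= len(tmap[row["transcript_id"]].sequence)


class TestPareLibrary:
    def test_depth_conserved_exactly(self, small_dataset, small_cfg):
        for tags in small_dataset.pare.values():
            assert sum(tags.values()) == small_cfg.pare_depth

    def test_seed_determinism(self, small_cfg, small_dataset):
        again = gen_pare_library(
            small_dataset.transcripts, small_dataset.truth, small_cfg,
            "control", 1,
        )[0]
        assert again == small_dataset.pare[("control", 1)]

    def test_pure_peak_library_hits_only_slice_sites(self):
        cfg = SimConfig(
            n_genes=10, n_mirnas=3, n_planted_targets=10, peak_fraction=1.0,
            pare_depth=2_000, n_hairpins=5, seed=8,
        )
        transcripts, gene_truth = gen_transcriptome(cfg)
        mirnas, _, hp_truth = gen_mirna_set(cfg)
        transcripts, targets, _ = plant_targets(transcripts, mirnas, cfg)
        truth = TruthTable(gene_truth, targets, hp_truth)
        tags, _ = gen_pare_library(transcripts, truth, cfg, "control", 1)
        slice_tags = set()
        tmap = {t.transcript_id: t for t in transcripts}
        for _, row in targets.iterrows():
            seq = tmap[row["transcript_id"]].sequence
            s = row["slice_pos"]
            slice_tags.add(seq[s - 1 : s - 1 + cfg.tag_length])
        targeted = set(targets["transcript_id"])
        # genes without planted sites still emit background tags
        background_ok = {
            t
            for tid in tmap
            if tid not in targeted
            for t in [tmap[tid].sequence]
        }
        for tag in tags:
            if tag not in slice_tags:
                assert any(tag in tmap[tid].sequence for tid in tmap
                           if tid not in targeted)

    def test_planted_effect_ratio(self):
        """Dd/Dc expected-tag ratio of a responsive gene equals 2^effect,
        and observed counts fall within 3 binomial SDs of expectation."""
        cfg = SimConfig(n_genes=200, pare_depth=200_000, seed=9)
        ds = simulate_dataset(cfg)
        _, exp_c = gen_pare_library(ds.transcripts, ds.truth, cfg, "control", 1)
        _, exp_d = gen_pare_library(ds.transcripts, ds.truth, cfg, "drought", 1)
        resp = ds.truth.genes.query("decay_type in ('I', 'II')")
        ratio = (exp_d / exp_c)[resp.index]
        expected = 2.0 ** (cfg.effect_size_log2 * resp["direction"])
        # renormalisation shifts the planted ratio by at most a few percent
        assert np.allclose(ratio, expected, rtol=0.05)
        tag_counts_c = ds.pare[("control", 1)]
        total = sum(tag_counts_c.values())
        assert total == cfg.pare_depth
        # per-gene observed vs expected proportion within 3 binomial SDs
        from degradome_kit.quantify import TranscriptomeIndex, build_profiles, map_tags

        res = map_tags(tag_counts_c, ds.transcripts, max_mismatch=0)
        profs = build_profiles(res, ds.transcripts)
        tmap = {t.transcript_id: t for t in ds.transcripts}
        within = 0
        checked = 0
        for tid, prof in profs.items():
            p = exp_c[tmap[tid].gene_id]
            mean = cfg.pare_depth * p
            sd = np.sqrt(cfg.pare_depth * p * (1 - p))
            # multi-mapping can move mass between genes; allow 3 SD + 1
            if abs(prof.total_mass - mean) <= 3 * sd + 1:
                within += 1
            checked += 1
        assert within / checked > 0.95


class TestRnaseqCounts:
    def test_seed_determinism(self, small_dataset, small_cfg):
        again = gen_rnaseq_counts(
            small_dataset.transcripts, small_dataset.truth, small_cfg
        )
        pd.testing.assert_frame_equal(again, small_dataset.rnaseq)

    def test_null_genes_equal_mean_across_conditions(self):
        # needs enough responsive genes for the pairing balance to bite
        cfg = SimConfig(n_genes=400, rnaseq_depth=400_000, seed=12)
        ds = simulate_dataset(cfg)
        counts = ds.rnaseq
        null = ds.truth.genes.query("decay_type in ('II', 'none')").index
        c = counts.loc[null, "control"].sum(axis=1)
        d = counts.loc[null, "drought"].sum(axis=1)
        # type-II genes have no planted transcription effect
        ratio = (d.sum() + 1) / (c.sum() + 1)
        assert 0.95 < ratio < 1.05

    def test_poisson_limit(self):
        """At dispersion -> 0 the count variance matches the Poisson mean."""
        cfg = SimConfig(n_genes=500, nb_dispersion=0.0, rnaseq_depth=500_000,
                        decay_type_fractions={"none": 1.0}, seed=10,
                        n_replicates=2)
        transcripts, gene_truth = gen_transcriptome(cfg)
        mirnas, hairpins, hp_truth = gen_mirna_set(cfg)
        truth = TruthTable(gene_truth, pd.DataFrame(
            columns=["mirna_id", "transcript_id", "site_start", "slice_pos"]
        ), hp_truth)
        counts = gen_rnaseq_counts(transcripts, truth, cfg)
        reps = counts["control"]
        m = reps.mean(axis=1)
        # Pearson dispersion statistic ~ 1 under Poisson sampling
        stat = (((reps.sub(m, axis=0)) ** 2).div(m, axis=0)).to_numpy().mean()
        assert 0.5 < stat < 1.7

    def test_overdispersion_visible_at_large_dispersion(self):
        cfg = SimConfig(n_genes=300, nb_dispersion=0.2, seed=11,
                        decay_type_fractions={"none": 1.0})
        transcripts, gene_truth = gen_transcriptome(cfg)
        _, hairpins, hp_truth = gen_mirna_set(cfg)
        truth = TruthTable(gene_truth, pd.DataFrame(
            columns=["mirna_id", "transcript_id", "site_start", "slice_pos"]
        ), hp_truth)
        counts = gen_rnaseq_counts(transcripts, truth, cfg)
        reps = counts["control"]
        m = reps.mean(axis=1)
        stat = (((reps.sub(m, axis=0)) ** 2).div(m, axis=0)).to_numpy().mean()
        assert stat > 2.0


def test_full_dataset_determinism(small_cfg, small_dataset):
    ds2 = simulate_dataset(small_cfg)
    assert ds2.pare == small_dataset.pare
    assert ds2.hairpin_tags == small_dataset.hairpin_tags
    assert [t.sequence for t in ds2.transcripts] == [
        t.sequence for t in small_dataset.transcripts
    ]


def test_write_dataset_byte_identical(tmp_path, small_cfg):
    from degradome_kit.simulate import write_dataset

    cfg = SimConfig(n_genes=10, n_mirnas=3, n_planted_targets=5,
                    pare_depth=2000, rnaseq_depth=5000, n_hairpins=5, seed=1)
    for d in ("a", "b"):
        write_dataset(simulate_dataset(cfg), tmp_path / d)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
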