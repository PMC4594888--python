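"""Planted-truth recovery benchmarks.

Each function simulates a study with the generator, runs the relevant
analysis stages from scratch and measures recovery/calibration against
the planted truth.  They are used both by the acceptance test suite
and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import differential, hairpins as hp, targets
from .decay import classify_genes
from .quantify import TranscriptomeIndex, build_profiles, gene_rpm, map_tags, merge_replicates
from .simulate import SimConfig, gen_hairpin_tags, gen_mirna_set, simulate_dataset


def target_recovery(seed: int = 1) -> dict:
    """Recovery of planted category-0 cleavage sites.

    500 transcripts, 20 miRNAs, 50 planted perfect-complement sites,
    peak fraction 0.8, 1e5 tags; hits are called on the control library
    (replicates pooled) and compared with the planted truth.
    """
    cfg = SimConfig(
        n_genes=500, n_mirnas=20, n_planted_targets=50,
        peak_fraction=0.8, pare_depth=100_000, n_hairpins=5, seed=seed,
    )
    ds = simulate_dataset(cfg)
    index = TranscriptomeIndex(ds.transcripts)
    pooled = None
    for rep in (1, 2):
        res = map_tags(ds.pare[("control", rep)], index, max_mismatch=1)
        profs = build_profiles(res, ds.transcripts)
        if pooled is None:
            pooled = profs
        else:
            for tid in pooled:
                pooled[tid].counts = pooled[tid].counts + profs[tid].counts
    cands = targets.scan_candidates(ds.mirnas, ds.transcripts, max_score=4.0)
    hits, _ = targets.validate_with_degradome(cands, pooled, min_reads=2.0)
    truth = {
        (r["mirna_id"], r["transcript_id"], int(r["slice_pos"]))
        for _, r in ds.truth.targets.iterrows()
    }
    found_cat0 = {
        (h.alignment.mirna_id, h.alignment.transcript_id, h.slice_pos)
        for h in hits
        if h.category == 0
    }
    found_all = {
        (h.alignment.mirna_id, h.alignment.transcript_id, h.slice_pos)
        for h in hits
    }
    recovered = len(truth & found_cat0)
    return {
        "n_planted": len(truth),
        "recovery_pct": 100.0 * recovered / len(truth),
        "false_positives": len(found_all - truth),
        "n_hits": len(hits),
    }


def hairpin_mode_recovery(seed: int = 1) -> dict:
    """Processing-mode recovery on 100 hairpins, half planted per mode."""
    cfg = SimConfig(
        n_hairpins=100,
        hairpin_mode_fractions={"loop_last": 0.5, "loop_first": 0.5,
                                "dispersed": 0.0},
        hairpin_purity=0.8, hairpin_tags_per_hairpin=25, seed=seed,
    )
    _, hairpin_list, hp_truth = gen_mirna_set(cfg)
    from .simulate import TruthTable

    tt = TruthTable(pd.DataFrame(), pd.DataFrame(), hp_truth)
    tags = gen_hairpin_tags(hairpin_list, tt, cfg)
    profs = hp.profile_hairpin(tags, hairpin_list, max_mismatch=0)
    calls = {c.hairpin_id: c for c in hp.process_hairpins(profs, hairpin_list)}
    correct = sum(
        calls[hid].mode == row["mode"] for hid, row in hp_truth.iterrows()
    )
    with_signal = [c for c in calls.values() if c.total_mass > 0]
    arm_ok = sum(
        c.arm_verdict == "simultaneous-compatible" for c in with_signal
    )
    return {
        "n_hairpins": len(hairpin_list),
        "mode_recovery_pct": 100.0 * correct / len(hairpin_list),
        "arm_simultaneous_pct": 100.0 * arm_ok / len(with_signal),
    }


def differential_calibration(seed: int = 1, n_genes: int = 200_000) -> dict:
    """Size and oracle agreement of the two-library test under the null.

    Null genes draw Poisson counts with a common per-gene mean in two
    libraries of matched size; the z-test's raw-p tail at 0.001 and its
    decision agreement with the exact conditional binomial oracle are
    measured.
    """
    rng = np.random.default_rng([seed, 101])
    m = rng.lognormal(3.0, 1.0, size=n_genes)
    c1 = rng.poisson(m)
    c2 = rng.poisson(m)
    n = float(m.sum())  # matched library sizes
    p_z = differential.two_library_test(c1, n, c2, n)
    frac = float((p_z < 1e-3).mean())
    p_e = differential.exact_binomial_test(c1, c2, n, n)
    pooled = c1 + c2
    mask = pooled >= 20
    agreement = float(((p_z < 1e-3) == (p_e < 1e-3))[mask].mean())
    return {
        "n_genes": n_genes,
        "null_p_fraction_below_1e3": frac,
        "oracle_decision_agreement_pct": 100.0 * agreement,
    }


def decay_type_recovery(seed: int = 1) -> dict:
    """Planted decay-type recovery through the full two-layer pipeline.

    Runs tag mapping, per-condition pooled differential tests on both
    layers and grid classification at default thresholds; measures the
    fraction of planted type I/II/IV genes recovering their type and
    the II<->IV confusion rate.  Also reports replicate RPM correlation
    and the joint fold-change correlation.
    """
    cfg = SimConfig(seed=seed)  # study-scale defaults
    ds = simulate_dataset(cfg)
    index = TranscriptomeIndex(ds.transcripts)
    mass: dict[str, pd.Series] = {}
    rpm_tabs: dict[tuple[str, int], object] = {}
    for cond in ("control", "drought"):
        for rep in (1, 2):
            res = map_tags(ds.pare[(cond, rep)], index, max_mismatch=1)
            profs = build_profiles(res, ds.transcripts)
            g = pd.Series(
                {t.gene_id: profs[t.transcript_id].total_mass
                 for t in ds.transcripts}
            ).sort_index()
            mass[f"{cond}_{rep}"] = g
            rpm_tabs[(cond, rep)] = gene_rpm(profs, res.n_matched_copies,
                                             ds.transcripts)
    _, rep_r2 = merge_replicates([rpm_tabs[("control", 1)],
                                  rpm_tabs[("control", 2)]])
    d_ctrl = (mass["control_1"] + mass["control_2"]).round()
    d_trt = (mass["drought_1"] + mass["drought_2"]).round()
    d_calls = differential.diff_table(d_ctrl, d_trt, layer="D",
                                      gene_ids=d_ctrl.index)
    counts = ds.rnaseq
    r_calls = differential.diff_table(
        counts["control"].sum(axis=1), counts["drought"].sum(axis=1),
        layer="R", gene_ids=counts.index,
    )
    assignments = classify_genes(d_calls, r_calls)
    truth = ds.truth.genes
    planted = truth[truth["decay_type"] != "none"]
    called = assignments.loc[planted.index, "type"]
    recovered = (called == planted["decay_type"]).mean()
    ii = planted[planted["decay_type"] == "II"].index
    iv = planted[planted["decay_type"] == "IV"].index
    confusion = max(
        (assignments.loc[ii, "type"] == "IV").mean() if len(ii) else 0.0,
        (assignments.loc[iv, "type"] == "II").mean() if len(iv) else 0.0,
    )
    from .pipeline import joint_fc_correlation

    fc_r2, _ = joint_fc_correlation(d_calls, r_calls)
    return {
        "n_planted": int(len(planted)),
        "type_recovery_pct": 100.0 * float(recovered),
        "ii_iv_confusion_pct": 100.0 * float(confusion),
        "replicate_r2": float(rep_r2),
        "joint_fc_r2": float(fc_r2),
    }


def oracle_equivalences(seed: int = 1) -> dict:
    """Exact-agreement checks against independent reference computations."""
    from .features import enumerate_max_pairs, fold_mfe_fallback
    from .quantify import map_tags_bruteforce

    rng = np.random.default_rng([seed, 202])
    # mapping vs all-positions scan
    from .models import TranscriptModel

    transcripts = [
        TranscriptModel(f"t{i}.1", f"t{i}",
                        "".join(rng.choice(list("ACGT"), 500)),
                        None, (1, 498), None)
        for i in range(10)
    ]
    tags = {}
    for _ in range(40):
        t = transcripts[rng.integers(10)]
        s = rng.integers(0, 480)
        tag = list(t.sequence[s : s + 20])
        for _ in range(rng.integers(0, 3)):
            tag[rng.integers(20)] = rng.choice(list("ACGT"))
        tags["".join(tag)] = 1
    map_ok = all(
        map_tags(tags, transcripts, mm).assignments
        == map_tags_bruteforce(tags, transcripts, mm)
        for mm in (0, 1)
    )
    # alignment scoring vs per-position penalty oracle
    score_ok = all(
        targets.score_alignment(
            mir := "".join(rng.choice(list("ACGU"), 21)),
            site := "".join(rng.choice(list("ACGT"), 21)),
        )[0] == _score_oracle(mir, site)
        for _ in range(1000)
    )
    # folding fallback vs exhaustive pairing enumeration (<= 12 nt)
    fold_seqs = ["GGGAAACCC", "ACGUACGUACGU", "AAAAAA"] + [
        "".join(rng.choice(list("ACGU"), rng.integers(4, 13)))
        for _ in range(30)
    ]
    fold_ok = all(
        fold_mfe_fallback(s) == -enumerate_max_pairs(s) for s in fold_seqs
    )
    # BH step-up vs hand-computed vectors
    bh_ok = np.allclose(
        differential.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
    ) and np.allclose(
        differential.bh_adjust([0.005, 0.04, 0.04, 0.8]),
        [0.02, 0.04 * 4 / 3, 0.04 * 4 / 3, 0.8],
    )
    n_ok = sum([map_ok, score_ok, fold_ok, bh_ok])
    return {
        "map_tags_oracle_exact": bool(map_ok),
        "score_oracle_exact": bool(score_ok),
        "fold_oracle_exact": bool(fold_ok),
        "bh_oracle_exact": bool(bh_ok),
        "oracles_passed_pct": 100.0 * n_ok / 4,
    }


def conservation_invariants(seed: int = 1) -> dict:
    """Exact conservation checks: tag mass, RPM totals, MFEI formula."""
    from .features import mfei

    cfg = SimConfig(n_genes=80, pare_depth=20_000, n_hairpins=5, seed=seed)
    ds = simulate_dataset(cfg)
    res = map_tags(ds.pare[("control", 1)], ds.transcripts, max_mismatch=1)
    profs = build_profiles(res, ds.transcripts)
    total_mass = sum(p.total_mass for p in profs.values())
    mass_err = abs(total_mass - res.n_matched_copies)
    rpm = gene_rpm(profs, res.n_matched_copies, ds.transcripts)
    rpm_err = abs(rpm.values.sum() - 1e6)
    return {
        "mass_conservation_abs_error": float(mass_err),
        "rpm_total_abs_error": float(rpm_err),
        "mfei_reference_value": mfei(-40.0, 100, 0.5),
    }


def _score_oracle(mirna: str, site: str) -> float:
    wc = {"A": "U", "U": "A", "G": "C", "C": "G"}
    mir = mirna.upper().replace("T", "U")
    tgt = site.upper().replace("T", "U")
    L = len(mir)
    total = 0.0
    for i in range(1, L + 1):
        m, t = mir[i - 1], tgt[L - i]
        if wc[m] == t:
            pen = 0.0
        elif (m, t) in {("G", "U"), ("U", "G")}:
            pen = 0.5
        else:
            pen = 1.0
        total += pen * (2.0 if 2 <= i <= 13 else 1.0)
    return total
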