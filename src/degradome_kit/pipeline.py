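"""End-to-end orchestration of the degradome analysis stages.

``run_all`` wires the stages together over a directory of inputs in
the formats the generator writes (FASTA transcriptome + GFF3, PARE
tag FASTAs per condition/replicate, RNA-seq count TSV, miRNA and
hairpin files), applies the differential thresholds to both layers,
and writes every stage's tables plus a run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decay, differential, features, hairpins as hp, io as dio
from . import quantify, targets

log = logging.getLogger("degradome_kit")

ALL_STAGES = ("quantify", "differential", "classify", "features",
              "targets", "hairpins")


@dataclass
class RunConfig:
    """Paths, thresholds and stage toggles for one pipeline run."""

    input_dir: str
    out_dir: str
    conditions: tuple[str, str] = ("control", "drought")
    replicates: tuple[int, ...] = (1, 2)
    fc_thresh: float = 1.0
    p_thresh: float = 0.001
    max_mismatch: int = 1
    max_score: float = 4.0
    min_reads: float = 2.0
    offset_tolerance: int = 0
    dominance: float = 2.0
    min_total: float = 5.0
    window: int = 1
    fold_engine: str = "auto"
    fold_max_len: int = 500  # regions longer than this skip MFEI
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("conditions", "replicates", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def joint_fc_correlation(
    d_calls: pd.DataFrame, r_calls: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation of D- and R-layer log2 fold changes.

    Computed over genes present in both layers; also returns the
    scatter table (gene_id, d_log2fc, r_log2fc).
    """
    shared = d_calls.index.intersection(r_calls.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    scatter = pd.DataFrame(
        {
            "gene_id": shared,
            "d_log2fc": d_calls.loc[shared, "log2fc"].to_numpy(),
            "r_log2fc": r_calls.loc[shared, "log2fc"].to_numpy(),
        }
    )
    r = np.corrcoef(scatter["d_log2fc"], scatter["r_log2fc"])[0, 1]
    return float(r * r), scatter


def run_all(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    ind = Path(cfg.input_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "stages": {},
    }

    required = [ind / "transcripts.fa", ind / "genes.gff3"]
    for p in required:
        if not p.exists():
            raise FileNotFoundError(f"missing required input: {p}")

    seqs = dio.read_fasta(ind / "transcripts.fa")
    transcripts = dio.read_gff3(ind / "genes.gff3", seqs)
    tmap = {t.transcript_id: t for t in transcripts}
    log.info("loaded %d transcripts", len(transcripts))

    profiles_by_lib: dict[str, dict] = {}
    gene_mass: dict[str, pd.Series] = {}
    rpm_tables: dict[str, quantify.AbundanceTable] = {}

    if "quantify" in cfg.stages:
        index = quantify.TranscriptomeIndex(transcripts)
        for cond in cfg.conditions:
            for rep in cfg.replicates:
                lib = f"{cond}_{rep}"
                tags = dio.read_tag_library(ind / f"pare_{cond}_{rep}.fa")
                res = quantify.map_tags(tags, index, cfg.max_mismatch)
                profs = quantify.build_profiles(res, tmap, library_id=lib)
                profiles_by_lib[lib] = profs
                mass = pd.Series(
                    {t.gene_id: profs[t.transcript_id].total_mass
                     for t in transcripts}
                ).sort_index()
                gene_mass[lib] = mass
                rpm_tables[lib] = quantify.gene_rpm(
                    profs, res.n_matched_copies, tmap, library_id=lib
                )
                dio.write_profiles(out / f"profiles_{lib}.tsv", profs)
        rep_r2 = {}
        for cond in cfg.conditions:
            tabs = [rpm_tables[f"{cond}_{r}"] for r in cfg.replicates]
            mean_tab, r2 = quantify.merge_replicates(tabs)
            rep_r2[cond] = r2
            mean_tab.values.rename("rpm").to_csv(
                out / f"rpm_mean_{cond}.tsv", sep="\t", index_label="gene_id"
            )
        manifest["stages"]["quantify"] = {
            "libraries": sorted(profiles_by_lib),
            "replicate_r2": rep_r2,
        }
    else:
        manifest["stages"]["quantify"] = "skipped"

    d_calls = r_calls = None
    if "differential" in cfg.stages:
        if "quantify" not in cfg.stages:
            raise RuntimeError("differential requires the quantify stage")
        ctrl, trt = cfg.conditions
        d_ctrl = sum(gene_mass[f"{ctrl}_{r}"] for r in cfg.replicates)
        d_trt = sum(gene_mass[f"{trt}_{r}"] for r in cfg.replicates)
        d_calls = differential.diff_table(
            d_ctrl.round(), d_trt.round(), layer="D",
            gene_ids=d_ctrl.index, fc_thresh=cfg.fc_thresh,
            p_thresh=cfg.p_thresh,
        )
        counts = dio.read_counts_tsv(ind / "rnaseq_counts.tsv")
        r_ctrl = counts[[c for c in counts.columns if c.startswith(ctrl)]].sum(axis=1)
        r_trt = counts[[c for c in counts.columns if c.startswith(trt)]].sum(axis=1)
        r_calls = differential.diff_table(
            r_ctrl, r_trt, layer="R", gene_ids=counts.index,
            fc_thresh=cfg.fc_thresh, p_thresh=cfg.p_thresh,
        )
        d_calls.drop(columns="gene_id").to_csv(out / "diff_D.tsv", sep="\t")
        r_calls.drop(columns="gene_id").to_csv(out / "diff_R.tsv", sep="\t")
        r2, scatter = joint_fc_correlation(d_calls, r_calls)
        scatter.to_csv(out / "joint_fc_scatter.tsv", sep="\t", index=False)
        manifest["stages"]["differential"] = {
            "n_genes": int(len(d_calls)),
            "joint_fc_r2": r2,
        }
    else:
        manifest["stages"]["differential"] = "skipped"

    if "classify" in cfg.stages:
        if d_calls is None:
            raise RuntimeError("classify requires the differential stage")
        assignments = decay.classify_genes(d_calls, r_calls)
        assignments.drop(columns="gene_id").to_csv(
            out / "decay_classes.tsv", sep="\t"
        )
        summary = decay.summarize_types(assignments)
        summary.to_csv(out / "decay_type_summary.tsv", sep="\t", index=False)
        manifest["stages"]["classify"] = {
            "classified": int(assignments["class"].notna().sum()),
            "ambiguous": int(assignments["class"].isna().sum()),
        }
    else:
        assignments = None
        manifest["stages"]["classify"] = "skipped"

    if "features" in cfg.stages:
        feats = features.feature_table(
            transcripts, cfg.fold_engine, max_fold_len=cfg.fold_max_len
        )
        feats.drop(columns="transcript_id").to_csv(
            out / "features.tsv", sep="\t"
        )
        comparisons = []
        if assignments is not None:
            tid_of = {t.gene_id: t.transcript_id for t in transcripts}
            groups = {}
            for dtype in ("I", "II", "IV"):
                ids = assignments.index[assignments["type"] == dtype]
                groups[f"type_{dtype}"] = [tid_of[g] for g in ids]
            sizes = [len(v) for v in groups.values() if len(v)]
            groups = {k: v for k, v in groups.items() if v}
            if sizes:
                ctrl_size = int(round(np.mean(sizes)))
                groups["random"] = features.random_control_set(
                    [t.transcript_id for t in transcripts], ctrl_size, cfg.seed
                )
            groups["all"] = [t.transcript_id for t in transcripts]
            for feat in ("mrna_len", "utr5_len", "utr3_len", "intron_count"):
                comparisons.append(features.compare_feature(feats, groups, feat))
        if comparisons:
            pd.concat(comparisons).to_csv(
                out / "feature_comparisons.tsv", sep="\t", index=False
            )
        manifest["stages"]["features"] = {"n_transcripts": int(len(feats))}
    else:
        manifest["stages"]["features"] = "skipped"

    if "targets" in cfg.stages:
        if "quantify" not in cfg.stages:
            raise RuntimeError("targets requires the quantify stage")
        mirnas = dio.read_fasta(ind / "mirnas.fa")
        cands = targets.scan_candidates(mirnas, transcripts, cfg.max_score)
        # validate against the control degradome (replicate profiles pooled)
        ctrl = cfg.conditions[0]
        pooled = {}
        for tid, t in tmap.items():
            arr = sum(
                profiles_by_lib[f"{ctrl}_{r}"][tid].counts
                for r in cfg.replicates
            )
            pooled[tid] = quantify.SignalProfile(tid, arr, library_id=ctrl)
        hits, dropped = targets.validate_with_degradome(
            cands, pooled, cfg.min_reads, cfg.offset_tolerance, library_id=ctrl
        )
        rows = [
            {
                "mirna_id": h.alignment.mirna_id,
                "transcript_id": h.alignment.transcript_id,
                "target_start": h.alignment.target_start,
                "target_end": h.alignment.target_end,
                "score": h.alignment.score,
                "slice_pos": h.slice_pos,
                "peak_reads": h.peak_reads,
                "category": h.category,
                "pairing": h.alignment.pairing,
            }
            for h in hits
        ]
        pd.DataFrame(rows).to_csv(out / "target_hits.tsv", sep="\t", index=False)
        manifest["stages"]["targets"] = {
            "candidates": len(cands), "hits": len(hits), "dropped": dropped,
        }
    else:
        manifest["stages"]["targets"] = "skipped"

    if "hairpins" in cfg.stages:
        hairpin_list = dio.read_hairpins(ind / "hairpins.tsv", ind / "hairpins.fa")
        tag_file = ind / "pare_hairpin.fa"
        hp_tags = dio.read_tag_library(tag_file) if tag_file.exists() else {}
        profs = hp.profile_hairpin(hp_tags, hairpin_list, max_mismatch=0)
        calls = hp.process_hairpins(
            profs, hairpin_list, min_total=cfg.min_total,
            dominance=cfg.dominance, window=cfg.window,
        )
        hp.calls_to_frame(calls).to_csv(
            out / "hairpin_calls.tsv", sep="\t", index=False
        )
        with_signal = sum(c.total_mass > 0 for c in calls)
        manifest["stages"]["hairpins"] = {
            "n_hairpins": len(calls),
            "with_signal": int(with_signal),
        }
    else:
        manifest["stages"]["hairpins"] = "skipped"

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
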