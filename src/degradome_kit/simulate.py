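"""Synthetic degradome study generator with planted ground truth.

Emulates a two-condition (control vs drought) degradome experiment:

* a transcriptome of mRNAs with 5'UTR / CDS / 3'UTR structure and
  annotated intron counts;
* mature miRNAs and stem-loop precursors with recorded miRNA/miRNA*
  coordinates;
* miRNA cleavage sites written into chosen transcripts, so that the
  slice coordinate (paired to miRNA base 10) is known exactly;
* PARE tag libraries (two conditions x two replicates): 20-nt 5'
  signatures drawn multinomially, with a configurable fraction of a
  target's tags at its planted slice site over a 5'->3' decay
  background, and condition-dependent abundance shifts for planted
  decay types;
* negative-binomial RNA-seq counts sharing the same gene-level
  abundances;
* hairpin-derived tag sets planted according to a processing mode
  (loop-last / loop-first / dispersed).

Planted decay types follow the joint degradation(D)/transcription(R)
patterns: type I shifts both layers in the same direction, type II
shifts D only, type IV shifts R only; "none" genes are null in both.
All outputs are pure functions of the configuration, including its
seed; replicates share gene-level expected abundances and differ only
in sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .models import Hairpin, TranscriptModel, revcomp

CONDITIONS = ("control", "drought")
STOP_CODONS = ("TAA", "TAG", "TGA")
_WC_DNA = {"A": "T", "T": "A", "G": "C", "C": "G"}

# independent random streams derived from the master seed
_STREAM_TRANSCRIPTOME = 1
_STREAM_ABUNDANCE = 2
_STREAM_MIRNA = 3
_STREAM_TARGETS = 4
_STREAM_PARE = 5
_STREAM_RNASEQ = 6
_STREAM_HAIRPIN_TAGS = 7


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    n_genes: int = 500
    length_range: tuple[int, int] = (600, 2500)
    gc_target: float = 0.5
    n_mirnas: int = 20
    n_planted_targets: int = 50
    decay_type_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.10, "II": 0.05, "IV": 0.10, "none": 0.75}
    )
    effect_size_log2: float = 2.0
    pare_depth: int = 100_000
    rnaseq_depth: int = 500_000
    nb_dispersion: float = 0.001
    peak_fraction: float = 0.8
    background_model: str = "exp5to3"  # or "uniform"
    n_hairpins: int = 100
    hairpin_mode_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"loop_last": 0.5, "loop_first": 0.5,
                                 "dispersed": 0.0}
    )
    seed: int = 0
    # secondary knobs
    tag_length: int = 20
    target_mispairs: int = 0
    intron_mean: float = 3.0
    responsive_utr_boost: int = 0  # extra UTR nt for planted-type genes
    hairpin_tags_per_hairpin: int = 25
    hairpin_tag_fraction: float = 1.0
    hairpin_purity: float = 0.8
    hairpin_arm5_leak: float = 0.02
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.length_range[0] < 200:
            raise ValueError("length_range minimum must be >= 200 nt")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        for name in ("gc_target", "peak_fraction", "hairpin_tag_fraction",
                     "hairpin_purity", "hairpin_arm5_leak"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name, fr in (("decay_type_fractions", self.decay_type_fractions),
                         ("hairpin_mode_fractions", self.hairpin_mode_fractions)):
            if any(not 0 <= v <= 1 for v in fr.values()):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.pare_depth <= 0 or self.rnaseq_depth <= 0:
            raise ValueError("depths must be positive")
        if self.background_model not in ("uniform", "exp5to3"):
            raise ValueError("background_model must be uniform or exp5to3")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


@dataclass
class TruthTable:
    """Planted ground truth for every downstream stage."""

    genes: pd.DataFrame  # gene_id, decay_type, direction (+1/-1/0)
    targets: pd.DataFrame  # mirna_id, transcript_id, site_start, slice_pos
    hairpins: pd.DataFrame  # hairpin_id, mode
    skipped_targets: int = 0


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _sanitize_cds(bases: np.ndarray, rng: np.random.Generator) -> None:
    """Force ATG start, a stop end, and no internal stop codons (in place)."""
    n = len(bases)
    bases[0:3] = list("ATG")
    bases[n - 3 : n] = list(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    for i in range(3, n - 3, 3):
        while "".join(bases[i : i + 3]) in STOP_CODONS:
            bases[i + 2] = "ACGT"[rng.integers(4)]


def _assign_types(cfg: SimConfig) -> np.ndarray:
    rng = cfg.rng(_STREAM_TRANSCRIPTOME, 99)
    order = rng.permutation(cfg.n_genes)
    types = np.array(["none"] * cfg.n_genes, dtype=object)
    start = 0
    for t in ("I", "II", "IV"):
        k = int(round(cfg.decay_type_fractions.get(t, 0.0) * cfg.n_genes))
        types[order[start : start + k]] = t
        start += k
    return types


def assign_decay_types(
    cfg: SimConfig, lengths: pd.Series | None = None
) -> pd.DataFrame:
    """Planted decay type and direction per gene (deterministic per seed).

    Within each responsive type, directions are assigned in
    mass-matched pairs (one up, one down per adjacent pair of the
    expected-library-mass ranking, mass = abundance x length when
    lengths are known) so planted effects leave total library
    composition balanced — non-responsive genes then keep
    condition-invariant sampling proportions.
    """
    types = _assign_types(cfg)
    rng = cfg.rng(_STREAM_TRANSCRIPTOME, 98)
    mass = _gene_base_abundance(cfg).to_numpy()
    if lengths is not None:
        mass = mass * lengths.to_numpy()
    direction = np.zeros(cfg.n_genes, dtype=int)
    for t in ("I", "II", "IV"):
        idx = np.nonzero(types == t)[0]
        idx = idx[np.argsort(mass[idx])]
        for j in range(0, len(idx), 2):
            flip = 1 if rng.random() < 0.5 else -1
            direction[idx[j]] = flip
            if j + 1 < len(idx):
                direction[idx[j + 1]] = -flip
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(cfg.n_genes)],
            "decay_type": types,
            "direction": direction,
        }
    ).set_index("gene_id", drop=False)


def gen_transcriptome(cfg: SimConfig) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Random mRNAs with UTR/CDS structure plus the gene truth table.

    Each transcript carries a 5'UTR, an ATG-initiated stop-terminated
    CDS of length divisible by 3 with no internal stops, and a 3'UTR;
    intron counts are Poisson-drawn and recorded in the annotation.
    Genes with a planted decay type may receive
    ``responsive_utr_boost`` extra nucleotides on each UTR.
    """
    rng = cfg.rng(_STREAM_TRANSCRIPTOME)
    types = _assign_types(cfg)
    lo, hi = cfg.length_range
    transcripts: list[TranscriptModel] = []
    for i in range(cfg.n_genes):
        gid = f"gene{i:05d}"
        total = int(rng.integers(lo, hi + 1))
        utr5 = int(rng.integers(30, max(31, total // 6)))
        utr3 = int(rng.integers(50, max(51, total // 4)))
        cds_len = total - utr5 - utr3
        cds_len -= cds_len % 3
        if cds_len < 90:
            cds_len = 90
        if types[i] != "none":
            utr5 += cfg.responsive_utr_boost
            utr3 += cfg.responsive_utr_boost
        total = utr5 + cds_len + utr3
        bases = _random_bases(rng, total, cfg.gc_target)
        _sanitize_cds(bases[utr5 : utr5 + cds_len], rng)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.1",
                gene_id=gid,
                sequence="".join(bases),
                utr5=(1, utr5),
                cds=(utr5 + 1, utr5 + cds_len),
                utr3=(utr5 + cds_len + 1, total),
                intron_count=int(rng.poisson(cfg.intron_mean)),
            )
        )
    lengths = pd.Series(
        {t.gene_id: float(len(t.sequence)) for t in transcripts}
    ).reindex([f"gene{i:05d}" for i in range(cfg.n_genes)])
    gene_truth = assign_decay_types(cfg, lengths)
    return transcripts, gene_truth


def gen_mirna_set(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[Hairpin], pd.DataFrame]:
    """Mature miRNAs plus stem-loop precursors with planted modes.

    Each hairpin is built as one stem-loop: a 25-nt basal stem, the
    miRNA arm, a 12-nt loop, a star arm that is the reverse complement
    of the miRNA with at most 2 substitutions (duplex cuts leave the
    canonical 2-nt 3' overhangs), and the complementary basal stem.
    The mature arm (5' or 3') is drawn per hairpin.
    """
    rng = cfg.rng(_STREAM_MIRNA)
    mirnas = {
        f"mir{i:03d}": "".join(_random_bases(rng, int(rng.choice([20, 21, 22])),
                                             cfg.gc_target))
        for i in range(cfg.n_mirnas)
    }
    modes = list(cfg.hairpin_mode_fractions)
    n_per = [int(round(cfg.hairpin_mode_fractions[m] * cfg.n_hairpins))
             for m in modes]
    while sum(n_per) < cfg.n_hairpins:
        n_per[0] += 1
    mode_list = [m for m, k in zip(modes, n_per) for _ in range(k)][: cfg.n_hairpins]
    rng.shuffle(mode_list)

    flank = 25
    loop_len = 12
    hairpins: list[Hairpin] = []
    rows = []
    for i, mode in enumerate(mode_list):
        hid = f"hp{i:03d}"
        Lm = int(rng.choice([20, 21, 22]))
        mir = "".join(_random_bases(rng, Lm, cfg.gc_target))
        star = list(revcomp(mir))
        for j in rng.choice(Lm, size=int(rng.integers(0, 3)), replace=False):
            star[j] = rng.choice([b for b in "ACGT" if b != star[j]])
        star = "".join(star)
        mir_arm = "five_prime" if rng.random() < 0.5 else "three_prime"
        arm5, arm3 = (mir, star) if mir_arm == "five_prime" else (star, mir)
        f5 = "".join(_random_bases(rng, flank, cfg.gc_target))
        loop = "".join(_random_bases(rng, loop_len, 0.2))  # AU-rich loop
        seq = f5 + arm5 + loop + arm3 + revcomp(f5)
        a5 = (flank + 1, flank + len(arm5))
        a3 = (flank + len(arm5) + loop_len + 1,
              flank + len(arm5) + loop_len + len(arm3))
        mir_iv, star_iv = (a5, a3) if mir_arm == "five_prime" else (a3, a5)
        hairpins.append(
            Hairpin(hid, seq, mir_interval=mir_iv, star_interval=star_iv,
                    mir_arm=mir_arm)
        )
        rows.append((hid, mode))
    truth = pd.DataFrame(rows, columns=["hairpin_id", "mode"]).set_index(
        "hairpin_id", drop=False
    )
    return mirnas, hairpins, truth


def plant_targets(
    transcripts: list[TranscriptModel],
    mirnas: Mapping[str, str],
    cfg: SimConfig,
) -> tuple[list[TranscriptModel], pd.DataFrame, int]:
    """Write miRNA complementary sites into transcripts; returns truth rows.

    The reverse complement of the miRNA — with ``target_mispairs``
    substitutions at positions not paired to miRNA bases 10-11 — is
    written into a random downstream location of each chosen transcript
    (sequence replaced in place, coordinates unchanged).  The slice
    position is the transcript coordinate paired with miRNA base 10:
    site_start + L - 10 (1-based), kept far enough from the 3' end for
    a full tag to fit.
    """
    rng = cfg.rng(_STREAM_TARGETS)
    mir_ids = sorted(mirnas)
    order = rng.permutation(len(transcripts))
    rows = []
    skipped = 0
    out = list(transcripts)
    k = 0
    for idx in order:
        if len(rows) >= cfg.n_planted_targets:
            break
        tr = out[idx]
        mid = mir_ids[k % len(mir_ids)]
        mseq = mirnas[mid]
        L = len(mseq)
        site = list(revcomp(mseq))
        if cfg.target_mispairs:
            allowed = [j for j in range(L) if L - j not in (10, 11)]
            for j in rng.choice(allowed, size=cfg.target_mispairs, replace=False):
                site[j] = rng.choice([b for b in "ACGT" if b != site[j]])
        site = "".join(site)
        cds_start = tr.cds[0]
        max_start = len(tr.sequence) - L - cfg.tag_length - 5
        if max_start <= cds_start:
            skipped += 1
            continue
        s = int(rng.integers(cds_start, max_start + 1))
        seq = tr.sequence[: s - 1] + site + tr.sequence[s - 1 + L :]
        out[idx] = replace(tr, sequence=seq)
        rows.append((mid, tr.transcript_id, s, s + L - 10))
        k += 1
    truth = pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "site_start", "slice_pos"]
    )
    return out, truth, skipped


def _gene_base_abundance(cfg: SimConfig) -> pd.Series:
    """Log-normal gene-level expected abundances, shared by all libraries."""
    rng = cfg.rng(_STREAM_ABUNDANCE)
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    return pd.Series(vals, index=[f"gene{i:05d}" for i in range(cfg.n_genes)])


def _condition_factor(
    gene_truth: pd.DataFrame, cfg: SimConfig, layer: str, condition: str
) -> pd.Series:
    """Per-gene abundance factor for one data layer and condition.

    Degradation (D) responds for types I and II; transcription (R)
    responds for types I and IV; type-I genes move the same way in
    both layers.  The planted effect is split symmetrically across
    conditions (2^(+e/2) drought, 2^(-e/2) control for an up gene, so
    the drought/control ratio is exactly 2^e) which, together with the
    paired direction assignment, keeps the two libraries' compositions
    balanced.
    """
    responds = {"D": ("I", "II"), "R": ("I", "IV")}[layer]
    sign = 1.0 if condition == "drought" else -1.0
    fac = np.where(
        gene_truth["decay_type"].isin(responds),
        2.0 ** (sign * cfg.effect_size_log2 / 2.0 * gene_truth["direction"]),
        1.0,
    )
    return pd.Series(fac, index=gene_truth.index)


def _background_weights(cfg: SimConfig, n_pos: int) -> np.ndarray:
    if cfg.background_model == "uniform":
        w = np.ones(n_pos)
    else:  # exp5to3: survivors of 5'->3' decay pile up toward the 3' end
        w = np.exp(3.0 * np.arange(n_pos) / max(n_pos - 1, 1))
    return w / w.sum()


def expected_pare_profile(
    tr: TranscriptModel, slice_sites: list[int], cfg: SimConfig
) -> np.ndarray:
    """Within-transcript distribution of tag 5'-end positions."""
    n_pos = len(tr.sequence) - cfg.tag_length + 1
    probs = _background_weights(cfg, n_pos)
    if slice_sites:
        probs = probs * (1.0 - cfg.peak_fraction)
        share = cfg.peak_fraction / len(slice_sites)
        for s in slice_sites:
            probs[s - 1] += share
    return probs


def gen_pare_library(
    transcripts: list[TranscriptModel],
    truth: TruthTable,
    cfg: SimConfig,
    condition: str,
    replicate: int,
) -> tuple[dict[str, int], pd.Series]:
    """One PARE tag library: multiset of 20-nt 5' signatures.

    Gene totals are multinomial with probabilities proportional to
    abundance x length (times the drought effect for D-responsive
    genes under the drought condition); within a gene, tags fall on
    the planted slice sites with probability ``peak_fraction`` and on
    the decay background otherwise.  Exactly ``pare_depth`` tags are
    emitted.  Returns (tag multiset, per-gene expected proportions).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    lengths = pd.Series(
        {t.gene_id: float(len(t.sequence)) for t in transcripts}
    )
    abund = _gene_base_abundance(cfg).reindex(lengths.index) * lengths
    abund = abund * _condition_factor(truth.genes, cfg, "D", condition).reindex(
        lengths.index
    )
    probs = (abund / abund.sum()).to_numpy()
    rng = cfg.rng(_STREAM_PARE, CONDITIONS.index(condition), replicate)
    gene_totals = rng.multinomial(cfg.pare_depth, probs)
    sites_by_tid: dict[str, list[int]] = {}
    for _, row in truth.targets.iterrows():
        sites_by_tid.setdefault(row["transcript_id"], []).append(
            int(row["slice_pos"])
        )
    tags: dict[str, int] = {}
    for tr, n in zip(transcripts, gene_totals):
        if n == 0:
            continue
        pos_probs = expected_pare_profile(
            tr, sites_by_tid.get(tr.transcript_id, []), cfg
        )
        pos_counts = rng.multinomial(n, pos_probs)
        for p in np.nonzero(pos_counts)[0]:
            tag = tr.sequence[p : p + cfg.tag_length]
            tags[tag] = tags.get(tag, 0) + int(pos_counts[p])
    expected = pd.Series(probs, index=lengths.index)
    return tags, expected


def gen_rnaseq_counts(
    transcripts: list[TranscriptModel],
    truth: TruthTable,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Negative-binomial RNA-seq counts, gene x (condition, replicate).

    Means are proportional to abundance x length scaled to
    ``rnaseq_depth`` per library; variance = m + dispersion * m^2
    (Poisson in the dispersion -> 0 limit).  Types I and IV receive
    the drought effect on this layer.
    """
    lengths = pd.Series({t.gene_id: float(len(t.sequence)) for t in transcripts})
    base = _gene_base_abundance(cfg).reindex(lengths.index) * lengths
    rng = cfg.rng(_STREAM_RNASEQ)
    cols = {}
    for condition in CONDITIONS:
        abund = base * _condition_factor(truth.genes, cfg, "R", condition).reindex(
            lengths.index
        )
        means = (abund / abund.sum()).to_numpy() * cfg.rnaseq_depth
        for rep in range(1, cfg.n_replicates + 1):
            if cfg.nb_dispersion < 1e-9:
                counts = rng.poisson(means)
            else:
                r = 1.0 / cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + means))
            cols[(condition, f"rep{rep}")] = counts
    out = pd.DataFrame(cols, index=lengths.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["condition", "replicate"])
    return out


def gen_hairpin_tags(
    hairpins: list[Hairpin],
    truth: TruthTable,
    cfg: SimConfig,
) -> dict[str, int]:
    """Hairpin-derived PARE tags planted according to processing mode.

    A ``hairpin_tag_fraction`` subset of hairpins emits
    ``hairpin_tags_per_hairpin`` tags each: a ``hairpin_purity``
    fraction at the mode's signature cut site (3'-arm loop-distal for
    loop-last, loop-proximal for loop-first), at most
    ``hairpin_arm5_leak`` on the 5' arm, and the remainder on the rest
    of the 3' side; dispersed hairpins spread tags uniformly.
    """
    from .hairpins import locate_cut_sites

    rng = cfg.rng(_STREAM_HAIRPIN_TAGS)
    n_with = int(round(cfg.hairpin_tag_fraction * len(hairpins)))
    chosen = set(rng.permutation(len(hairpins))[:n_with])
    tags: dict[str, int] = {}
    for i, h in enumerate(hairpins):
        if i not in chosen:
            continue
        n_pos = len(h.sequence) - cfg.tag_length + 1
        sites = locate_cut_sites(h)
        mode = truth.hairpins.loc[h.hairpin_id, "mode"]
        probs = np.zeros(n_pos)
        if mode == "dispersed":
            probs[:] = 1.0
        else:
            sig = sites.distal_pos if mode == "loop_last" else sites.proximal_pos
            probs[sig - 1] = cfg.hairpin_purity
            arm5_end = min(h.arm5_interval[1], n_pos)
            probs[:arm5_end] += cfg.hairpin_arm5_leak / arm5_end
            rest = 1.0 - cfg.hairpin_purity - cfg.hairpin_arm5_leak
            loop_start = h.loop_interval[0]
            span = np.arange(loop_start - 1, n_pos)
            span = span[span != sig - 1]
            probs[span] += rest / len(span)
        probs = probs / probs.sum()
        counts = rng.multinomial(cfg.hairpin_tags_per_hairpin, probs)
        for p in np.nonzero(counts)[0]:
            tag = h.sequence[p : p + cfg.tag_length]
            tags[tag] = tags.get(tag, 0) + int(counts[p])
    return tags


@dataclass
class SyntheticDataset:
    """Everything one run of the generator produces."""

    cfg: SimConfig
    transcripts: list[TranscriptModel]
    mirnas: dict[str, str]
    hairpins: list[Hairpin]
    truth: TruthTable
    pare: dict[tuple[str, int], dict[str, int]]  # (condition, replicate) -> tags
    rnaseq: pd.DataFrame
    hairpin_tags: dict[str, int]


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Run the full generator: transcriptome, miRNAs, truth, libraries."""
    transcripts, gene_truth = gen_transcriptome(cfg)
    mirnas, hairpins, hp_truth = gen_mirna_set(cfg)
    transcripts, target_truth, skipped = plant_targets(transcripts, mirnas, cfg)
    truth = TruthTable(gene_truth, target_truth, hp_truth, skipped)
    pare = {
        (cond, rep): gen_pare_library(transcripts, truth, cfg, cond, rep)[0]
        for cond in CONDITIONS
        for rep in range(1, cfg.n_replicates + 1)
    }
    rnaseq = gen_rnaseq_counts(transcripts, truth, cfg)
    hp_tags = gen_hairpin_tags(hairpins, truth, cfg)
    return SyntheticDataset(
        cfg, transcripts, mirnas, hairpins, truth, pare, rnaseq, hp_tags
    )


# ---------------------------------------------------------------------------
# plain-text output


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as FASTA/GFF3/TSV files; returns the path map."""
    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["transcripts"] = outdir / "transcripts.fa"
    dio.write_fasta(
        paths["transcripts"],
        [(t.transcript_id, t.sequence) for t in ds.transcripts],
    )
    paths["gff"] = outdir / "genes.gff3"
    dio.write_gff3(paths["gff"], ds.transcripts)
    paths["mirnas"] = outdir / "mirnas.fa"
    dio.write_fasta(paths["mirnas"], sorted(ds.mirnas.items()))
    paths["hairpins_fa"] = outdir / "hairpins.fa"
    dio.write_fasta(
        paths["hairpins_fa"], [(h.hairpin_id, h.sequence) for h in ds.hairpins]
    )
    paths["hairpins_tsv"] = outdir / "hairpins.tsv"
    dio.write_hairpin_table(paths["hairpins_tsv"], ds.hairpins)
    for (cond, rep), tags in ds.pare.items():
        key = f"pare_{cond}_{rep}"
        paths[key] = outdir / f"{key}.fa"
        dio.write_tag_fasta(paths[key], tags)
    paths["hairpin_tags"] = outdir / "pare_hairpin.fa"
    dio.write_tag_fasta(paths["hairpin_tags"], ds.hairpin_tags)
    paths["rnaseq"] = outdir / "rnaseq_counts.tsv"
    flat = ds.rnaseq.copy()
    flat.columns = [f"{c}_{r}" for c, r in flat.columns]
    flat.to_csv(paths["rnaseq"], sep="\t", index_label="gene_id")
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_targets"] = outdir / "truth_targets.tsv"
    ds.truth.targets.to_csv(paths["truth_targets"], sep="\t", index=False)
    paths["truth_hairpins"] = outdir / "truth_hairpins.tsv"
    ds.truth.hairpins.to_csv(paths["truth_hairpins"], sep="\t", index=False)
    return paths
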