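"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import pytest

from degradome_kit.models import TranscriptModel
from degradome_kit.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_genes=60,
        n_mirnas=5,
        n_planted_targets=15,
        pare_depth=20_000,
        rnaseq_depth=60_000,
        n_hairpins=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture()
def toy_transcript() -> TranscriptModel:
    seq = (
        "GGGTTTCCCAAGGTTACGATCGATCGTAGCTAGCATGCA"  # 5'UTR filler
        + "ATG" + "GCTGCAGCT" * 10 + "TAA"  # CDS
        + "TTTACGTACGTTGCAACGGATCCTAGGATCCGTTGCAA"  # 3'UTR filler
    )
    n = len(seq)
    return TranscriptModel(
        transcript_id="toy.1",
        gene_id="toy",
        sequence=seq,
        utr5=(1, 39),
        cds=(40, 39 + 96),
        utr3=(136, n),
        intron_count=2,
    )
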