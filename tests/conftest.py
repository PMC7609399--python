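"""Shared fixtures: small synthetic communities and pipeline runs.

The expensive full-scale pipeline runs are session-scoped so the
acceptance-style checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from segvirome.community import (
    CommunitySpec,
    TaxonSpec,
    VirusSpec,
    build_genomes,
    lichen_community_spec,
)


def make_virus(
    name: str = "V1",
    segment_lengths: list[int] | None = None,
    motif5: str = "ACGTACGTACGTACGTACGTACGTACGTAC",
    motif3: str = "TTGGCCAATTGGCCAATTGGCCAATTGGCC",
    divergence: float = 0.0,
    abundance: float = 1.0,
    is_major: bool = True,
    panel_id: str = "RdRp_Partitiviridae_1",
) -> VirusSpec:
    segment_lengths = segment_lengths or [1700, 500]
    return VirusSpec(
        name=name,
        n_segments=len(segment_lengths),
        segment_lengths=segment_lengths,
        terminal_motif_5p=motif5,
        terminal_motif_3p=motif3,
        within_motif_divergence=divergence,
        has_rdrp_on_segment=0,
        relative_abundance=abundance,
        is_major=is_major,
        rdrp_panel_id=panel_id,
    )


def make_spec(viruses: list[VirusSpec], n_ds: int = 2000, n_ss: int = 500, seed: int = 0, **kw) -> CommunitySpec:
    defaults = dict(
        background_taxa=[
            TaxonSpec("Leca", "Lecanoromycetes", 0.7, reference_id="SSU_Lecanoromycetes_1"),
            TaxonSpec("Treb", "Trebouxiophyceae", 0.3, reference_id="SSU_Trebouxiophyceae_1"),
        ],
        dsrna_class_fractions={"rRNA": 0.05, "major_virus": 0.85, "minor_virus": 0.0, "other": 0.10},
        ssrna_class_fractions={"rRNA": 0.90, "major_virus": 0.02, "minor_virus": 0.0, "other": 0.08},
        n_read_pairs_dsrna=n_ds,
        n_read_pairs_ssrna=n_ss,
        seed=seed,
    )
    defaults.update(kw)
    return CommunitySpec(viruses=viruses, **defaults)


@pytest.fixture(scope="session")
def small_spec() -> CommunitySpec:
    v1 = make_virus("V1")
    v2 = make_virus(
        "V2",
        segment_lengths=[1650, 450],
        motif5="GGATCCGGATCCGGATCCGGATCCGGATCC",
        motif3="CAGTTACAGTTACAGTTACAGTTACAGTTA",
        panel_id="RdRp_Totiviridae_1",
    )
    return make_spec([v1, v2], seed=11)


@pytest.fixture(scope="session")
def small_genomes(small_spec):
    return build_genomes(small_spec, small_spec.seed)


@pytest.fixture(scope="session")
def lichen_run():
    """Full-scale default-community pipeline run (the study conditions)."""
    from segvirome.pipeline import run_pipeline

    spec = lichen_community_spec(seed=1)
    return run_pipeline(spec, 1)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
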