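import numpy as np
import pytest

from plantmir.preprocess import annotate_tags, clean_and_collapse, map_perfect, merge_tag_sets
from plantmir.seqtools import read_fasta
from plantmir.simulate import (
    SimulationConfig,
    build_genome_with_hairpins,
    simulate_degradome_library,
    simulate_small_rna_libraries,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def default_sim():
    """One fully simulated study (seed 1) shared by read-level tests."""
    cfg = SimulationConfig(seed=1)
    genome_fa, truth, gff = build_genome_with_hairpins(cfg)
    control, drought = simulate_small_rna_libraries(genome_fa, truth, cfg)
    transcripts_fa = simulate_transcriptome(truth, cfg)
    degradome_fq = simulate_degradome_library(transcripts_fa, truth, cfg)
    return {
        "config": cfg,
        "genome_fa": genome_fa,
        "genome": read_fasta(genome_fa),
        "truth": truth,
        "gff": gff,
        "control": control,
        "drought": drought,
        "transcripts_fa": transcripts_fa,
        "transcripts": read_fasta(transcripts_fa),
        "degradome": degradome_fq,
    }


@pytest.fixture(scope="session")
def annotated_tags(default_sim):
    """Cleaned, collapsed, mapped and annotated tags for the default study."""
    cfg = default_sim["config"]
    control = clean_and_collapse(default_sim["control"], cfg.adapter, library="control")
    drought = clean_and_collapse(default_sim["drought"], cfg.adapter, library="drought")
    tags = merge_tag_sets(control, drought)
    map_perfect(tags, default_sim["genome"])
    annotate_tags(tags, default_sim["gff"], {})
    return tags


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
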