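import numpy as np
import pytest

import recruitplot as rp


def make_hit(
    query_id="r1",
    subject_id="gA",
    percent_identity=99.0,
    alignment_length=200,
    query_start=1,
    query_end=200,
    subject_start=1000,
    subject_end=1199,
    bitscore=300.0,
    evalue=0.0,
    query_length=200,
    **kw,
):
    return rp.AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=percent_identity,
        alignment_length=alignment_length,
        query_start=query_start,
        query_end=query_end,
        subject_start=subject_start,
        subject_end=subject_end,
        bitscore=bitscore,
        evalue=evalue,
        query_length=query_length,
        **kw,
    )


@pytest.fixture
def hit_factory():
    return make_hit


@pytest.fixture(scope="session")
def community_bundle():
    """Seeded 5-species community: config, reference, truth, short+long reads.

    Session-scoped because the simulation is the most expensive fixture.
    """
    cfg = rp.default_community(7, depth_bases=1_500_000, genome_length=30_000)
    ref, truth = rp.make_reference(cfg)
    short_reads, long_reads, truth = rp.fragment_and_read(ref, cfg, truth)
    return cfg, ref, truth, short_reads, long_reads


@pytest.fixture(scope="session")
def toy_reference():
    """Two ~15% divergent 20 kb genomes with sequences, for aligner tests."""
    rng = np.random.default_rng(123)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    codes_a = rng.integers(0, 4, 20_000, dtype=np.uint8)
    mask = rng.random(codes_a.size) < 0.15
    codes_b = codes_a.copy()
    codes_b[mask] = (codes_b[mask] + rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)) % 4
    return rp.ReferenceDB(
        [
            rp.Genome("gA", "SpeciesA", sequence=bases[codes_a].tobytes().decode()),
            rp.Genome("gB", "SpeciesB", sequence=bases[codes_b].tobytes().decode()),
        ]
    )
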