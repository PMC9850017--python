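import numpy as np
import pandas as pd
import pytest

from invadiv import synthdata
from invadiv.datatypes import ClusterMap, GeneFragment, GenotypeMatrix


@pytest.fixture(scope="session")
def default_sim():
    """One dataset from the packaged paper-like scenario (fixed seed)."""
    return synthdata.simulate_dataset(synthdata.default_paper_like_scenario(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A faster, smaller scenario for unit-level checks."""
    cfg = synthdata.ScenarioConfig(seed=5, n_genes=25, n_microsat=5)
    return synthdata.simulate_dataset(cfg)


def make_gm(dosage, transcripts=None, positions=None, sample_prefix="s",
            ref="A", alt="G", gq=None, dp=None):
    """Hand-rolled GenotypeMatrix from a (samples x sites) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    transcripts = transcripts or ["tx1"] * m
    positions = positions or list(range(1, m + 1))
    sites = pd.DataFrame(
        {"transcript": transcripts, "pos": positions,
         "ref": [ref] * m, "alt": [alt] * m}
    )
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        sites=sites, dosage=dosage,
        gq=None if gq is None else np.asarray(gq, dtype=np.float32),
        dp=None if dp is None else np.asarray(dp, dtype=np.float32),
    )


def make_fragment(name="geneA", transcript="tx1", seq="ATGTTAGGATCC",
                  frame_offset=0):
    return GeneFragment(
        gene_name=name, transcript_id=transcript,
        intervals=[(1, len(seq))], frame_offset=frame_offset, coding_seq=seq,
    )


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def frag_factory():
    return make_fragment


@pytest.fixture
def two_cluster_map():
    def _make(gm, split=None):
        n = gm.n_samples
        split = split if split is not None else n // 2
        return ClusterMap(
            {s: ("A" if i < split else "B") for i, s in enumerate(gm.sample_ids)}
        )

    return _make
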