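import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barcodegap.seqio import AlignedLocus, SpecimenRecord

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)


@pytest.fixture
def two_species_metadata():
    """Two species x two specimens plus an outgroup."""
    recs = [
        SpecimenRecord("a1", "A", "native"),
        SpecimenRecord("a2", "A", "native"),
        SpecimenRecord("b1", "B", "non-native"),
        SpecimenRecord("b2", "B", "non-native"),
        SpecimenRecord("out1", "Outgroup sp.", "outgroup"),
    ]
    return {r.specimen_id: r for r in recs}


@pytest.fixture
def tiny_locus(two_species_metadata):
    """20-site alignment: a1==a2; b's differ from a's at 4 transversions
    and from each other at 1 transition."""
    m = two_species_metadata
    return AlignedLocus("toy", [
        (m["a1"], "AAAAAAAAAACCCCCCCCCC"),
        (m["a2"], "AAAAAAAAAACCCCCCCCCC"),
        (m["b1"], "CCAAAAAAAAAACCCCCCCC"),
        (m["b2"], "CCAAAAAAAAAACCCCCCCT"),
    ])


@pytest.fixture
def metadata_tsv(tmp_path, two_species_metadata):
    from barcodegap.seqio import write_metadata

    path = tmp_path / "metadata.tsv"
    write_metadata(two_species_metadata, path)
    return path
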