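import pytest
from hypothesis import settings

from annokit.simulate import LocusBundle, SyntheticLocusSpec, generate_locus

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def simple_locus() -> LocusBundle:
    """One plus-strand three-exon locus shared by read-only tests."""
    return generate_locus(SyntheticLocusSpec(seed=42))


@pytest.fixture(scope="session")
def two_isoform_locus() -> LocusBundle:
    """A locus with a full-length -PA and an exon-skipping -PB isoform."""
    return generate_locus(
        SyntheticLocusSpec(seed=7, exon_lengths=(90, 120, 75), skip_exon_isoform=2)
    )


@pytest.fixture(scope="session")
def cascade_locus() -> LocusBundle:
    """Multi-exon locus whose first exon ends in G, so truncating its donor
    boundary by one nucleotide produces a GG donor and a downstream
    frameshift cascade."""
    for seed in range(1000):
        bundle = generate_locus(
            SyntheticLocusSpec(
                seed=seed,
                exon_lengths=(120, 90, 150, 87, 120),
                intron_lengths=(60, 55, 70, 48),
            )
        )
        cds = bundle.cds[bundle.model.isoform_name]
        if cds[119] == "G":  # last base of exon 1
            return bundle
    raise RuntimeError("no suitable seed found")
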