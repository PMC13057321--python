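import pathlib

import pytest
from hypothesis import HealthCheck, settings

import repshape as rs
from repshape.io import DSegment, JSegment, SegmentLibrary, VSegment

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIXTURES = pathlib.Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def default_library():
    return rs.load_default_library()


@pytest.fixture(scope="session")
def toy_library():
    """The 3V/2D/3J toy library printed in tests/fixtures/toy_segments.tsv."""
    return rs.read_segment_library(FIXTURES / "toy_segments.tsv")


@pytest.fixture(scope="session")
def small_library():
    """2 V / 1 D / 2 J library for exhaustive pgen enumeration."""
    return SegmentLibrary(
        [VSegment("V1", "TRBV1", "TGTGCCAGC"), VSegment("V2", "TRBV2", "TGCGCCTCA")],
        [DSegment("D1", "GGGACA")],
        [JSegment("J1", "GCTTTCTTT", 3), JSegment("J2", "TACACCTTC", 6)],
    )


@pytest.fixture(scope="session")
def forced_library():
    """Single-scenario library: one V, one D, one J with no deletion slack."""
    return SegmentLibrary(
        [VSegment("V1", "TRBV1", "TGTGCC")],
        [DSegment("D1", "GGG")],
        [JSegment("J1", "TTTTTC", 0)],
    )


@pytest.fixture(scope="session")
def cohorts(default_library):
    """10 preterm-like + 10 adult-like simulated samples at study depth."""
    pre = rs.simulate_cohort(default_library, "preterm_like", 10,
                             n_rearrangements=3000, n_umis=4500, seed=11)
    adu = rs.simulate_cohort(default_library, "adult_like", 10,
                             n_rearrangements=3000, n_umis=4500, seed=22)
    return pre, adu
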