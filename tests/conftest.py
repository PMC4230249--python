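import pytest

from seriomap.genotypes import CrossFamily, MarkerGenotypes, to_backcross
from seriomap.simulate import SimMapConfig, simulate_cross


def make_marker(marker_id, dam, sire, calls):
    """Compact MarkerGenotypes builder: alleles as 'a/b' strings, calls as
    'a/c' strings or None."""
    def pair(s):
        if s is None:
            return None
        a, b = s.split("/")
        return tuple(sorted((a, b)))

    return MarkerGenotypes(marker_id, pair(dam), pair(sire), tuple(pair(c) for c in calls))


@pytest.fixture
def small_family():
    return CrossFamily("dam", "sire", ("p1", "p2", "p3", "p4"))


@pytest.fixture(scope="session")
def study_scale_cross():
    """One full-scale simulated cross under the study conditions: 24
    chromosomes, 29 markers each, 90 progeny, 0.5% genotyping error, 2%
    missing data.  Session-scoped because several analyses reuse it."""
    cfg = SimMapConfig(
        n_chromosomes=24,
        markers_per_chromosome=29,
        n_progeny=90,
        error_rate=0.005,
        missing_rate=0.02,
        seed=0,
    )
    family, markers, truth = simulate_cross(cfg)
    vectors = [to_backcross(m, "dam") for m in markers]
    return family, markers, truth, vectors
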