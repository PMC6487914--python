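import numpy as np
import pytest

from msel.cohort import MultiSourceCohort, SourceSpec, Subject, smartphone_pd_spec


@pytest.fixture(scope="session")
def tiny_spec() -> SourceSpec:
    """Four-source layout with tiny feature counts for hand-built examples."""
    return smartphone_pd_spec({"tapping": 2, "walking": 3, "voice": 2, "memory": 1})


def make_subject(spec: SourceSpec, sid: str, label: int, sources, rng=None, shift=0.0) -> Subject:
    rng = rng or np.random.default_rng(abs(hash(sid)) % (2**31))
    data = {}
    for src in sources:
        p = len(spec.feature_names[src])
        data[src] = rng.standard_normal(p) + shift * label
    return Subject(id=sid, label=label, source_data=data)


def make_cohort(spec: SourceSpec, patterns: list[tuple[str, int, list[str]]], seed=0) -> MultiSourceCohort:
    """Build a cohort from (id, label, sources) triples with random features."""
    rng = np.random.default_rng(seed)
    return MultiSourceCohort(
        spec=spec, subjects=[make_subject(spec, sid, lab, srcs, rng) for sid, lab, srcs in patterns]
    )


@pytest.fixture
def mixed_cohort(tiny_spec) -> MultiSourceCohort:
    """14 subjects covering complete, partial and single-source patterns."""
    pats = [
        ("c1", 1, ["tapping", "walking", "voice", "memory"]),
        ("c2", 0, ["tapping", "walking", "voice", "memory"]),
        ("c3", 1, ["tapping", "walking", "voice", "memory"]),
        ("p1", 1, ["tapping", "walking", "voice"]),
        ("p2", 0, ["voice", "memory"]),
        ("p3", 1, ["tapping"]),
        ("p4", 0, ["memory"]),
        ("p5", 1, ["walking", "voice"]),
        ("p6", 0, ["tapping", "walking"]),
        ("p7", 1, ["voice"]),
        ("p8", 0, ["tapping", "voice"]),
        ("p9", 1, ["walking"]),
        ("p10", 0, ["tapping", "walking", "memory"]),
        ("p11", 1, ["tapping", "voice", "memory"]),
    ]
    return make_cohort(tiny_spec, pats)
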