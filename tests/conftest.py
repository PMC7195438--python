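import numpy as np
import pytest

from teloprobe.diffscan import GroupedProfiles
from teloprobe.reactivity import compute_raw_reactivity, normalize_2_8
from teloprobe.synthetic import MapSimConfig, simulate_map_counts


def grouped_profiles(config: MapSimConfig, min_coverage: int = 1000):
    """Simulate count tables and turn them into grouped normalized profiles."""
    tables, truth = simulate_map_counts(config)
    by_sample = {}
    for t in tables:
        by_sample.setdefault((t.group_id, t.replicate_id), {})[t.channel] = t
    groups = {}
    for (group, _rep), channels in sorted(by_sample.items()):
        prof = normalize_2_8(
            compute_raw_reactivity(channels["+"], channels["-"], min_coverage=min_coverage)
        )
        groups.setdefault(group, []).append(prof)
    return GroupedProfiles(groups=groups), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
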