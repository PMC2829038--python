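import pytest
from hypothesis import HealthCheck, settings

from sprpath.moves import is_one_spr_apart
from sprpath.simulate import bfs_oracle
from sprpath.tree import are_isomorphic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def assert_valid_path(path, source, target, distance):
    """A result path must be a chain of single-SPR steps from source to target.

    Uses the brute-force one-step oracle on small trees and the collapse-based
    one-SPR test on large ones.
    """
    assert len(path) == distance + 1
    assert are_isomorphic(path[0], source)
    assert are_isomorphic(path[-1], target)
    small = source.n_leaves <= 10
    for x, y in zip(path, path[1:]):
        if small:
            assert bfs_oracle(x, y, max_d=1) == 1
        else:
            assert is_one_spr_apart(x, y)


@pytest.fixture
def check_path():
    return assert_valid_path
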