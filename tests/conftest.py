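import pytest

from foragefit import GambleSetConfig, WalkSpec, enumerate_walk, generate_gamble_set


@pytest.fixture(scope="session")
def small_gamble_set():
    """80 pairs (20 per combo): enough structure, fast to fit."""
    return generate_gamble_set(GambleSetConfig(pairs_per_combo=20), seed=11)


@pytest.fixture(scope="session")
def study_gamble_set():
    """Full-size 480-pair set matching the task design."""
    return generate_gamble_set(seed=7)


@pytest.fixture(scope="session")
def example_dist():
    """Endpoint distribution of the worked random-walk example
    (x0=2, n=3, g=3, p=0.4)."""
    return enumerate_walk(WalkSpec(2, 3, 3, 0.4))


def brute_force_walk(x0: int, n: int, g: int, p: float) -> dict[int, float]:
    """Independent oracle: enumerate all 2^n full success/failure sequences
    with their product probabilities; the walker freezes at zero once
    absorbed but the sequence probability is always the full product."""
    import itertools

    mass: dict[int, float] = {}
    for seq in itertools.product([True, False], repeat=n):
        x = x0
        weight = 1.0
        for success in seq:
            weight *= p if success else (1.0 - p)
            if x > 0:
                x = x + (g - 1) if success else x - 1
        mass[x] = mass.get(x, 0.0) + weight
    return mass


@pytest.fixture(scope="session")
def walk_oracle():
    return brute_force_walk
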