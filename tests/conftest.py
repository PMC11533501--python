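import numpy as np
import pytest

from kinetomech import simgen


@pytest.fixture
def symmetric_flipflop():
    """Noisy symmetric flip-flop trajectory (d = 37 nm both ways)."""
    cfg = simgen.FlipFlopConfig(
        displacement_by_direction=(("toward_plus", 37.0), ("toward_minus", 37.0)),
        n_cycles=6,
        seed=11,
    )
    return simgen.make_flipflop_trajectory(cfg), cfg


def child_seed(seed: int, tag: str) -> int:
    """Mirror of the pipeline's deterministic seed derivation."""
    import zlib

    mixed = np.random.SeedSequence([seed, zlib.crc32(tag.encode())])
    return int(mixed.generate_state(1)[0] % (2**31))
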