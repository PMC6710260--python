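import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from conkatseq.debarcode import SubpoolScheme
from conkatseq.simulator import PRESETS, simulate_run

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_scheme(**overrides) -> SubpoolScheme:
    """A deterministic toy scheme: 24 column and 16 row 8-mers."""
    rng = np.random.default_rng(20_240_101)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def draw(n):
        out = []
        while len(out) < n:
            cand = rng.integers(0, 4, 8)
            if all(int(np.sum(cand != prev)) >= 3 for prev in out):
                out.append(cand)
        return [bases[c].tobytes().decode() for c in out]

    kwargs = dict(
        plate_id="P1",
        column_barcodes={b: i for i, b in enumerate(draw(24))},
        row_barcodes={b: i for i, b in enumerate(draw(16))},
        primer_len=12,
        total_len=42,
        spacer=0,
        domain_type="AD",
    )
    kwargs.update(overrides)
    return SubpoolScheme(**kwargs)


@pytest.fixture(scope="session")
def toy_scheme() -> SubpoolScheme:
    return make_scheme()


@pytest.fixture(scope="session")
def small_run():
    """The desk-scale direct-mode study condition: 384 x 1000 library, seed 1."""
    return simulate_run(dataclasses.replace(PRESETS["small"], seed=1))


@pytest.fixture(scope="session")
def tiny_read_run():
    """A read-mode-sized simulation (96 subpools) with error-free reads."""
    return simulate_run(dataclasses.replace(PRESETS["tiny"], seed=3))
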