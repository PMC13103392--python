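import dataclasses

import numpy as np
import pytest

from hitquant import (HalfSibSimConfig, VialCount, generate_half_sib,
                      paired_mi_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_vials():
    """Two paired units in one group, hand-checkable counts."""
    return [
        VialCount("s", "B1", "g1", "u1", "hit", 50, 10),
        VialCount("s", "B1", "g1", "u1", "sham", 50, 2),
        VialCount("s", "B1", "g1", "u2", "hit", 40, 0),
        VialCount("s", "B1", "g1", "u2", "sham", 40, 4),
    ]


@pytest.fixture(scope="session")
def halfsib_dataset():
    """One study-scale half-sib dataset with its truth (shared across tests)."""
    cfg = HalfSibSimConfig(seed=11)
    vials, truth = generate_half_sib(cfg)
    records, warnings = paired_mi_records(vials)
    return cfg, vials, records, truth


def make_halfsib_mi(cfg: HalfSibSimConfig):
    vials, _ = generate_half_sib(cfg)
    records, _ = paired_mi_records(vials)
    return records


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
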