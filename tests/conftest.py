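import pytest

from dcache_ai2 import (FamilyGenConfig, ReferencePocketModel, build_column_map,
                        generate_family)


@pytest.fixture(scope="session")
def ref():
    return ReferencePocketModel()


@pytest.fixture(scope="session")
def small_family(ref):
    """A 200-row synthetic family with planted matches and ground truth."""
    cfg = FamilyGenConfig(n_seqs=200, full_match_fraction=0.1,
                          partial_match_fraction=0.1, seed=42)
    return generate_family(cfg)


@pytest.fixture(scope="session")
def small_cmap(small_family, ref):
    family, _, _ = small_family
    return build_column_map(family, ref)
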