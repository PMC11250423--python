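import numpy as np
import pytest

import bindmaps as bm


@pytest.fixture(scope="session")
def small_mixed_bank():
    """Mixed-class glyph bank: class-dependent luminance, 10 per class."""
    return bm.build_bank(bm.mixed_bank_config(n_per_class=10, seed=7))


@pytest.fixture(scope="session")
def small_tops_bank():
    """Tops glyph bank: class-independent luminance, 20 per class."""
    return bm.build_bank(bm.tops_bank_config(n_per_class=20, seed=7))


@pytest.fixture(scope="session")
def tiny_dataset(small_mixed_bank):
    """A very small original-variant dataset for fast pipeline tests."""
    bank = bm.build_bank(bm.mixed_bank_config(n_per_class=10, obj_size=10,
                                              seed=3))
    cfg = bm.DatasetConfig(variant="original", n_images=72, canvas_size=36,
                           seed=3)
    return bank, cfg, bm.generate_dataset(bank, cfg)


@pytest.fixture(scope="session")
def tiny_net_config():
    return bm.NetworkConfig(conv_blocks=((4, 3),), dense_widths=(24,),
                            common_dense_widths=(16,), batch_size=32,
                            max_epochs=3, patience=3, seed=11)


def make_record(identity="t-shirt", level="low", orientation="up",
                location=1, exemplar_id=0, lum_value=10.0):
    return bm.ObjectRecord(exemplar_id, identity, lum_value, level,
                           orientation, location)


@pytest.fixture
def record_factory():
    return make_record
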