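import numpy as np
import pytest

from immunomargin.geometry import partition_rois
from immunomargin.synthesize import TissueGeometryConfig, generate_tissue


@pytest.fixture(scope="session")
def disc_section():
    """Disc tumor, radius 2000 um, 10 um pixels, partitioned at 500 um."""
    cfg = TissueGeometryConfig(
        width_um=6400.0, height_um=6400.0, pixel_size_um=10.0, radius_um=2000.0
    )
    section = generate_tissue(cfg)
    section.partition = partition_rois(section)
    return section


@pytest.fixture(scope="session")
def small_section():
    """Small disc tumor for fast pipeline-level tests (20 um pixels)."""
    cfg = TissueGeometryConfig(
        width_um=4800.0, height_um=4800.0, pixel_size_um=20.0, radius_um=1200.0
    )
    section = generate_tissue(cfg)
    section.partition = partition_rois(section)
    return section


@pytest.fixture
def rng():
    return np.random.default_rng(20240604)
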