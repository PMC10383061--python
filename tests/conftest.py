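import numpy as np
import pytest

from lfiaquant import (
    GrayImage,
    PipelineConfig,
    StripSpec,
    ThresholdParams,
    generate_strip,
)


@pytest.fixture
def params() -> ThresholdParams:
    return ThresholdParams()


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def blank_strip():
    """Zero-concentration strip with default texture, seed 42."""
    return generate_strip(StripSpec(concentration=0.0, seed=42))


@pytest.fixture
def dark_strip():
    """High-concentration strip: all four lines clearly visible."""
    return generate_strip(StripSpec(concentration=1000.0, seed=7))


def painted_strip(
    width=600,
    height=200,
    background=220,
    bands=(),
):
    """A noise-free strip with flat-topped rectangular lines.

    ``bands`` is a sequence of (head, end, depth): columns head..end
    (inclusive) are darkened by ``depth`` gray levels.
    """
    px = np.full((height, width), background, dtype=np.int64)
    for head, end, depth in bands:
        px[:, head : end + 1] -= depth
    return GrayImage(np.clip(px, 0, 255))
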