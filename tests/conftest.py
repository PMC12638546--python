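"""Shared fixtures: the four reference blink videos and their analyses.

Rendering and analyzing the standard fixtures dominates suite runtime, so
both are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

import blinkscope as bs


@pytest.fixture(scope="session")
def fixtures():
    """name -> (FrameSequence, GroundTruth) for the four blink patterns."""
    return bs.standard_fixtures()


@pytest.fixture(scope="session")
def analyzed(fixtures):
    """name -> PipelineResult of the full analysis chain."""
    return {name: bs.analyze_sequence(seq) for name, (seq, _) in fixtures.items()}


@pytest.fixture(scope="session")
def noise_free_blink():
    """A clean complete blink plus ground truth (renderer determinism base)."""
    spec = bs.BlinkSpec(
        pre_open_ms=150, close_ms=116, closed_ms=30, open_ms=216,
        post_open_ms=150, amplitude=1.0,
    )
    scene = bs.SceneSpec(noise_sd=0.0, seed=0)
    return bs.render_blink_video([spec], scene, fps=240.0)


def frames_per_ms(fps: float = 240.0) -> float:
    return fps / 1000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
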