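"""Shared fixtures for the ansq test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ansq.protocol import ResponseTrace
from ansq.synthetic import canonical_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def squat_map_template():
    """A smooth unimodal canonical template (gamma pulse, 60 s epoch)."""
    return canonical_template("squat", "squat", "MAP")


def make_trace(template, y=None, **meta):
    """Wrap an array as a ResponseTrace on a template's grid."""
    meta.setdefault("test", template.test)
    meta.setdefault("epoch", template.epoch)
    meta.setdefault("modality", template.modality)
    if y is None:
        y = template.f.copy()
    return ResponseTrace(t=template.t.copy(), y=np.asarray(y, float), **meta)
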