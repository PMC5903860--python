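"""Shared fixtures: thin wrappers over the package's synthetic generators."""

from __future__ import annotations

import pytest

from memflex import synthetic_data

PATCH_TEMPLATE = synthetic_data.patch_template()


def make_defect_patch(window=None, depth: float = 0.15, **kwargs):
    """Constructed interface patch; returns (topo, frame, ref, planted_area)."""
    topo, frame, ref, truth = synthetic_data.make_defect_patch(
        window=window, depth=depth, **kwargs)
    return topo, frame, ref, truth.defects.get("area", 0.0)


@pytest.fixture(scope="session")
def defect_free_patch():
    return make_defect_patch(window=None)
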