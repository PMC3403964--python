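"""Shared fixtures.

The headline two-class experiment (140 cells, co-localization 0.3 vs 0.7,
seed 42) is expensive (~20 s), so it is generated once per session and
shared between the texture-distribution tests and the acceptance suite.
Unit tests use a smaller cell geometry for speed.
"""

import numpy as np
import pytest

from cocluster import (
    ImageSet,
    SyntheticClassSpec,
    generate_dataset,
    rwc_per_cell,
    run_pipeline,
    segment_cells,
)
from cocluster.segmentation import iter_cells
from cocluster.texture import feature_table_from_cells

HEADLINE_SEED = 42


def small_spec(**kwargs):
    """A compact cell class for fast unit tests."""
    defaults = dict(n_cells=3, cell_radius_px=16.0, puncta_count=30,
                    marker_puncta_count=15, puncta_sigma_px=1.5, seed=0)
    defaults.update(kwargs)
    return SyntheticClassSpec(**defaults)


@pytest.fixture(scope="session")
def headline_experiment():
    """End-to-end run of the two-class discrimination experiment.

    Two classes share every texture parameter and differ only in the
    fraction of protein puncta duplicated into the marker channel (0.3 vs
    0.7).  Segmentation, feature extraction, RWC and clustering all use the
    package's own pipeline.
    """
    specs = [
        SyntheticClassSpec(n_cells=70, coloc_fraction=0.3,
                           seed=HEADLINE_SEED, class_label="low"),
        SyntheticClassSpec(n_cells=70, coloc_fraction=0.7,
                           seed=HEADLINE_SEED, class_label="high"),
    ]
    channel_a, channel_b, truth_labels, truths = generate_dataset(specs)
    image = ImageSet(channels={"protein": channel_a, "marker": channel_b})
    mask = segment_cells(channel_a)
    cells = list(iter_cells(image, mask))
    table = feature_table_from_cells(
        cells, class_labels=[t.class_label for t in truths]
    )
    rwc_by_cell = {cid: res.rwc_1 for cid, res in rwc_per_cell(image, mask)}
    result, report = run_pipeline(table, rwc_by_cell, k=2, seed=HEADLINE_SEED)
    return {
        "channel_a": channel_a,
        "channel_b": channel_b,
        "truth_labels": truth_labels,
        "truths": truths,
        "image": image,
        "mask": mask,
        "table": table,
        "rwc_by_cell": rwc_by_cell,
        "result": result,
        "report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
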