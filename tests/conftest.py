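"""Shared fixtures: synthetic ROIs, small cohorts, and the session-scoped
end-to-end pipeline run used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from voitex import EngineConfig, PhantomSpec, ROIVoxelSet
from voitex.radiomics import discretize


def make_roi(
    intensities: np.ndarray,
    mask: np.ndarray | None = None,
    spacing=(1.0, 1.0, 1.0),
    label: int = 1,
) -> ROIVoxelSet:
    """Build an ROIVoxelSet straight from a dense intensity block."""
    intensities = np.asarray(intensities, dtype=float)
    if mask is None:
        mask = np.ones(intensities.shape, dtype=bool)
    coords = np.argwhere(mask)
    return ROIVoxelSet(
        label=label,
        intensities=intensities[mask],
        coords=coords,
        spacing=spacing,
        grid_shape=intensities.shape,
    )


def random_small_roi(seed: int, max_side: int = 5, ng: int = 4):
    """A random ROI of shape <= 5x5x5 with a random (nonempty) mask,
    discretized to `ng` levels. Returns (roi, discretized)."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    intensities = rng.random(shape) * 100
    roi = make_roi(intensities, mask)
    d = discretize(roi, EngineConfig(n_bins=ng))
    return roi, d


@pytest.fixture(scope="session")
def engine_config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture(scope="session")
def default_phantom_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A 6-scan cohort (2 control / 1 prodromal / 3 pd) on disk."""
    from voitex import CohortSpec, generate_cohort

    outdir = tmp_path_factory.mktemp("tiny_cohort")
    cohort = CohortSpec(n_per_class=(2, 1, 3), seed=11)
    manifest = generate_cohort(cohort, outdir)
    return manifest


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full default pipeline (91 scans, 64^3 grids) run once per session."""
    from voitex import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = PipelineConfig(n_per_class=(20, 7, 64), master_seed=7)
    return run_pipeline(config, outdir)
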