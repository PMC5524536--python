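import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pedmut.genotype_calling import GenotypeCallSet
from pedmut.pipeline import PipelineConfig, run_full_pipeline
from pedmut.site_filtering import ANNOTATION_NAMES
from pedmut.synthetic_pedigree import simulate_reference

settings.register_profile(
    "pedmut",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("pedmut")


@pytest.fixture(scope="session")
def small_panel():
    return simulate_reference(length=50_000, repeat_fraction=0.2, seed=11)


def make_callset(
    gt,
    depth=60,
    alt_frac=None,
    positions=None,
    annotations=None,
    label="A",
    individuals=None,
):
    """Hand-crafted call set: gt is (n_individuals, n_sites); alt counts are
    derived from genotype unless alt_frac (same shape) is given."""
    gt = np.asarray(gt, dtype=np.int8)
    n_ind, n_sites = gt.shape
    if individuals is None:
        individuals = ("father", "mother") + tuple(f"off{i+1:02d}" for i in range(n_ind - 2))
    depth_arr = np.full(gt.shape, depth, dtype=np.int64)
    if alt_frac is None:
        alt_frac = np.choose(np.maximum(gt, 0), [0.0, 0.5, 1.0])
        alt_frac[gt == -1] = 0.0
    alt_count = np.rint(depth_arr * np.asarray(alt_frac)).astype(np.int64)
    if positions is None:
        positions = np.arange(n_sites) * 100 + 50
    if annotations is None:
        annotations = pd.DataFrame({n: np.zeros(n_sites) for n in ANNOTATION_NAMES})
    return GenotypeCallSet(
        label=label,
        individuals=tuple(individuals),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.zeros(n_sites, dtype=np.uint8),
        alt=np.full(n_sites, 3, dtype=np.uint8),
        gt=gt,
        gq=np.full(gt.shape, 99.0),
        depth=depth_arr,
        alt_count=alt_count,
        annotations=annotations,
    )


@pytest.fixture(scope="session")
def small_run():
    """One modest full-pipeline run shared across tests (300 kb, 30 DNMs)."""
    cfg = PipelineConfig(length=300_000, n_spikes=200).with_seed(5)
    cfg = dataclasses.replace(cfg, sim=dataclasses.replace(cfg.sim, n_dnms=30))
    return run_full_pipeline(cfg)
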