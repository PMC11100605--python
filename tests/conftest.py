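import numpy as np
import pytest

from isletfish.simulate import SimParams, default_pipeline_config, generate_field


def small_sim_params(**overrides) -> SimParams:
    """A fast-to-render field: ~8 cells on 256x256, one gene."""
    kw = dict(
        field_shape_px=(256, 256),
        n_cells=8,
        nucleus_radius_px_range=(6.0, 8.0),
        cell_expansion_truth_px=10.0,
        beta_fraction=0.5,
        gene_means_beta={"G": 12.0},
        gene_means_nonbeta={"G": 3.0},
        nuclear_fraction_true={"G": 0.3},
        n_autofluor_outliers=1,
        seed=11,
    )
    kw.update(overrides)
    return SimParams(**kw)


@pytest.fixture(scope="session")
def small_field():
    """(stack, nucleus_mask, cell_mask, ground_truth) for a small field."""
    return generate_field(small_sim_params())


@pytest.fixture(scope="session")
def small_field_run(small_field):
    """Full pipeline result on the small field."""
    from isletfish.pipeline import run_pipeline

    stack, _, _, gt = small_field
    cfg = default_pipeline_config(gt.params)
    return run_pipeline(stack, cfg), gt


@pytest.fixture
def rng():
    return np.random.default_rng(0)
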