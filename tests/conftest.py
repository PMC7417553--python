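import numpy as np
import pytest

import simguided as sg


@pytest.fixture(scope="session")
def tiny_layout():
    """2 submodalities x 3 features, 10 subjects."""
    return sg.DatasetLayout(
        modalities={
            "cognition": {"reaction_time": ("rt_mean", "rt_sd", "rt_lapses")},
            "MRI": {"volumes": ("vol_hippocampus", "vol_thalamus",
                                "vol_caudate")},
        },
        n_subjects=10,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_layout):
    """Fully observed simulated cohort on the tiny layout."""
    spec = sg.LatentCohortSpec(layout=tiny_layout, variant="cluster",
                               snr_db=10.0, seed=7)
    return sg.generate_cohort(spec)


@pytest.fixture()
def holed_cohort(tiny_cohort):
    """tiny_cohort with one hole punched at (subject 4, rt_mean)."""
    ds = sg.MultimodalDataset(
        layout=tiny_cohort.layout,
        blocks={k: v.copy() for k, v in tiny_cohort.blocks.items()},
        outcomes=tiny_cohort.outcomes.copy(),
        covariates=tiny_cohort.covariates.copy(),
        meta=dict(tiny_cohort.meta),
    )
    ds.blocks["reaction_time"].iloc[4, 0] = np.nan
    return ds


@pytest.fixture(scope="session")
def bench_cohort():
    """120-subject, 4-submodality cluster cohort at +10 dB."""
    spec = sg.LatentCohortSpec(layout=sg.small_layout(120, 4, 3),
                               variant="cluster", snr_db=10.0, seed=3)
    return sg.generate_cohort(spec)
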