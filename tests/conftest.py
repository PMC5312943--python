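import numpy as np
import pandas as pd
import pytest

from macdev import ModuleSpec, SampleDesign, TimecourseSpec, generate_timecourse


@pytest.fixture
def design() -> SampleDesign:
    return SampleDesign.default_timecourse()


@pytest.fixture
def planted_timecourse():
    """One 40-gene module at 8-fold induction among 200 genes (seeded)."""
    spec = TimecourseSpec(
        n_genes=200,
        module_specs=[ModuleSpec(40, "24h", 8.0)],
        noise_sd=0.3,
        seed=11,
    )
    matrix, truth = generate_timecourse(spec)
    return spec, matrix, truth


@pytest.fixture
def three_module_spec():
    def make(seed: int) -> TimecourseSpec:
        return TimecourseSpec(
            n_genes=200,
            module_specs=[
                ModuleSpec(60, "6h", 8.0),
                ModuleSpec(60, "24h", 8.0),
                ModuleSpec(60, "48h", 8.0),
            ],
            noise_sd=0.3,
            seed=seed,
        )

    return make


@pytest.fixture
def tiny_rel(design) -> pd.DataFrame:
    """Small deterministic relative-expression matrix (already 0h-centred)."""
    rng = np.random.default_rng(7)
    rel = pd.DataFrame(
        rng.normal(0, 1, (12, 14)),
        index=[f"g{i}" for i in range(12)],
        columns=design.sample_ids,
    )
    return rel.sub(rel[design.condition_samples("0h")].mean(axis=1), axis=0)
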