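import numpy as np
import pytest

from crnets import (
    ExpressionMatrix,
    SynthConfig,
    compute_coexpression,
    simulate_study,
)

# The standard evaluation study: generator defaults (600 genes, 60 TFs,
# 400 conditions, six 10-gene modules, rho=0.8, 1% background edges, half
# the modules planted in all three networks), one fixed seed.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    return simulate_study(SynthConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_coexpr(study):
    return compute_coexpression(study.expression)


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        values=rng.standard_normal((12, 30)),
        gene_ids=[f"g{i:02d}" for i in range(12)],
        condition_ids=[f"c{j:02d}" for j in range(30)],
    )
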