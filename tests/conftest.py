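import warnings

import pytest

from reosig import io as rio
from reosig import screen, signature as sig, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """The default-scale synthetic cohort (~1000 genes, 30 planted pairs, n=342)."""
    config = simulate.SyntheticConfig(seed=1)
    expr, clinical, truth = simulate.generate_cohort(config)
    return expr, clinical, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for unit tests that only need realistic structure."""
    config = simulate.SyntheticConfig(
        n_genes=120,
        n_stage1=20,
        n_stage2_noctx=60,
        n_stage2_ctx=15,
        n_stage34=25,
        n_planted_pairs=5,
        n_planted_de_extra=5,
        seed=11,
    )
    expr, clinical, truth = simulate.generate_cohort(config)
    return expr, clinical, truth


@pytest.fixture(scope="session")
def recovery_run(default_cohort):
    """Full discovery chain on the default cohort, computed once per session."""
    expr, clinical, truth = default_cohort
    nonmet = rio.select_cohort(clinical, {"I"}, ctx="any")
    met = rio.select_cohort(clinical, {"III", "IV"}, ctx="any")
    de = screen.de_genes(expr, met, nonmet, fdr_threshold=0.1)
    reversals = screen.reversed_pairs(expr, met, nonmet, de.index, fdr_threshold=0.2)
    cohort = rio.select_cohort(clinical, {"II"}, ctx=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates = sig.prognostic_pairs(expr, clinical, reversals, 0.01, samples=cohort)
    chosen = sig.forward_select(candidates, expr, clinical, samples=cohort)
    return {
        "de": de,
        "reversals": reversals,
        "cohort": cohort,
        "candidates": candidates,
        "signature": chosen,
    }
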