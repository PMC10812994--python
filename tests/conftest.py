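import numpy as np
import pytest
from hypothesis import settings

from neurotx import synthetic
from neurotx.association import dual_threshold, extract_t_at_samples, mass_correlation
from neurotx.synthetic import (default_truth, generate_expression_samples,
                               make_smooth_stat_map)
from neurotx.transcriptome import prepare_expression

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mask():
    """Default desk-scale analysis mask (24x28x24 at 3 mm)."""
    return synthetic.make_mask(seed=1)


@pytest.fixture(scope="session")
def small_mask():
    return synthetic.make_mask(shape=(16, 16, 16), seed=2)


@pytest.fixture(scope="session")
def screen_run(mask):
    """One full expression screen under default conditions, shared by tests.

    Generates probe-level samples coupled to a smooth reference map, runs
    the nine-step preprocessing, and correlates every gene with the map.
    """
    truth = default_truth(seed=10)
    ref_map = make_smooth_stat_map(mask, seed=11)
    expr = generate_expression_samples(mask, truth, ref_map, 300, seed=12)
    matrix, assignment = prepare_expression(expr.sample_set,
                                            expr.current_map, mask)
    tvec = extract_t_at_samples(ref_map, matrix.regions)
    assoc = dual_threshold(mass_correlation(matrix, tvec))
    return {
        "truth": truth, "ref_map": ref_map, "expr": expr,
        "matrix": matrix, "assignment": assignment, "assoc": assoc,
    }
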