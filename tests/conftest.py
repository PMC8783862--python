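import numpy as np
import pandas as pd
import pytest

from testoscreen import (
    ATHLETE_MAF,
    CONTROL_MAF,
    CohortSpec,
    VariantSpec,
    panel_with_mafs,
    reported_associations,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def athlete_panel():
    return panel_with_mafs(ATHLETE_MAF)


@pytest.fixture(scope="session")
def control_panel():
    return panel_with_mafs(CONTROL_MAF)


@pytest.fixture(scope="session")
def reported_stats():
    return reported_associations()


@pytest.fixture
def small_genotypes(athlete_panel):
    """40-individual deterministic genotype table over the five-variant panel."""
    return simulate_genotypes(CohortSpec(n=40, panel=athlete_panel, seed=7))


def hwe_score_brute_force(mafs):
    """Exhaustive 3^m enumeration of the allele-count score distribution."""
    from itertools import product

    mafs = list(mafs)
    out = np.zeros(2 * len(mafs) + 1)
    for geno in product((0, 1, 2), repeat=len(mafs)):
        prob = 1.0
        for g, p in zip(geno, mafs):
            q = 1.0 - p
            prob *= (q * q, 2.0 * p * q, p * p)[g]
        out[sum(geno)] += prob
    return out
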