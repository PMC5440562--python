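"""Shared fixtures: the synthetic study bundle, built once per session."""

from __future__ import annotations

import pytest

from budnet.coexpression import coexpr_matrix
from budnet.de import DECriteria, call_de, intersect_de
from budnet.synthetic import (
    SyntheticSpec,
    gen_compendium,
    gen_experiments,
    gen_genesets,
    gen_promoters,
)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: compendium, contrasts, gene sets, promoters."""
    spec = SyntheticSpec(seed=1)
    comp, truth = gen_compendium(spec)
    experiments = gen_experiments(spec, truth)
    genesets = gen_genesets(spec, truth)
    promoters = gen_promoters(spec, truth)
    return {
        "spec": spec,
        "compendium": comp,
        "truth": truth,
        "experiments": experiments,
        "genesets": genesets,
        "promoters": promoters,
    }


@pytest.fixture(scope="session")
def similarity(bundle):
    """Mutual-rank similarity over the default compendium."""
    return coexpr_matrix(bundle["compendium"], "mutual_rank")


@pytest.fixture(scope="session")
def seed_list(bundle):
    """Three-contrast intersection seed list on the default fixture."""
    criteria = DECriteria(significance_threshold=0.05)
    return intersect_de([call_de(t, criteria) for t in bundle["experiments"]])
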