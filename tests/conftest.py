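import numpy as np
import pandas as pd
import pytest

from ltsp_sig import ExpressionMatrix, GeneSet, GeneSetCollection


def make_matrix(values, gene_ids=None, sample_ids=None, conditions=None,
                scale="linear"):
    """Build an ExpressionMatrix from a 2-D array with generated IDs."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_s)]
    if conditions is None:
        conditions = {s: "C" for s in sample_ids}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        condition_of=dict(conditions), scale=scale)


def make_collection(sets, provenance="test"):
    """Collection from {set_id: [genes]}."""
    coll = GeneSetCollection(provenance=provenance)
    for sid, members in sets.items():
        coll.add(GeneSet(set_id=sid, name=sid, members=tuple(members)))
    return coll


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def three_condition_matrix(rng):
    """Log10-scale 60x13 matrix with the LL/STS/LTSsn 5/3/5 design."""
    samples, cond = [], {}
    for label, n in (("LL", 5), ("STS", 3), ("LTSsn", 5)):
        for r in range(1, n + 1):
            s = f"{label}_{r}"
            samples.append(s)
            cond[s] = label
    vals = rng.normal(1.0, 0.4, size=(60, len(samples)))
    return make_matrix(vals, sample_ids=samples, conditions=cond, scale="log10")
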