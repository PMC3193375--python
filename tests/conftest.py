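import pytest

from refogbench.model import GeneRecord, PredictedOGSet, RefOG, RefOGSet


def G(gene_id: str, species: str = "hs") -> GeneRecord:
    return GeneRecord(gene_id, species)


def make_refog(refog_id, gene_ids, species="hs"):
    return RefOG(refog_id, frozenset(G(g, species) for g in gene_ids))


def make_predictions(ogs: dict, method="toy", species="hs") -> PredictedOGSet:
    return PredictedOGSet(method, {
        og: [g if isinstance(g, GeneRecord) else G(g, species) for g in genes]
        for og, genes in ogs.items()
    })


@pytest.fixture
def toy_refog():
    """A four-member family used across the gene/group-level examples."""
    return make_refog("R1", ["a", "b", "c", "d"])


@pytest.fixture
def toy_split_predictions():
    """Members spread over three OGs with at most one alien each."""
    return make_predictions({"OG1": ["a", "b", "x"], "OG2": ["c", "y"], "OG3": ["d"]})


@pytest.fixture
def identity_setup():
    """Predictions that reproduce the RefOGs exactly."""
    refogs = RefOGSet([
        make_refog("R1", ["a", "b", "c"], "hs"),
        make_refog("R2", ["d", "e"], "dm"),
    ])
    preds = PredictedOGSet("perfect", {r.refog_id: set(r.members) for r in refogs})
    return refogs, preds
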