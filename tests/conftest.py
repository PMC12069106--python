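import pytest

from fccmap import generate_universe, paper_marginals, run_pipeline_on_bundle
from fccmap.chem_registry import ChemicalRecord, IdentifierSet


def make_ids(cas=None, inchikey=None, smiles=None, names=()):
    return IdentifierSet.from_strings(cas=cas, inchikey=inchikey, smiles=smiles,
                                      names=names)


def make_chem(chem_id, cas=None, inchikey=None, smiles=None, names=(),
              in_fccdb=True, in_fccmigex=False, is_mixture=False):
    return ChemicalRecord(
        chem_id=chem_id,
        identifiers=make_ids(cas, inchikey, smiles, names or (chem_id,)),
        is_mixture=is_mixture,
        in_fccdb=in_fccdb,
        in_fccmigex=in_fccmigex,
    )


@pytest.fixture(scope="session")
def paper_bundle():
    return generate_universe(paper_marginals(seed=1))


@pytest.fixture(scope="session")
def paper_result(paper_bundle):
    return run_pipeline_on_bundle(paper_bundle)
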