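from __future__ import annotations

import pytest

from genestrata import fixtures as fx


@pytest.fixture(scope="session")
def bundle():
    """The standard recovery fixture: 50 species, depth <= 8, 100 genes."""
    return fx.gen_bundle(seed=20240915, n_species=50, max_depth=8, n_genes=100)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    fx.write_bundle(bundle, out)
    return out


@pytest.fixture(scope="session")
def toy_primates():
    """The four-species example table used for comparison-set selection."""
    from genestrata.taxonomy import TaxonomicLineage, TaxonomyTable

    rows = {
        "hsa": ("Root", "Hominidae", "Homo", "H.sapiens"),
        "ptr": ("Root", "Hominidae", "Pan", "P.troglodytes"),
        "ggo": ("Root", "Hominidae", "Gorilla", "G.gorilla"),
        "mmu": ("Root", "Muridae", "Mus", "M.musculus"),
    }
    return TaxonomyTable(
        {code: TaxonomicLineage(code, taxa) for code, taxa in rows.items()}
    )
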