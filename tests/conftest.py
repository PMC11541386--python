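import io

import pytest

from metid import chem_registry as chem
from metid import feature_matching as fm
from metid import spectral_synthesis as spec
from metid import synthetic_data as sim


@pytest.fixture(scope="session")
def parents():
    return chem.load_parents()


@pytest.fixture(scope="session")
def parents_by_id(parents):
    return {p.id: p for p in parents}


@pytest.fixture(scope="session")
def reactions():
    return chem.load_reactions()


@pytest.fixture(scope="session")
def reactions_by_id(reactions):
    return {r.id: r for r in reactions}


@pytest.fixture(scope="session")
def cmp_candidates(parents, reactions):
    return chem.enumerate_cmp(parents, reactions)


@pytest.fixture(scope="session")
def parent_spectra_pos():
    return sim.parent_merged_spectra("positive")


@pytest.fixture(scope="session")
def library_pos(cmp_candidates, parent_spectra_pos, parents):
    """Positive-mode library over the scan-range-filtered CMP candidates,
    with the parents' own records included."""
    kept = chem.mz_cutoff_filter(cmp_candidates, 800.0)
    parent_records = [parent_spectra_pos[p.id] for p in parents]
    return spec.build_library(
        kept, parent_spectra_pos, polarity="positive", extra_records=parent_records
    )


def feature_records_from_table(table, metadata):
    """Round a simulated table through the TSV parser."""
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return fm.read_feature_table(buf, metadata)
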