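import pytest

from npstpipe import amplicon, synthetic


@pytest.fixture(scope="session")
def panel():
    """3 PABA-family + 5 background references, fixed seed."""
    return synthetic.generate_reference_panel(3, 5, 7)


@pytest.fixture(scope="session")
def library(panel):
    paba = [r.id for r in panel if r.is_paba_family]
    other = [r.id for r in panel if not r.is_paba_family]
    planted = {
        "poolA": paba[:2] + other[:2],
        "poolB": [paba[2]] + other[2:],
    }
    return synthetic.plant_amplicons(
        panel, 2, 6, planted, seed=3, insert_len=2000
    )


@pytest.fixture(scope="session")
def clean_reads(library):
    """Error-free reads, 3 per planted template, flattened."""
    per_pool = synthetic.simulate_reads(library, 0.0, seed=5, reads_per_template=3)
    return [(rid, seq) for pool in sorted(per_pool) for rid, seq in per_pool[pool]]


@pytest.fixture(scope="session")
def assigned_reads(library, clean_reads):
    assigned, unassigned = amplicon.debarcode_and_trim(clean_reads, library.barcode_map())
    assert not unassigned
    return assigned


@pytest.fixture(scope="session")
def npsts(assigned_reads):
    return amplicon.cluster_npst(assigned_reads)


@pytest.fixture(scope="session")
def lap_arch():
    return synthetic.lap_architecture_fixture()
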