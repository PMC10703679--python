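import numpy as np
import pytest

from scicomb.config import PipelineConfig
from scicomb.fixtures import FixtureSpec, make_genome_fixture, make_read_fixture


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def genome():
    """Toy annotation with overlap motifs; -> (ann, chrom_lengths, seqs, empty_zone)."""
    return make_genome_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def read_fixture(tmp_path_factory):
    """Full read bundle with planted 1- and 2-error barcodes.

    -> dict(dir, ann, truth, rt, lig, layout)
    """
    d = tmp_path_factory.mktemp("reads")
    spec = FixtureSpec(seed=11, n_cells=8, reads_per_pseudocell=50,
                       barcode_error1_frac=0.10, barcode_error2_frac=0.05)
    ann, truth, rt, lig, layout = make_read_fixture(spec, d)
    return {"dir": d, "ann": ann, "truth": truth, "rt": rt, "lig": lig,
            "layout": layout, "spec": spec}
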