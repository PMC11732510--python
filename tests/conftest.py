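import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mimicscan.analog import mouse_mog35_55
from mimicscan.motifs import build_motifs

MOG_MOUSE = "MEVGWYRSPFSRVVHLYRNGK"
P3 = "TTLSFYRPPFLRVRRPFYIIF"
SCRAMBLED = "KGNRYLHVVRSFPSRYWGVEM"


@pytest.fixture(scope="session")
def epitope():
    return mouse_mog35_55()


@pytest.fixture(scope="session")
def motif_set(epitope):
    return build_motifs(epitope)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The packaged-style smoke fixture, built once per session."""
    from mimicscan.simulate import make_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    truth = make_fixture(outdir, seed=7)
    return outdir, truth
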