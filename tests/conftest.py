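import numpy as np
import pytest

from tipselect.pipeline import generate_bundle
from tipselect.rankprod import ScoredGeneList


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """One synthetic study bundle shared by the I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(out, seed=11)


@pytest.fixture
def toy_lists():
    """Three small congruent lists: gene 'a' tops every dataset."""
    rng = np.random.default_rng(3)
    genes = list("abcdefgh")
    lists = []
    for d in range(3):
        scores = rng.permutation(len(genes)).astype(float)
        scores[0] = len(genes) + 1  # 'a' always wins
        lists.append(ScoredGeneList(f"d{d}", genes, scores))
    return lists
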