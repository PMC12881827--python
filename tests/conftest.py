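import numpy as np
import pytest
from hypothesis import settings

import motifgrammar as mg

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_hot_motifs():
    """Three short deterministic motifs (one-hot columns)."""

    def one_hot(seq):
        m = np.zeros((len(seq), 4))
        for i, c in enumerate(seq):
            m[i, "ACGT".index(c)] = 1.0
        return m

    ms = mg.MotifSet(alphabet=mg.DNA)
    ms.add(mg.Motif("motif_0", one_hot("ACG")))
    ms.add(mg.Motif("motif_1", one_hot("TTT")))
    ms.add(mg.Motif("motif_2", one_hot("GATA")))
    return ms


@pytest.fixture
def simulated_motifs(rng):
    spec = mg.MotifSimSpec(n_motifs=8, len_min=10, len_max=10, alpha=1.0)
    return mg.simulate_motifs(spec, rng)


@pytest.fixture
def overlapping_grammar():
    """Three groups with shared motifs, self-favoring group transitions."""
    members = {
        "group_0": ["motif_0", "motif_1", "motif_2"],
        "group_1": ["motif_2", "motif_3", "motif_4", "motif_5"],
        "group_2": ["motif_1", "motif_6", "motif_7"],
    }
    cond = [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]
    return mg.build_grammar(members, group_conditional=cond)
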