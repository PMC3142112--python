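import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from noeturn.builder import CapSpec, build_extended
from noeturn.noe import NoeSet, infer_turns, restraints_from_noes, turn_hbond_restraints
from noeturn.synth import fixture_paper


@pytest.fixture(scope="session")
def paper():
    return fixture_paper()


@pytest.fixture(scope="session")
def s42(paper):
    return paper.sequence_full


@pytest.fixture(scope="session")
def s21(paper):
    return paper.sequence_truncated


@pytest.fixture()
def fast_refinement_kwargs():
    """Short protocol preserving the 3:5:1 equilibration:production:snapshot
    ratio (and hence the 5-snapshot structure) at reduced step counts."""
    return dict(
        equil_steps=6000,
        prod_steps=10000,
        snapshot_interval=2000,
        tau_update=1000,
        temperature_schedule=((0, 500.0), (6000, 300.0)),
    )


@pytest.fixture(scope="session")
def second_turn_inputs(paper):
    """Extended 34-41 fragment plus its restraints (NOE + turn hydrogen
    bond), the refinement input for the D-Pro hairpin."""
    seq = paper.sequence_full
    frag = seq.subsequence(34, 41)
    conf = build_extended(frag, CapSpec())
    window = NoeSet(
        [p for p in paper.noes_full if 34 <= p.residue_i <= 41 and 34 <= p.residue_j <= 41]
    )
    noe_restraints = restraints_from_noes(window, seq)
    hyp = [h for h in infer_turns(paper.noes_full, seq) if h.start == 36][0]
    return conf, noe_restraints + turn_hbond_restraints(hyp), noe_restraints
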