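import numpy as np
import pytest

from numtscope.core import Locus, Role, SequenceRecord


def make_record(
    rid: str,
    residues: str,
    taxon: str = "Acrididae",
    locus: Locus = Locus.COI,
    role: Role = Role.CLONE,
) -> SequenceRecord:
    return SequenceRecord(id=rid, taxon=taxon, locus=locus, role=role,
                          residues=residues)


@pytest.fixture
def rng():
    return np.random.default_rng(20140508)


@pytest.fixture
def record_factory():
    return make_record
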