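import numpy as np
import pytest

from cglamella import topology as topo
from cglamella.frames import CGFrame


@pytest.fixture(scope="session")
def registry():
    return topo.default_registry()


@pytest.fixture(scope="session")
def mixture_spec():
    """CER:CHOL:FFA 1:0.5:1, the ternary composition of the study."""
    return topo.CompositionSpec(
        {"CER_NS": 1.0, "CHOL": 0.5, "FFA_C24": 1.0}, n_lipids=1800, n_leaflets=6
    )


def make_rod_frame(directions, n_beads=5, spacing=0.4, box=(20.0, 20.0, 20.0),
                   species="FFA_C24", origin_z=10.0):
    """Straight-chain 'lipids' (HEAD + TAIL beads) along given directions.

    A minimal frame for director/tilt/S2 tests; bead counts need not
    match the full template (directors only use tail-role beads).
    """
    directions = np.asarray(directions, dtype=float)
    positions, types, mids, specs = [], [], [], []
    for m, d in enumerate(directions):
        d = d / np.linalg.norm(d)
        anchor = np.array([5.0 + 0.01 * m, 5.0, origin_z])
        positions.append(anchor)
        types.append("HEAD")
        mids.append(m)
        specs.append(species)
        for j in range(n_beads):
            positions.append(anchor + (j + 1) * spacing * d)
            types.append("TAIL")
            mids.append(m)
            specs.append(species)
    return CGFrame(
        positions=np.array(positions),
        bead_types=np.array(types),
        mol_ids=np.array(mids),
        mol_species=np.array(specs),
        box=np.array(box),
    )
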