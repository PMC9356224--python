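import numpy as np
import pytest

from ionperm import synth, umbrella
from ionperm.core import Bead, Frame


@pytest.fixture
def flat_potential():
    """No z-structure, no radial confinement: free diffusion."""
    return synth.GroovePotential(z_terms=(), radial_k=0.0)


@pytest.fixture
def confined_flat_potential():
    """Flat along z, harmonic in XY (keeps walkers near the axis)."""
    return synth.GroovePotential(z_terms=(), radial_k=2.0)


@pytest.fixture
def open_pg():
    return synth.preset_potential("open_pg")


@pytest.fixture
def small_windows():
    return umbrella.generate_windows(-2.5, 2.5, 0.25)


def make_frame(time, ion_xyz, ref_z=0.0, partners=()):
    """Frame with an ion, a reference at (0, 0, ref_z), and partner beads.

    ``partners`` is an iterable of (partner_id, xyz) pairs.
    """
    beads = [
        Bead("K+", "ion", np.asarray(ion_xyz, dtype=float), radius=1.33,
             charge=1.0),
        Bead("REF", "reference", np.array([0.0, 0.0, ref_z]), radius=1.0),
    ]
    for pid, xyz in partners:
        beads.append(Bead(pid, "partner", np.asarray(xyz, dtype=float),
                          radius=1.0))
    return Frame(time=time, beads=beads)


# Printed per-partner interacting-frame counts for the worked-example
# window (center Z0 = -1.5 A, 4500 total frames), with their published
# percentages.
TABLE1_COUNTS = {
    "POPG 909": (3732, 82.9),
    "THR 381": (953, 21.2),
    "VAL 337": (135, 3.0),
    "SER 382": (53, 1.2),
    "TYR 513": (37, 0.8),
    "THR 340": (18, 0.4),
    "LEU 336": (9, 0.2),
    "PHE 440": (2, 0.04),
}
TABLE1_TOTAL = 4500
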