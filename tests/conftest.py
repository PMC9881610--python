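import numpy as np
import pytest

from fragdock import (
    AtomClassAssignment,
    Conformer,
    FragMapGrid,
    FragMapSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_grid(rng):
    """A random 5x5x5 GFE grid with non-trivial origin and spacing."""
    vals = rng.uniform(-5.0, 3.0, size=(5, 5, 5))
    return FragMapGrid(
        map_type="GENN",
        origin=np.array([-2.0, 1.0, 0.5]),
        spacing=np.array([1.0, 0.5, 2.0]),
        values=vals,
    )


@pytest.fixture
def flat_maps():
    """Congruent flat maps (one per default type) with value -1 everywhere."""
    types = ("GENN", "GEND", "GENA", "MAMN", "ACEO")
    grids = {
        t: FragMapGrid(
            map_type=t,
            origin=np.full(3, -15.0),
            spacing=np.ones(3),
            values=np.full((31, 31, 31), -1.0),
        )
        for t in types
    }
    return FragMapSet(grids)


def make_point_ligand(label="GENN", coords=(0.0, 0.0, 0.0)):
    """Single-heavy-atom ligand with a chosen classification label."""
    from fragdock import Atom, Ligand

    element = {"GENN": "C", "GEND": "O", "GENA": "O", "MAMN": "N", "ACEO": "O"}[label]
    charge = {"MAMN": 1, "ACEO": -1}.get(label, 0)
    n_h = {"GEND": 1}.get(label, 0)
    lig = Ligand(
        name="pt",
        atoms=[Atom(element=element, formal_charge=charge, coords=np.asarray(coords, float), n_hydrogens=n_h)],
        bonds=[],
    )
    return lig, AtomClassAssignment([label]), Conformer.from_ligand(lig)
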