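import numpy as np
import pytest

import mofsans as m
from mofsans.models import atoms_to_scatterers
from mofsans.sld import ContrastCondition


@pytest.fixture(scope="session")
def gfp():
    """Synthetic GFP-scale monomer (session-wide, deterministic)."""
    return m.synthetic_gfp(seed=0)


@pytest.fixture(scope="session")
def gfp_scatterers(gfp):
    cond = ContrastCondition(fD=0.5, deuterated_solute=True)
    return atoms_to_scatterers(gfp, cond)


@pytest.fixture(scope="session")
def mesocage_chain():
    return m.build_lattice({"chain": 4, "radius": 30.0, "spacing": 51.5})


@pytest.fixture
def sphere_curve():
    """Noise-free sphere (R = 30 A) form-factor curve with nominal 1% sigma."""
    q = np.geomspace(0.005, 0.5, 260)
    I = m.sphere_form(30.0, q)
    return m.Curve1D(q, I, 0.01 * I, meta={"R": "30"})


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
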