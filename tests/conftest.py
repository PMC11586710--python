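import numpy as np
import pytest

from sugausspb import PBParams, default_params, make_born_ion, make_two_atom
from sugausspb.structio import Atom, Solute


@pytest.fixture
def born_ion():
    return make_born_ion(1.0, 2.0)


@pytest.fixture
def two_atom():
    return make_two_atom()


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def tripeptide_like():
    """Small deterministic multi-atom solute with mixed charges and radii,
    roughly the size/packing of a capped tripeptide backbone."""
    rng = np.random.default_rng(20240817)
    n = 12
    pos = np.cumsum(rng.normal(scale=1.2, size=(n, 3)), axis=0)
    pos -= pos.mean(axis=0)
    radii = rng.uniform(1.2, 1.9, size=n)
    charges = rng.uniform(-0.6, 0.6, size=n)
    charges -= charges.mean()  # net-neutral
    charges[0] += 1.0  # give it a net charge of +1
    atoms = tuple(
        Atom(f"X{i}", tuple(pos[i]), float(charges[i]), float(radii[i])) for i in range(n)
    )
    return Solute(atoms=atoms, id="tripeptide_like")


def numeric_gradient(f, point, h=1e-5):
    """Central-difference gradient of a scalar function of a 3-point."""
    point = np.asarray(point, dtype=float)
    out = np.zeros(3)
    for ax in range(3):
        dp = np.zeros(3)
        dp[ax] = h
        out[ax] = (f(point + dp) - f(point - dp)) / (2 * h)
    return out
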