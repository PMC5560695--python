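import numpy as np
import pytest

from saconf import FixtureSpec, default_model, write_ensemble


@pytest.fixture(scope="session")
def model():
    """The bundled 27-letter alphabet model."""
    return default_model()


def planted_spec(seed: int = 7) -> FixtureSpec:
    """The reference planted-ground-truth ensemble: 20 conformers of a
    60-residue chain (helix/loop/strand/helix), one 8-residue flexible
    window at residues 25-32 with sigma = 1.0 A, and two point
    mutations away from the window."""
    return FixtureSpec(
        n_conformers=20,
        length=60,
        seed=seed,
        segments=[((1, 18), "helix"), ((19, 34), "loop"),
                  ((35, 50), "strand"), ((51, 60), "helix")],
        flexible_windows=[((25, 32), 1.0)],
        mutations=[(3, 10, "W"), (7, 50, "H")],
        het_groups=["LIG"],
    )


@pytest.fixture(scope="session")
def planted_ensemble(tmp_path_factory):
    """Planted ensemble written to disk: (directory, truth dict)."""
    out = tmp_path_factory.mktemp("planted")
    truth = write_ensemble(planted_spec(), out)
    return out, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
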