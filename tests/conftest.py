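import numpy as np
import pytest

import cgsaxs as cg


@pytest.fixture(scope="session")
def default_grid():
    return cg.QGrid()


@pytest.fixture(scope="session")
def fixture_atoms():
    """A 30-residue synthetic all-atom structure."""
    return cg.generate_structure(cg.FixtureSpec(n_residues=30, seed=123))


@pytest.fixture(scope="session")
def recovery_results():
    """Parameter-recovery outcomes at noise levels {1, 0.3, 0} (shared:
    the estimation sweep over 3 x 51 bins is the expensive step)."""
    import warnings
    config = cg.MCMCConfig(iterations=600_000, burn_in=300_000, thinning=100,
                           seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return cg.experiments.recovery_experiment(
            noise_levels=(1.0, 0.3, 0.0), seed=1, config=config)


@pytest.fixture(scope="session")
def trained_two_body_table():
    """Two-body form-factor table trained against all-atom oracle curves.

    Shared by the validation and decoy-recognition tests; training is the
    expensive step, so it runs once per session.
    """
    return cg.experiments.train_fixture_table("two", seed=1)


def random_bead_structure(rng, n_beads, granularity="one", spread=30.0):
    """Random coarse structure with labels drawn from the alphabet."""
    alphabet = cg.BeadAlphabet.for_granularity(granularity)
    labels = rng.choice(alphabet.labels, size=n_beads)
    beads = [
        cg.CoarseBead(str(lbl), rng.uniform(-spread, spread, 3), i)
        for i, lbl in enumerate(labels)
    ]
    return cg.CoarseStructure(beads, granularity)


def random_table(rng, granularity="one", grid=None, f_max=40.0):
    grid = grid or cg.QGrid()
    alphabet = cg.BeadAlphabet.for_granularity(granularity)
    values = rng.uniform(0.0, f_max, (len(alphabet.labels), grid.n_bins))
    return cg.FormFactorTable(alphabet, grid, values)


def naive_debye_per_particle(coords, factors, q):
    """Independent Debye evaluation: explicit accumulation per source
    particle with a where-based sinc (no shared code with the production
    kernel).  ``factors`` has shape (M, Q)."""
    coords = np.asarray(coords, float)
    M = coords.shape[0]
    out = np.zeros(q.size)
    for i in range(M):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        for k, qk in enumerate(q):
            x = qk * d
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.where(np.abs(x) < 1e-12, 1.0, np.sin(x) / x)
            out[k] += factors[i, k] * (factors[:, k] * s).sum()
    return out


def naive_debye_scalar(coords, factors, q):
    """Fully scalar double-loop Debye sum (small M only)."""
    import math
    M = len(coords)
    out = []
    for qk in q:
        total = 0.0
        for i in range(M):
            for j in range(M):
                d = math.dist(coords[i], coords[j])
                x = qk * d
                s = 1.0 if abs(x) < 1e-12 else math.sin(x) / x
                total += factors[i] * factors[j] * s
        out.append(total)
    return np.array(out)
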