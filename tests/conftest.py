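"""Shared fixtures and geometry builders."""

from __future__ import annotations

import numpy as np
import pytest

from dyescreen import DimerFrame, make_dipole


def frame_from_axes(u_m, u_n, R=1.26, l_m=1.0, l_n=1.0, mu_m=15.35, mu_n=15.35,
                    separation=(1.0, 0.0, 0.0)):
    """Dimer frame with unit axes u_m/u_n and centers R apart along `separation`."""
    u_m = np.asarray(u_m, float)
    u_n = np.asarray(u_n, float)
    sep = np.asarray(separation, float)
    sep = sep / np.linalg.norm(sep)
    c_m = np.zeros(3)
    c_n = R * sep
    return DimerFrame(
        dye_m=make_dipole(c_m - 0.5 * l_m * u_m, c_m + 0.5 * l_m * u_m, mu_m),
        dye_n=make_dipole(c_n - 0.5 * l_n * u_n, c_n + 0.5 * l_n * u_n, mu_n),
    )


def random_frame(rng, R_range=(0.5, 5.0), l_range=(0.01, 1.5), mu=10.0):
    """Random valid dimer frame (uniform axes, random separation direction)."""
    def unit(v):
        return v / np.linalg.norm(v)

    u_m = unit(rng.normal(size=3))
    u_n = unit(rng.normal(size=3))
    sep = unit(rng.normal(size=3))
    R = rng.uniform(*R_range)
    l_m = rng.uniform(*l_range)
    l_n = rng.uniform(*l_range)
    return frame_from_axes(u_m, u_n, R=R, l_m=l_m, l_n=l_n, mu_m=mu, mu_n=mu,
                           separation=sep)


@pytest.fixture(scope="session")
def molecule_dataset_small():
    """300-molecule noiseless dataset + precomputed features (shared)."""
    from dyescreen import featurize_table
    from dyescreen.fixtures import MoleculePrescription, gen_molecule_dataset

    presc = MoleculePrescription(
        n_molecules=300, low_fraction=0.8, noise_sigma=0.0, seed=11,
        max_chain_repeat=6,
    )
    df, truth = gen_molecule_dataset(presc)
    X, _, _ = featurize_table(df)
    X.index = df.index
    return df, truth, X


@pytest.fixture(scope="session")
def molecule_dataset_2000():
    """2000-molecule noiseless dataset + features (used by acceptance checks)."""
    from dyescreen import featurize_table
    from dyescreen.fixtures import MoleculePrescription, gen_molecule_dataset

    presc = MoleculePrescription(
        n_molecules=2000, low_fraction=0.92, noise_sigma=0.0, seed=7,
    )
    df, truth = gen_molecule_dataset(presc)
    X, _, _ = featurize_table(df)
    X.index = df.index
    return df, truth, X
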