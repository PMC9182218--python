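"""Synthetic fixtures with known ground truth.

Two generators make every stage testable without external data:

* :func:`gen_dimer_trajectory` emits a dye-dimer endpoint table whose frames
  are sampled from a prescribed mixture of orientation states (emulating the
  non-intercalated O1 / intercalated O2 structure seen in dye-DNA duplex
  simulations), together with a ground-truth sidecar.

* :func:`gen_molecule_dataset` emits a molecule table whose extinction
  coefficients are a documented monotone function of structural features
  (conjugation length, ring count, molecular weight) plus optional Gaussian
  noise, with the low/high class fraction controlled exactly.

All randomness flows from a single integer seed; equal seeds give identical
outputs.

Geometry realization
--------------------
A target absolute orientation factor t in [0, 2] is realized exactly by one
of two coplanar families (separation axis x):

* t <= 1: parallel dipoles tilted at angle theta to the separation,
  cos^2(theta) = (1 - t)/3, giving kappa = +t (t = 1 is the pure H stack,
  t = 0 the magic angle);
* t > 1: mirrored "splayed head-to-tail" dipoles at angle alpha,
  cos^2(alpha) = t - 1, giving kappa = -t (t = 2 is the collinear J dimer).

Each frame is then given a random rigid rotation and translation (which
leave kappa, R and J invariant) so generated tables are not trivially
axis-aligned.

State dispersion is prescribed directly in observable space: per frame,
|kappa| and R are drawn from (truncated) normal distributions with the
prescribed means and standard deviations and realized exactly. Isotropic
Cartesian endpoint jitter is a separate instrument-noise knob (default off
for dispersion-prescribed states, since stacking it on top of prescribed
dispersions would double-count variance); it is used to exercise the
centroid-extraction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trajectory import EndpointTable

DEFAULT_JITTER_NM = 0.05


# ---------------------------------------------------------------------------
# dimer trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatePrescription:
    """One orientation state of the mixture.

    kappa/R dispersions are realized exactly in observable space;
    jitter_sigma adds isotropic Gaussian noise to every endpoint coordinate
    on top (nm).
    """

    occupancy: float
    R_mean: float                 # nm
    kappa_mean: float             # target |kappa| in [0, 2]
    R_std: float = 0.0
    kappa_std: float = 0.0
    jitter_sigma: float = 0.0
    name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(f"occupancy must be in [0,1], got {self.occupancy}")
        if self.R_mean <= 0:
            raise ValidationError("R_mean must be positive")
        if not 0.0 <= self.kappa_mean <= 2.0:
            raise ValidationError("kappa_mean must lie in [0, 2]")
        if self.R_std < 0 or self.kappa_std < 0 or self.jitter_sigma < 0:
            raise ValidationError("dispersions must be >= 0")


@dataclass(frozen=True)
class TrajectoryPrescription:
    states: tuple[StatePrescription, ...]
    l_m: float = 1.2              # dye lengths, nm
    l_n: float = 1.2
    mu_m: float = 15.35           # Debye
    mu_n: float = 15.35
    n_frames: int = 1000
    stride_ps: float = 10.0
    seed: int = 0
    switching: str = "block"      # "block": one transition per state change
    #: optional excluded-volume floor (nm): inter-dye endpoint pairs closer
    #: than this are resampled from their state distribution. Off by default:
    #: enforcing it distorts the prescribed (kappa, R) marginals, because the
    #: marginals are sampled independently while real trajectories avoid
    #: contact through kappa-R correlation. Enable for bounded-|J| fixtures.
    min_contact_nm: float = 0.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.min_contact_nm < 0:
            raise ValidationError("min_contact_nm must be >= 0")
        if not self.states:
            raise ValidationError("at least one state required")
        total = sum(s.occupancy for s in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"occupancies must sum to 1, got {total}")
        if self.switching not in ("block", "iid"):
            raise ValidationError("switching must be 'block' or 'iid'")
        if self.l_m <= 0 or self.l_n <= 0:
            raise ValidationError("dye lengths must be positive")


def _axes_for_kappa(t: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit dipole axes realizing |kappa| = t with separation along x."""
    if t <= 1.0:
        c = np.sqrt((1.0 - t) / 3.0)
        s = np.sqrt(1.0 - c * c)
        u = np.array([c, s, 0.0])
        return u, u.copy()
    c = np.sqrt(t - 1.0)
    s = np.sqrt(1.0 - (t - 1.0))
    return np.array([c, s, 0.0]), np.array([c, -s, 0.0])


def _truncated_normal(rng, mean, std, lo, hi, size):
    """Rejection-sampled truncated normal (std may be 0)."""
    if std == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, std, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, std, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _random_rotations(rng, n):
    """n uniform random rotation matrices (quaternion method)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1)[:, None]
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )


def gen_dimer_trajectory(
    prescription: TrajectoryPrescription,
) -> tuple[EndpointTable, pd.DataFrame]:
    """Generate an endpoint table plus a ground-truth sidecar.

    The sidecar has one row per frame: state name, the exactly realized
    (pre-jitter) ``kappa_true`` (absolute) and ``R_true``, and the noiseless
    endpoint coordinates.
    """
    p = prescription
    rng = np.random.default_rng(p.seed)
    n = p.n_frames

    # assign frames to states
    if p.switching == "block":
        counts = [int(round(s.occupancy * n)) for s in p.states]
        counts[-1] = n - sum(counts[:-1])
        if counts[-1] < 0:
            raise ValidationError("occupancy rounding produced a negative block")
        state_idx = np.repeat(np.arange(len(p.states)), counts)
    else:
        state_idx = rng.choice(
            len(p.states), size=n, p=[s.occupancy for s in p.states]
        )

    kappa_true = np.empty(n)
    R_true = np.empty(n)
    for i, s in enumerate(p.states):
        m = state_idx == i
        k = int(m.sum())
        if k == 0:
            continue
        kappa_true[m] = _truncated_normal(rng, s.kappa_mean, s.kappa_std, 0.0, 2.0, k)
        R_true[m] = _truncated_normal(rng, s.R_mean, s.R_std, 0.3, np.inf, k)

    # noiseless endpoints in the canonical frame; frames whose inter-dye
    # endpoint pairs violate the excluded-volume floor are resampled
    def build(kappa, R):
        u_m, u_n = _axes_for_kappa(kappa)
        c_n = np.array([R, 0.0, 0.0])
        e = np.empty((4, 3))
        e[0] = -0.5 * p.l_m * u_m
        e[1] = +0.5 * p.l_m * u_m
        e[2] = c_n - 0.5 * p.l_n * u_n
        e[3] = c_n + 0.5 * p.l_n * u_n
        return e

    def min_inter_dye_distance(e):
        d = e[:2, None, :] - e[None, 2:, :]
        return float(np.sqrt((d**2).sum(axis=-1)).min())

    ends = np.empty((n, 4, 3))
    for f in range(n):
        s = p.states[state_idx[f]]
        e = build(kappa_true[f], R_true[f])
        tries = 0
        while min_inter_dye_distance(e) < p.min_contact_nm:
            tries += 1
            if tries > 200:
                raise ValidationError(
                    f"state {s.name or state_idx[f]} cannot satisfy the "
                    f"{p.min_contact_nm} nm contact floor"
                )
            kappa_true[f] = _truncated_normal(
                rng, s.kappa_mean, s.kappa_std, 0.0, 2.0, 1
            )[0]
            R_true[f] = _truncated_normal(rng, s.R_mean, s.R_std, 0.3, np.inf, 1)[0]
            e = build(kappa_true[f], R_true[f])
        ends[f] = e

    # random rigid motion per frame (kappa, R, J invariant)
    rot = _random_rotations(rng, n)
    trans = rng.uniform(-5.0, 5.0, size=(n, 1, 3))
    ends_clean = np.einsum("fij,faj->fai", rot, ends) + trans

    ends_noisy = ends_clean.copy()
    for i, s in enumerate(p.states):
        if s.jitter_sigma > 0:
            m = state_idx == i
            ends_noisy[m] += rng.normal(0.0, s.jitter_sigma, size=ends_noisy[m].shape)

    time = p.stride_ps * np.arange(n)
    table = EndpointTable(
        time=time,
        r_m=ends_noisy[:, 0],
        s_m=ends_noisy[:, 1],
        r_n=ends_noisy[:, 2],
        s_n=ends_noisy[:, 3],
        stride_ps=p.stride_ps,
    )
    names = [s.name or f"state{i}" for i, s in enumerate(p.states)]
    sidecar = pd.DataFrame(
        {
            "time_ps": time,
            "state": [names[i] for i in state_idx],
            "kappa_true": kappa_true,
            "R_true": R_true,
        }
    )
    for a, key in enumerate(["r_m", "s_m", "r_n", "s_n"]):
        for d, ax in enumerate("xyz"):
            sidecar[f"{key}_{ax}_clean"] = ends_clean[:, a, d]
    return table, sidecar


def cy5_o2_prescription(
    n_frames: int = 1000, seed: int = 0, jitter_sigma: float = 0.0
) -> TrajectoryPrescription:
    """Single-state fixture with the intercalated Cy5 dimer statistics
    (|kappa| = 1.35 +/- 0.22, R = 1.26 +/- 0.21 nm; mu = 15.35 D)."""
    return TrajectoryPrescription(
        states=(
            StatePrescription(
                occupancy=1.0,
                R_mean=1.26,
                R_std=0.21,
                kappa_mean=1.35,
                kappa_std=0.22,
                jitter_sigma=jitter_sigma,
                name="O2",
            ),
        ),
        l_m=1.2,
        l_n=1.2,
        mu_m=15.35,
        mu_n=15.35,
        n_frames=n_frames,
        seed=seed,
    )


def cy55_o2_prescription(
    n_frames: int = 1000, seed: int = 0, jitter_sigma: float = 0.0
) -> TrajectoryPrescription:
    """Single-state fixture with the intercalated Cy5.5 dimer statistics
    (|kappa| = 1.33 +/- 0.15, R = 1.17 +/- 0.17 nm; mu = 15.57 D; Cy5.5 is
    ~0.1 nm longer than Cy5)."""
    return TrajectoryPrescription(
        states=(
            StatePrescription(
                occupancy=1.0,
                R_mean=1.17,
                R_std=0.17,
                kappa_mean=1.33,
                kappa_std=0.15,
                jitter_sigma=jitter_sigma,
                name="O2",
            ),
        ),
        l_m=1.3,
        l_n=1.3,
        mu_m=15.57,
        mu_n=15.57,
        n_frames=n_frames,
        seed=seed,
    )


def intercalation_prescription(
    n_frames: int = 1000, seed: int = 0, o2_occupancy: float = 0.8,
    jitter_sigma: float = 0.0,
) -> TrajectoryPrescription:
    """Two-state fixture: non-intercalated O1 (R ~ 2.7 nm, |kappa| ~ 0.5)
    followed block-wise by intercalated O2 (Cy5 statistics)."""
    return TrajectoryPrescription(
        states=(
            StatePrescription(
                occupancy=1.0 - o2_occupancy,
                R_mean=2.7,
                R_std=0.15,
                kappa_mean=0.5,
                kappa_std=0.25,
                jitter_sigma=jitter_sigma,
                name="O1",
            ),
            StatePrescription(
                occupancy=o2_occupancy,
                R_mean=1.26,
                R_std=0.21,
                kappa_mean=1.35,
                kappa_std=0.22,
                jitter_sigma=jitter_sigma,
                name="O2",
            ),
        ),
        n_frames=n_frames,
        seed=seed,
    )


def write_dumbbell_pdb(table: EndpointTable, path) -> None:
    """Render an endpoint table as a multi-frame PDB of dumbbell
    pseudo-molecules (one pseudo-atom per dipole endpoint, two residues
    DYM/DYN), for exercising trajectory readers."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    u = mda.Universe.empty(
        4, n_residues=2, atom_resindex=[0, 0, 1, 1], trajectory=True
    )
    u.add_TopologyAttr("name", ["E1", "E2", "E1", "E2"])
    u.add_TopologyAttr("resname", ["DYM", "DYN"])
    u.add_TopologyAttr("resid", [1, 2])
    u.add_TopologyAttr("element", ["C", "C", "C", "C"])
    coords = np.stack([table.r_m, table.s_m, table.r_n, table.s_n], axis=1) * 10.0
    u.load_new(coords.astype(np.float32), format=MemoryReader,
               dt=table.stride_ps or 1.0)
    with mda.Writer(str(path), 4, multiframe=True) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


#: selection spec matching :func:`write_dumbbell_pdb` output
DUMBBELL_SELECTION_SPEC = {
    "dye_m_r": {"resname": "DYM", "names": ["E1"]},
    "dye_m_s": {"resname": "DYM", "names": ["E2"]},
    "dye_n_r": {"resname": "DYN", "names": ["E1"]},
    "dye_n_s": {"resname": "DYN", "names": ["E2"]},
}


# ---------------------------------------------------------------------------
# molecule datasets
# ---------------------------------------------------------------------------

# attachment order differs: _X_GROUPS are written as prefixes (last atom
# bonds to the ring), _Y_GROUPS inside parentheses (first atom bonds)
_X_GROUPS = ["O", "N", "OC", "Cl", "F", "C", "CC", "N#C", "OCC", "S"]
_Y_GROUPS = ["O", "N", "OC", "Cl", "F", "C", "CC", "C#N", "OCC", "S"]

_TEMPLATES = [
    "{x}c1ccc({chain}c2ccc({y})cc2)cc1",          # biphenyl-like polyene
    "{x}c1ccc({chain}c2ccc3cc({y})ccc3c2)cc1",    # naphthyl terminal
    "{x}c1ccc({chain}c2cc({y})ccn2)cc1",          # pyridyl terminal
]


@dataclass(frozen=True)
class MoleculePrescription:
    """Controls the synthetic molecule dataset.

    epsilon = 150000 * exp(beta * (score - cut)) + N(0, noise_sigma), with
    score a monotone structural feature combination (max carbon chain + 3 *
    aromatic rings + 0.05 * MolWt) and the cut placed so that exactly
    round(low_fraction * n) molecules fall below the 150,000 threshold.
    """

    n_molecules: int = 2000
    low_fraction: float = 0.92
    noise_sigma: float = 0.0      # M^-1 cm^-1
    seed: int = 0
    beta: float = 0.03
    max_chain_repeat: int = 25

    def __post_init__(self):
        if self.n_molecules < 10:
            raise ValidationError("need at least 10 molecules")
        if not 0.0 < self.low_fraction < 1.0:
            raise ValidationError("low_fraction must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def scaffold_library(max_chain_repeat: int = 1) -> list[str]:
    """Deduplicated canonical SMILES of the built-in scaffold family."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    seen, out = set(), []
    for template in _TEMPLATES:
        for k in range(max_chain_repeat + 1):
            chain = "C=C" * k
            for x in _X_GROUPS:
                for y in _Y_GROUPS:
                    smi = template.format(x=x, y=y, chain=chain)
                    mol = Chem.MolFromSmiles(smi)
                    if mol is None:
                        continue
                    canon = Chem.MolToSmiles(mol)
                    if canon not in seen:
                        seen.add(canon)
                        out.append(canon)
    return out


def _structure_score(mol) -> float:
    from rdkit.Chem import Descriptors, rdMolDescriptors

    from .screening import max_carbon_chain_length

    return (
        max_carbon_chain_length(mol)
        + 3.0 * rdMolDescriptors.CalcNumAromaticRings(mol)
        + 0.05 * Descriptors.MolWt(mol)
    )


def gen_molecule_dataset(
    prescription: MoleculePrescription,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a molecule table plus ground-truth sidecar.

    Returns (table, sidecar): the table has molecule_id, smiles, epsilon,
    source_label; the sidecar adds the structural score, the noiseless
    epsilon and the intended high/low label. The achieved low-class count is
    exactly round(low_fraction * n).
    """
    from rdkit import Chem

    p = prescription
    rng = np.random.default_rng(p.seed)
    library = scaffold_library(p.max_chain_repeat)
    if len(library) < p.n_molecules:
        raise ValidationError(
            f"scaffold family provides {len(library)} distinct molecules; "
            f"requested {p.n_molecules} (raise max_chain_repeat)"
        )
    picks = rng.choice(len(library), size=p.n_molecules, replace=False)
    smiles = [library[i] for i in picks]
    scores = np.array([_structure_score(Chem.MolFromSmiles(s)) for s in smiles])

    k_low = int(round(p.low_fraction * p.n_molecules))
    if k_low == 0 or k_low == p.n_molecules:
        raise ValidationError(
            f"low_fraction {p.low_fraction} infeasible for n={p.n_molecules}"
        )
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    if s_sorted[k_low - 1] == s_sorted[k_low]:
        raise ValidationError(
            "tied structural scores at the class boundary; "
            "cannot achieve the requested low fraction exactly"
        )
    cut = 0.5 * (s_sorted[k_low - 1] + s_sorted[k_low])

    eps_clean = 150_000.0 * np.exp(p.beta * (scores - cut))
    eps = eps_clean + rng.normal(0.0, p.noise_sigma, size=p.n_molecules)
    # recenter so the achieved class split is exact despite noise
    e_sorted = np.sort(eps)
    offset = 150_000.0 - 0.5 * (e_sorted[k_low - 1] + e_sorted[k_low])
    eps = np.clip(eps + offset, 0.0, None)
    eps_clean = np.clip(eps_clean + offset, 0.0, None)

    ids = [f"mol{i:05d}" for i in range(p.n_molecules)]
    table = pd.DataFrame(
        {
            "molecule_id": ids,
            "smiles": smiles,
            "epsilon": eps,
            "source_label": "synthetic",
        }
    )
    sidecar = pd.DataFrame(
        {
            "molecule_id": ids,
            "score": scores,
            "epsilon_noiseless": eps_clean,
            "label": np.where(eps >= 150_000.0, "high", "low"),
        }
    )
    return table, sidecar
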