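"""Reduce a dye-dimer trajectory to per-frame (t, R, |kappa|, |J|) series.

The workflow mirrors how MD trajectories of DNA-templated dye dimers are
analysed: per frame, each dye's transition-dipole endpoints are taken as the
(unweighted) centroids of its two terminal aryl groups; the orientation
factor and extended-dipole coupling are evaluated every frame (typically
every 10 ps); an initial equilibration window (default 100 ns) is excluded;
frames are segmented into non-intercalated (O1, large R) and intercalated
(O2, small R) states; post-equilibration windows are summarised as mean ±
population standard deviation; and 2-D histograms of |kappa| or |J| versus R
summarise the visited geometries.

All distances are nm, times ps, couplings meV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as _coupling
from .errors import (
    EmptyAnalysisError,
    PeriodicImageError,
    SelectionError,
    ValidationError,
)
from .geometry import CONSTANTS

ENDPOINT_COLUMNS = [
    "time_ps",
    "r_m_x", "r_m_y", "r_m_z",
    "s_m_x", "s_m_y", "s_m_z",
    "r_n_x", "r_n_y", "r_n_z",
    "s_n_x", "s_n_y", "s_n_z",
]

#: intra-group atom span beyond which we assume a broken (unimaged) molecule
MAX_GROUP_SPAN_NM = 1.5

#: default boundary between intercalated (O2) and non-intercalated (O1) states,
#: midway between the observed O2 (~0.9-1.5 nm) and O1 (~2.5-3.0 nm) R ranges
DEFAULT_R_THRESHOLD_NM = 2.0

DEFAULT_EQUILIBRATION_PS = 100_000.0  # 100 ns
DEFAULT_STRIDE_PS = 10.0


@dataclass
class EndpointTable:
    """Per-frame dipole endpoint coordinates for a dimer.

    Arrays: ``time`` (n,) in ps; ``r_m``, ``s_m``, ``r_n``, ``s_n`` (n, 3) in nm.
    """

    time: np.ndarray
    r_m: np.ndarray
    s_m: np.ndarray
    r_n: np.ndarray
    s_n: np.ndarray
    stride_ps: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        n = self.time.shape[0]
        if n == 0:
            raise ValidationError("endpoint table is empty")
        for name in ("r_m", "s_m", "r_n", "s_n"):
            a = np.asarray(getattr(self, name), float)
            if a.shape != (n, 3):
                raise ValidationError(
                    f"{name} must have shape ({n}, 3), got {a.shape}"
                )
            setattr(self, name, a)
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValidationError("frame times must be strictly increasing")
            if self.stride_ps is None and np.allclose(dt, dt[0]):
                self.stride_ps = float(dt[0])

    def __len__(self) -> int:
        return self.time.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        data = np.column_stack([self.time, self.r_m, self.s_m, self.r_n, self.s_n])
        return pd.DataFrame(data, columns=ENDPOINT_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EndpointTable":
        missing = [c for c in ENDPOINT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"endpoint table missing columns: {missing}")
        g = lambda cols: df[cols].to_numpy(float)
        return cls(
            time=df["time_ps"].to_numpy(float),
            r_m=g(["r_m_x", "r_m_y", "r_m_z"]),
            s_m=g(["s_m_x", "s_m_y", "s_m_z"]),
            r_n=g(["r_n_x", "r_n_y", "r_n_z"]),
            s_n=g(["s_n_x", "s_n_y", "s_n_z"]),
        )

    @classmethod
    def from_csv(cls, path) -> "EndpointTable":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class FrameSeries:
    """Per-frame R, |kappa|, |J| restricted to the post-equilibration window."""

    time: np.ndarray           # ps
    R: np.ndarray              # nm
    kappa_abs: np.ndarray
    J_abs: np.ndarray          # meV
    equilibration_cutoff: float
    stride_ps: float | None = None
    kappa_signed: np.ndarray | None = None
    J_signed: np.ndarray | None = None

    def __len__(self) -> int:
        return self.time.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.time,
                "R_nm": self.R,
                "kappa_abs": self.kappa_abs,
                "J_abs_meV": self.J_abs,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class StateSegments:
    """Per-frame O1/O2 labels plus contiguous state intervals.

    O2 (intercalated) iff R < R_threshold; O1 (non-intercalated) otherwise.
    ``intervals`` rows: (state, t_start_ps, t_end_ps, n_frames).
    """

    state: np.ndarray                 # array of "O1"/"O2" strings
    R_threshold: float
    intervals: list[tuple[str, float, float, int]]
    occupancy: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["state", "t_start_ps", "t_end_ps", "n_frames"]
        )


@dataclass
class SeriesSummary:
    """Windowed mean/std summary of a frame series (population std)."""

    window_start: float
    n_frames: int
    kappa_mean: float
    kappa_std: float
    R_mean: float
    R_std: float
    J_mean: float
    J_std: float

    def to_dict(self) -> dict:
        return {
            "window_start_ps": self.window_start,
            "n_frames": self.n_frames,
            "kappa_abs": {"mean": self.kappa_mean, "std": self.kappa_std},
            "R_nm": {"mean": self.R_mean, "std": self.R_std},
            "J_abs_meV": {"mean": self.J_mean, "std": self.J_std},
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class HeatmapGrid:
    """2-D occupancy histogram of |kappa| (or |J|) versus R."""

    x_edges: np.ndarray   # R, nm
    y_edges: np.ndarray
    counts: np.ndarray    # shape (len(x_edges)-1, len(y_edges)-1)
    y_quantity: str       # "kappa" or "J"

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(0.5 * (self.x_edges[:-1] + self.x_edges[1:]), name="R_nm"),
            columns=0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )
        df.to_csv(path)


# ---------------------------------------------------------------------------
# trajectory -> endpoint extraction
# ---------------------------------------------------------------------------

def _resolve_group(universe, spec, key: str):
    """Resolve one endpoint group from a selection spec entry.

    An entry is either an MDAnalysis selection string or a mapping with
    ``resname`` and ``names`` keys.
    """
    entry = spec[key]
    if isinstance(entry, str):
        sel = entry
    else:
        try:
            resname = entry["resname"]
            names = entry["names"]
        except (KeyError, TypeError) as exc:
            raise SelectionError(
                f"selection entry {key!r} must be a selection string or a "
                f"mapping with 'resname' and 'names'"
            ) from exc
        name_clause = " or ".join(f"name {n}" for n in names)
        sel = f"resname {resname} and ({name_clause})"
    group = universe.select_atoms(sel)
    if len(group) == 0:
        raise SelectionError(f"selection {key!r} ({sel!r}) matched no atoms")
    if not isinstance(entry, str):
        matched = set(group.names)
        missing = [n for n in entry["names"] if n not in matched]
        if missing:
            raise SelectionError(
                f"selection {key!r}: atom names not found: {missing}"
            )
    return group


def extract_endpoints(
    topology,
    selection_spec: dict,
    trajectory=None,
    mass_weighted: bool = False,
    dt_ps: float | None = None,
) -> EndpointTable:
    """Extract per-frame dipole endpoints from an MD trajectory.

    Parameters
    ----------
    topology : path
        GRO or (multi-frame) PDB file.
    selection_spec : dict
        Four entries keyed ``dye_m_r``, ``dye_m_s``, ``dye_n_r``,
        ``dye_n_s``; each either an MDAnalysis selection string or a mapping
        ``{"resname": ..., "names": [...]}`` naming one terminal aryl group.
    trajectory : path, optional
        XTC (or any MDAnalysis-readable) coordinate file; omit for a
        multi-frame PDB topology.
    mass_weighted : bool
        Use the center of mass instead of the unweighted centroid.
    dt_ps : float, optional
        Override the per-frame time step when the reader cannot supply one
        (e.g. PDB trajectories).

    Notes
    -----
    Coordinates are converted from the MDAnalysis angstrom convention to nm.
    Frames in which any selected group spans more than 1.5 nm raise
    :class:`PeriodicImageError`: the molecule is almost certainly split
    across the periodic boundary and the trajectory should be re-imaged
    (molecules made whole) before analysis.
    """
    import MDAnalysis as mda

    universe = (
        mda.Universe(str(topology))
        if trajectory is None
        else mda.Universe(str(topology), str(trajectory))
    )
    keys = ["dye_m_r", "dye_m_s", "dye_n_r", "dye_n_s"]
    missing = [k for k in keys if k not in selection_spec]
    if missing:
        raise SelectionError(f"selection spec missing entries: {missing}")
    groups = {k: _resolve_group(universe, selection_spec, k) for k in keys}

    n_frames = len(universe.trajectory)
    out = {k: np.empty((n_frames, 3)) for k in keys}
    times = np.empty(n_frames)
    for i, ts in enumerate(universe.trajectory):
        times[i] = ts.time if dt_ps is None else i * dt_ps
        for k, g in groups.items():
            pos = g.positions * 0.1  # angstrom -> nm
            span = _max_pairwise_distance(pos)
            if span > MAX_GROUP_SPAN_NM:
                raise PeriodicImageError(
                    f"group {k!r} spans {span:.2f} nm at frame {i} "
                    f"(> {MAX_GROUP_SPAN_NM} nm); re-image the trajectory so "
                    f"molecules are whole before extracting endpoints"
                )
            if mass_weighted:
                w = g.masses / g.masses.sum()
                out[k][i] = w @ pos
            else:
                out[k][i] = pos.mean(axis=0)
    return EndpointTable(
        time=times,
        r_m=out["dye_m_r"],
        s_m=out["dye_m_s"],
        r_n=out["dye_n_r"],
        s_n=out["dye_n_s"],
    )


def _max_pairwise_distance(pos: np.ndarray) -> float:
    if pos.shape[0] < 2:
        return 0.0
    d = pos[:, None, :] - pos[None, :, :]
    return float(np.sqrt((d**2).sum(axis=-1)).max())


# ---------------------------------------------------------------------------
# per-frame analysis
# ---------------------------------------------------------------------------

def analyze(
    table: EndpointTable,
    mu_m: float,
    mu_n: float,
    n_refr: float = CONSTANTS.refractive_index_default,
    equilibration_cutoff: float = DEFAULT_EQUILIBRATION_PS,
) -> FrameSeries:
    """Per-frame R, |kappa|, |J| for all frames at t >= equilibration_cutoff.

    mu values in Debye; cutoff in ps (default 100 ns).
    """
    if equilibration_cutoff < 0:
        raise ValidationError("equilibration cutoff must be >= 0")
    keep = table.time >= equilibration_cutoff
    if not np.any(keep):
        raise EmptyAnalysisError(
            f"no frames at t >= {equilibration_cutoff} ps "
            f"(last frame at {table.time[-1]} ps)"
        )
    R, kappa, J = _coupling.kappa_J_arrays(
        table.r_m[keep],
        table.s_m[keep],
        table.r_n[keep],
        table.s_n[keep],
        mu_m,
        mu_n,
        n_refr,
    )
    return FrameSeries(
        time=table.time[keep],
        R=R,
        kappa_abs=np.abs(kappa),
        J_abs=np.abs(J),
        equilibration_cutoff=float(equilibration_cutoff),
        stride_ps=table.stride_ps,
        kappa_signed=kappa,
        J_signed=J,
    )


def segment_states(
    series: FrameSeries, R_threshold: float = DEFAULT_R_THRESHOLD_NM
) -> StateSegments:
    """Label each frame O2 (intercalated, R < threshold) or O1 otherwise."""
    if len(series) == 0:
        raise ValidationError("cannot segment an empty series")
    if R_threshold <= 0:
        raise ValidationError("R_threshold must be positive")
    labels = np.where(series.R < R_threshold, "O2", "O1")
    intervals = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            intervals.append(
                (
                    str(labels[start]),
                    float(series.time[start]),
                    float(series.time[i - 1]),
                    i - start,
                )
            )
            start = i
    n = len(labels)
    occupancy = {
        "O1": float(np.count_nonzero(labels == "O1")) / n,
        "O2": float(np.count_nonzero(labels == "O2")) / n,
    }
    return StateSegments(
        state=labels,
        R_threshold=float(R_threshold),
        intervals=intervals,
        occupancy=occupancy,
    )


def summarize(series: FrameSeries, window_start: float = 0.0) -> SeriesSummary:
    """Mean and population std of |kappa|, R, |J| over t >= window_start."""
    keep = series.time >= window_start
    n = int(np.count_nonzero(keep))
    if n < 2:
        raise EmptyAnalysisError(
            f"summary window t >= {window_start} ps contains {n} frame(s); "
            f"need at least 2"
        )
    return SeriesSummary(
        window_start=float(window_start),
        n_frames=n,
        kappa_mean=float(series.kappa_abs[keep].mean()),
        kappa_std=float(series.kappa_abs[keep].std()),
        R_mean=float(series.R[keep].mean()),
        R_std=float(series.R[keep].std()),
        J_mean=float(series.J_abs[keep].mean()),
        J_std=float(series.J_abs[keep].std()),
    )


def heatmap(
    series: FrameSeries,
    y: str = "kappa",
    bin_R: float = 0.05,
    bin_y: float | None = None,
) -> HeatmapGrid:
    """2-D histogram of |kappa| (or |J|) versus R.

    Default bin widths: 0.05 nm in R, 0.05 in |kappa|, 2 meV in |J|.
    """
    if y not in ("kappa", "J"):
        raise ValidationError(f"y must be 'kappa' or 'J', got {y!r}")
    if bin_y is None:
        bin_y = 0.05 if y == "kappa" else 2.0
    if bin_R <= 0 or bin_y <= 0:
        raise ValidationError("bin widths must be positive")
    if len(series) == 0:
        raise ValidationError("cannot histogram an empty series")
    yvals = series.kappa_abs if y == "kappa" else series.J_abs
    x_edges = _cover_edges(series.R, bin_R)
    y_edges = _cover_edges(yvals, bin_y)
    counts, _, _ = np.histogram2d(series.R, yvals, bins=[x_edges, y_edges])
    return HeatmapGrid(x_edges=x_edges, y_edges=y_edges, counts=counts, y_quantity=y)


def _cover_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n + 1)
    # open the top edge a hair so max values land in the last bin
    edges[-1] = np.nextafter(edges[-1], np.inf)
    return edges


def plot_heatmap(grid: HeatmapGrid, path) -> None:
    """Render a heatmap grid to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, grid.counts.T, cmap="viridis")
    ax.set_xlabel("R (nm)")
    ax.set_ylabel("|kappa|" if grid.y_quantity == "kappa" else "|J| (meV)")
    fig.colorbar(mesh, ax=ax, label="frames")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
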