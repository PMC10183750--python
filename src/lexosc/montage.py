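"""Sensor montage geometry: 3-D positions, 2-D projection, neighbor graphs.

The neighbor graph drives three downstream steps: channel interpolation
(triangulation of nearest neighbors), the minimum-neighbor rule of the
cluster-forming step, and the searchlight mini-clusters (nearest electrodes
in the two-dimensional projection plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = ["Montage", "STUDY_CHANNELS", "load_montage", "build_neighbors"]

# 38-channel 10-20/10-10 layout used throughout the package.  The exact
# inventory of the recording cap is not public; this stand-in contains every
# region-of-interest electrode referenced by the analysis (including the
# legacy names T3/T4/T5/T6 and the 10-05 name PO2) and fills the remainder
# with standard 10-10 positions.
STUDY_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "PO7", "PO3", "POz", "PO2", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

# Legacy 10-20 names mapped onto modern 10-10 labels for position lookup.
_LEGACY_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


class MontageError(ValueError):
    """Raised for unresolvable channels or degenerate geometry."""


@dataclass
class Montage:
    """Channel names with 3-D head positions, planar projection and adjacency.

    Attributes
    ----------
    names : list of str
        Channel labels; unique, index-aligned with all other fields.
    pos3d : ndarray, shape (n, 3)
        Head-centered RAS coordinates (arbitrary head units, roughly a
        unit sphere).
    pos2d : ndarray, shape (n, 2)
        Azimuthal-equidistant projection of ``pos3d`` seen from the vertex.
    neighbors : ndarray of bool, shape (n, n)
        Symmetric, irreflexive adjacency (Delaunay triangulation edges on
        ``pos2d`` unless rebuilt with other settings).
    """

    names: list[str]
    pos3d: np.ndarray
    pos2d: np.ndarray = field(default=None)  # type: ignore[assignment]
    neighbors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise MontageError("channel names must be unique")
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        if self.pos3d.shape != (len(self.names), 3):
            raise MontageError("pos3d must be (n_channels, 3)")
        if self.pos2d is None:
            self.pos2d = azimuthal_equidistant(self.pos3d)
        if self.neighbors is None:
            self.neighbors = build_neighbors(self)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, channels) -> np.ndarray:
        """Indices of ``channels``; raises listing unknown names."""
        lookup = {n: i for i, n in enumerate(self.names)}
        unknown = [c for c in channels if c not in lookup]
        if unknown:
            raise MontageError(f"unknown channel(s): {', '.join(unknown)}")
        return np.array([lookup[c] for c in channels], dtype=int)

    def neighbor_names(self, channel: str) -> list[str]:
        i = self.index([channel])[0]
        return [self.names[j] for j in np.flatnonzero(self.neighbors[i])]


def _fit_sphere_center(pos: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere center of the sensor cloud."""
    a = np.c_[2 * pos, np.ones(len(pos))]
    b = (pos ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def azimuthal_equidistant(pos3d: np.ndarray) -> np.ndarray:
    """Project 3-D sensor positions to the plane, preserving arc length
    from the vertex (the standard flattening for sensor topographies).

    Positions are first re-centered on the best-fit sphere so that angular
    distances are computed about the head center, not the sensor centroid.
    """
    pos = np.asarray(pos3d, dtype=float)
    center = _fit_sphere_center(pos) if len(pos) >= 4 else pos.mean(axis=0)
    p = pos - center
    r = np.linalg.norm(p, axis=1)
    r = np.where(r == 0, 1.0, r)
    unit = p / r[:, None]
    polar = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    azimuth = np.arctan2(unit[:, 1], unit[:, 0])
    return np.column_stack([polar * np.cos(azimuth), polar * np.sin(azimuth)])


def build_neighbors(
    montage: Montage,
    method: str = "delaunay",
    max_dist: float | None = None,
) -> np.ndarray:
    """Symmetric channel adjacency from the planar layout.

    ``delaunay`` takes the triangulation edges on ``pos2d`` (optionally pruned
    to planar length <= ``max_dist``); ``distance`` connects all pairs within
    ``max_dist``.
    """
    pts = montage.pos2d
    n = len(pts)
    if n < 3:
        raise MontageError("need at least 3 channels to build neighbors")
    adj = np.zeros((n, n), dtype=bool)
    if method == "delaunay":
        try:
            tri = Delaunay(pts)
        except QhullError as err:
            raise MontageError(f"degenerate (collinear?) sensor layout: {err}") from None
        for simplex in tri.simplices:
            for a in range(3):
                i, j = simplex[a], simplex[(a + 1) % 3]
                adj[i, j] = adj[j, i] = True
    elif method == "distance":
        if max_dist is None:
            raise MontageError("method='distance' requires max_dist")
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        adj = d <= max_dist
    else:
        raise MontageError(f"unknown neighbor method {method!r}")
    if max_dist is not None:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        adj &= d <= max_dist
    np.fill_diagonal(adj, False)
    return adj


def _study_positions() -> np.ndarray:
    """3-D positions for the built-in layout from MNE's bundled 10-05 set."""
    import mne

    import warnings

    for name in ("colin27_1005", "standard_1005"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                std = mne.channels.make_standard_montage(name)
            break
        except ValueError:  # pragma: no cover - depends on mne version
            continue
    pos = std.get_positions()["ch_pos"]
    rows = []
    for ch in STUDY_CHANNELS:
        key = ch if ch in pos else _LEGACY_ALIASES.get(ch, ch)
        if key not in pos:  # pragma: no cover - all names ship with mne
            raise MontageError(f"position source lacks channel {ch}")
        rows.append(pos[key])
    arr = np.asarray(rows, dtype=float)
    return arr / np.linalg.norm(arr, axis=1).mean()  # ~unit-sphere head units


def load_montage(source: str = "study38", subset=None) -> Montage:
    """Load a montage from the built-in layout name or a TSV position file.

    The TSV format is ``name<TAB>x<TAB>y<TAB>z`` (head-centered RAS), one
    channel per row, with an optional header line.
    """
    if source == "study38":
        names, pos = list(STUDY_CHANNELS), _study_positions()
    else:
        names, rows = [], []
        with open(source) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or parts[0] in ("", "name"):
                    continue
                if len(parts) != 4:
                    raise MontageError(f"malformed montage row: {line!r}")
                names.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if len(names) < 3:
            raise MontageError("montage file must define at least 3 channels")
        pos = np.asarray(rows, dtype=float)
    mont = Montage(names=names, pos3d=pos)
    if subset is not None:
        idx = mont.index(subset)
        mont = Montage(names=[mont.names[i] for i in idx], pos3d=mont.pos3d[idx])
    return mont


def write_montage_tsv(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tx\ty\tz\n")
        for name, (x, y, z) in zip(montage.names, montage.pos3d):
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
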