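"""Sensor montage handling: 10-20 positions, synthetic lead fields, adjacency.

The package ships a 31-label 10-20 montage (``data/montage_1020_31.tsv``)
matching a common clinical EEG cap.  Positions are in metres in a
head-centred coordinate frame (x right, y anterior, z superior).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import Delaunay

__all__ = ["Montage", "load_montage", "default_montage", "gaussian_mixing", "sensor_adjacency"]


@dataclass
class Montage:
    """A named set of EEG sensors with 3-D positions.

    Parameters
    ----------
    labels : list of str
        Sensor names (10-20 nomenclature).
    positions : ndarray, shape (n_sensors, 3)
        Cartesian positions in metres, head-centred.
    """

    labels: list[str]
    positions: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_sensors, 3)")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Return the row index of a sensor label."""
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"sensor {label!r} not in montage") from None

    def projected_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection of sensors onto the x/y plane.

        The polar angle from the vertex becomes the radial distance, which
        keeps the outer ring of a cap from collapsing onto the equator.
        """
        p = self.positions
        r = np.linalg.norm(p, axis=1)
        theta = np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0))
        phi = np.arctan2(p[:, 1], p[:, 0])
        return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels,
             "x": self.positions[:, 0],
             "y": self.positions[:, 1],
             "z": self.positions[:, 2]})


def load_montage(path) -> Montage:
    """Read a tab-separated ``label  x  y  z`` montage file."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage file must have columns {sorted(required)}")
    return Montage(list(df["label"]), df[["x", "y", "z"]].to_numpy())


def default_montage() -> Montage:
    """The packaged 31-channel 10-20 montage."""
    ref = importlib.resources.files("alphashift.data") / "montage_1020_31.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_montage(path)


def gaussian_mixing(montage: Montage, centers, sigma_m: float = 0.05) -> np.ndarray:
    """Synthetic lead-field column: Gaussian bumps around centre sensors.

    Each source projects to the scalp as a sum of isotropic Gaussian bumps
    centred on the given sensor labels; the column is normalised so that the
    strongest sensor has weight 1.  This is a deliberately simple stand-in
    for a volume-conduction forward model: sensor-level claims about
    topography overlap only require a smooth, spatially localised projection.

    Parameters
    ----------
    centers : str or sequence of str
        Sensor label(s) at which the source projects maximally.
    sigma_m : float
        Spatial standard deviation of each bump in metres.
    """
    if isinstance(centers, str):
        centers = [centers]
    if sigma_m <= 0:
        raise ValueError("sigma_m must be positive")
    w = np.zeros(len(montage))
    for lab in centers:
        c = montage.positions[montage.index(lab)]
        d2 = np.sum((montage.positions - c) ** 2, axis=1)
        w += np.exp(-d2 / (2.0 * sigma_m**2))
    return w / np.max(np.abs(w))


def sensor_adjacency(montage: Montage, cap_factor: float = 1.5) -> csr_matrix:
    """Spatial neighbourhood graph of the montage.

    Edges are the Delaunay triangulation of the 2-D projected positions,
    pruned at ``cap_factor`` times the median edge length so that the hull
    does not link distant temporal/occipital sensors across the cap rim.

    Returns a symmetric boolean CSR matrix with an empty diagonal.
    """
    pts = montage.projected_2d()
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = lengths <= cap_factor * np.median(lengths)
    edges = edges[keep]
    n = len(montage)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n))
    return adj.tocsr()
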