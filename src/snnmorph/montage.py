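"""Electrode montages and their 3D template-space coordinates.

The default montage models a 66-channel acquisition: a 64-channel
extended 10/20 head cap plus two auxiliary surface channels (named
``AUX1``/``AUX2``; they carry no scalp position semantics and are
excluded from region aggregation).

Cap coordinates are generated from an idealised spherical 10/20-extended
layout (midline arc, circumferential ring, and interpolated coronal
arcs) and then scaled onto a head-shaped ellipsoid so that they live in
the same millimetre template space as the neuron grids in
:mod:`snnmorph.reservoir`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Semi-axes (x: left-right, y: back-front, z: down-up) of the template
#: head ellipsoid, in mm.  Shared with :func:`snnmorph.reservoir.synthetic_grid`.
HEAD_SEMI_AXES = (70.0, 85.0, 65.0)

# Midline electrodes at their fraction along the nasion -> inion arc.
_MIDLINE = {
    "Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "Cz": 0.5,
    "CPz": 0.6, "Pz": 0.7, "POz": 0.8, "Oz": 0.9, "Iz": 1.0,
}

# Circumferential ring, left path from Fpz to Oz in 18-degree steps.
_RING_LEFT = ["Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]
_RING_RIGHT = ["Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2"]

# Interpolated rows: (ring endpoint pair, midline label, slot grid).
# Slots follow the 10/5 numbering 7,5,3,1,z,2,4,6,8 at arc fractions k/8.
_ROWS = {
    "AF": (("AF7", "AF8"), "AFz", ["AF7", "AF5", "AF3", "AF1", "AFz", "AF2", "AF4", "AF6", "AF8"]),
    "F": (("F7", "F8"), "Fz", ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    "FC": (("FT7", "FT8"), "FCz", ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
    "C": (("T7", "T8"), "Cz", ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    "CP": (("TP7", "TP8"), "CPz", ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
    "P": (("P7", "P8"), "Pz", ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    "PO": (("PO7", "PO8"), "POz", ["PO7", "PO5", "PO3", "PO1", "POz", "PO2", "PO4", "PO6", "PO8"]),
}

# The 64 cap labels of the default montage, in row-major scalp order.
CAP_LABELS = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
    "Iz",
)

AUX_LABELS = ("AUX1", "AUX2")


@dataclass(eq=False)
class Montage:
    """An ordered set of channel labels with 3D template coordinates (mm)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), mm
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.labels)} labels"
            )
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def to_text(self) -> str:
        """Serialize as ``label x y z`` rows."""
        lines = [
            f"{lab}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}"
            for lab, p in zip(self.labels, self.positions)
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Montage":
        labels, rows = [], []
        for line in text.strip().splitlines():
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed montage row: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        return cls(tuple(labels), np.array(rows))


def _circle_through(a: np.ndarray, m: np.ndarray, b: np.ndarray):
    """Circle through three 3D points: returns (center, radius, e1, e2)."""
    u = b - a
    v = m - a
    n = np.cross(u, v)
    n = n / np.linalg.norm(n)
    e1 = u / np.linalg.norm(u)
    e2 = np.cross(n, e1)
    # 2D coordinates in the (e1, e2) plane basis anchored at a.
    bx = float(np.linalg.norm(u))
    mx, my = float(v @ e1), float(v @ e2)
    cx = bx / 2.0
    cy = (mx * mx + my * my - mx * bx) / (2.0 * my)
    center = a + cx * e1 + cy * e2
    radius = float(np.linalg.norm(a - center))
    return center, radius, e1, e2


def _arc_points(a: np.ndarray, m: np.ndarray, b: np.ndarray, fracs: np.ndarray) -> np.ndarray:
    """Points along the circular arc a -> m -> b at the given fractions."""
    center, radius, e1, e2 = _circle_through(a, m, b)

    def ang(p: np.ndarray) -> float:
        d = p - center
        return float(np.arctan2(d @ e2, d @ e1))

    def wrap(x: float) -> float:
        return (x + np.pi) % (2.0 * np.pi) - np.pi

    pa, pm, pb = ang(a), ang(m), ang(b)
    d1 = wrap(pm - pa)
    d2 = wrap(pb - pm)
    total = d1 + d2
    psis = pa + fracs * total
    return center + radius * (np.cos(psis)[:, None] * e1 + np.sin(psis)[:, None] * e2)


@lru_cache(maxsize=1)
def _unit_sphere_positions() -> dict:
    """Unit-sphere coordinates for every 10/20-extended label we may need."""
    pos: dict[str, np.ndarray] = {}
    # Midline: nasion (0, 1, 0) -> vertex (0, 0, 1) -> inion (0, -1, 0).
    for lab, f in _MIDLINE.items():
        th = np.pi * f
        pos[lab] = np.array([0.0, np.cos(th), np.sin(th)])
    # Ring at the Fpz/Oz level.
    z0 = pos["Fpz"][2]
    rho = pos["Fpz"][1]
    for k, lab in enumerate(_RING_LEFT, start=1):
        alpha = np.deg2rad(18.0 * k)
        pos[lab] = np.array([-rho * np.sin(alpha), rho * np.cos(alpha), z0])
    for k, lab in enumerate(_RING_RIGHT, start=1):
        alpha = np.deg2rad(18.0 * k)
        pos[lab] = np.array([rho * np.sin(alpha), rho * np.cos(alpha), z0])
    # Interpolated rows on circular arcs between ring electrodes.
    for (left, right), mid, slots in _ROWS.values():
        fracs = np.arange(9) / 8.0
        pts = _arc_points(pos[left], pos[mid], pos[right], fracs)
        for lab, p in zip(slots, pts):
            pos.setdefault(lab, p)
    return pos


def make_default_montage() -> Montage:
    """The default 66-channel montage: 64-channel extended 10/20 cap + 2 aux.

    Coordinates are in template-space mm, on the surface of the head
    ellipsoid with semi-axes :data:`HEAD_SEMI_AXES`; the auxiliary
    channels sit below the ears (mastoid-like placement).
    """
    sphere = _unit_sphere_positions()
    semi = np.array(HEAD_SEMI_AXES)
    labels = list(CAP_LABELS)
    coords = [sphere[lab] * semi for lab in labels]
    for sgn, lab in zip((-1.0, 1.0), AUX_LABELS):
        v = np.array([sgn * 0.95, -0.25, -0.35])
        coords.append(v / np.linalg.norm(v) * semi)
        labels.append(lab)
    return Montage(tuple(labels), np.array(coords))
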