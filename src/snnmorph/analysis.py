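"""Trained-model subtraction, change retention, and scalp-region summaries.

Two reservoirs trained on different conditions are compared edge-wise
(``delta = w_post - w_pre``); positive deltas are "increase" connections
and negative ones "decrease".  Only the top fraction (default 5 %) of
*relative* changes ``|delta| / max(|w_pre|, eps)`` is retained for
reporting.  Retained edges are then aggregated into ten scalp zones
(left/right frontal, frontocentral, temporal, centroparietal,
occipitoparietal) by assigning each endpoint neuron to its nearest
zone electrode, and summarised as a 10 x 10 increase/decrease matrix
plus a hemispheric dominance index in [-1, +1] (negative = left).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .montage import Montage
from .plasticity import TrainedModel
from .reservoir import NeuronGrid
from .synthetic import CouplingEdge

# The ten-zone grouping of cap electrodes (left/right x five sites).
_ZONE_LISTS: dict[str, tuple[str, ...]] = {
    "frontal_l": ("Fp1", "AF3", "F5", "F3", "F1"),
    "frontal_r": ("Fp2", "AF4", "F6", "F4", "F2"),
    "frontocentral_l": ("FC5", "FC3", "FC1", "C5", "C3", "C1"),
    "frontocentral_r": ("FC6", "FC4", "FC2", "C6", "C4", "C2"),
    "temporal_l": ("F7", "FT7", "T7", "TP7"),
    "temporal_r": ("F8", "FT8", "T8", "TP8"),
    "centroparietal_l": ("CP5", "CP3", "CP1", "P7", "P5", "P3", "P1"),
    "centroparietal_r": ("CP6", "CP4", "CP2", "P8", "P6", "P4", "P2"),
    "occipitoparietal_l": ("PO7", "PO5", "PO3", "O1"),
    "occipitoparietal_r": ("PO8", "PO6", "PO4", "O2"),
}

ZONE_ORDER = tuple(_ZONE_LISTS.keys())

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RegionScheme:
    """Named electrode zones; lists are pairwise disjoint."""

    zones: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for labels in self.zones.values():
            for lab in labels:
                if lab in seen:
                    raise ValueError(f"electrode {lab!r} appears in two zones")
                seen.add(lab)

    def zone_of(self, label: str) -> str | None:
        for name, labels in self.zones.items():
            if label in labels:
                return name
        return None

    def hemisphere(self, zone: str) -> str:
        return "left" if zone.endswith("_l") else "right"

    @property
    def electrodes(self) -> tuple[str, ...]:
        return tuple(lab for labels in self.zones.values() for lab in labels)


def default_region_scheme() -> RegionScheme:
    return RegionScheme(dict(_ZONE_LISTS))


def electrode_zone(
    label: str, scheme: RegionScheme | None = None, montage: Montage | None = None
) -> str:
    """Zone containing ``label``, or ``"unassigned"`` for channels outside
    the ten zones (auxiliary and midline channels).

    Raises ``KeyError`` for a label absent from the montage (when one is
    given) and from every zone.
    """
    scheme = scheme or default_region_scheme()
    zone = scheme.zone_of(label)
    if zone is not None:
        return zone
    if montage is not None:
        montage.index(label)  # raises KeyError for unknown labels
        return UNASSIGNED
    return UNASSIGNED


@dataclass(eq=False)
class ConnectivityDelta:
    """Per-edge signed weight change between two trained models."""

    sources: np.ndarray  # (M,) neuron index i of edge i -> j
    targets: np.ndarray  # (M,)
    w_pre: np.ndarray
    w_post: np.ndarray
    grid: NeuronGrid
    labels: tuple[str, str]  # (pre condition, post condition)
    retained: np.ndarray | None = None  # bool mask over edges
    retain_fraction: float = 0.05

    @property
    def delta(self) -> np.ndarray:
        return self.w_post - self.w_pre

    @property
    def n_edges(self) -> int:
        return len(self.sources)

    def retained_indices(self) -> np.ndarray:
        if self.retained is None:
            raise ValueError("run retain_top first")
        return np.nonzero(self.retained)[0]

    def to_table(self) -> "np.recarray":
        """Edge list with pre/post weights, delta, relative change, flag."""
        rel = relative_change(self)
        ret = self.retained if self.retained is not None else np.zeros(self.n_edges, bool)
        return np.rec.fromarrays(
            [self.sources, self.targets, self.w_pre, self.w_post, self.delta, rel, ret],
            names="neuron_i,neuron_j,w_pre,w_post,delta,relative_change,retained",
        )


def subtract_models(pre: TrainedModel, post: TrainedModel) -> ConnectivityDelta:
    """Edge-wise ``w_post - w_pre`` over the shared sparsity pattern."""
    if pre.model.grid.coords.shape != post.model.grid.coords.shape or not np.array_equal(
        pre.model.grid.coords, post.model.grid.coords
    ):
        raise ValueError("trained models have different neuron grids")
    if not np.array_equal(pre.model.connections, post.model.connections):
        raise ValueError("trained models have different sparsity patterns")
    i, j = np.nonzero(pre.model.connections)
    return ConnectivityDelta(
        sources=i.astype(np.int64),
        targets=j.astype(np.int64),
        w_pre=pre.weights[i, j].copy(),
        w_post=post.weights[i, j].copy(),
        grid=pre.model.grid,
        labels=(pre.trained_on, post.trained_on),
    )


def relative_change(delta: ConnectivityDelta, eps: float = 1e-6) -> np.ndarray:
    return np.abs(delta.delta) / np.maximum(np.abs(delta.w_pre), eps)


def retain_top(
    delta: ConnectivityDelta,
    fraction: float = 0.05,
    relative: bool = True,
    eps: float = 1e-6,
) -> ConnectivityDelta:
    """Keep the ``ceil(fraction * M)`` largest changes among the M nonzero
    deltas (relative by default); ties break by edge index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    score = relative_change(delta, eps) if relative else np.abs(delta.delta)
    nonzero = np.nonzero(delta.delta != 0)[0]
    keep_n = math.ceil(fraction * len(nonzero))
    retained = np.zeros(delta.n_edges, dtype=bool)
    if keep_n:
        # stable sort on descending score; ties fall back to edge order
        order = nonzero[np.argsort(-score[nonzero], kind="stable")]
        retained[order[:keep_n]] = True
    return replace(delta, retained=retained, retain_fraction=fraction)


@dataclass(eq=False)
class RegionSummary:
    """Zone-pair aggregated change magnitudes and hemispheric dominance."""

    increase: np.ndarray  # (10, 10) >= 0, source zone x target zone
    decrease: np.ndarray  # (10, 10) <= 0
    dominance: float  # (R - L) / (R + L) over |change|; 0 when empty
    zone_order: tuple[str, ...] = ZONE_ORDER

    def magnitude(self) -> np.ndarray:
        return self.increase - self.decrease

    def pair_magnitudes(self) -> dict[tuple[str, str], float]:
        """Unordered zone-pair magnitudes (direction collapsed)."""
        mag = self.magnitude()
        out: dict[tuple[str, str], float] = {}
        for a, za in enumerate(self.zone_order):
            for b in range(a, len(self.zone_order)):
                zb = self.zone_order[b]
                v = mag[a, b] if a == b else mag[a, b] + mag[b, a]
                out[(za, zb)] = float(v)
        return out


def _endpoint_zones(
    delta: ConnectivityDelta,
    scheme: RegionScheme,
    montage: Montage,
    max_distance: float,
    input_map: dict[str, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Zone index (-1 = unassigned) for each edge endpoint.

    Input neurons carry the zone of the channel mapped onto them; every
    other neuron takes the zone of its nearest zone electrode within
    ``max_distance`` mm (farther neurons stay unassigned as deep).
    """
    zone_labels = [lab for lab in scheme.electrodes if lab in montage]
    positions = np.array([montage.position_of(lab) for lab in zone_labels])
    zone_idx_of_label = np.array(
        [ZONE_ORDER.index(scheme.zone_of(lab)) for lab in zone_labels]
    )
    used = np.unique(np.concatenate([delta.sources, delta.targets]))
    d = cdist(delta.grid.coords[used], positions)
    nearest = np.argmin(d, axis=1)
    ok = d[np.arange(len(used)), nearest] <= max_distance
    zone_of_neuron = np.full(delta.grid.n_neurons, -1, dtype=int)
    zone_of_neuron[used[ok]] = zone_idx_of_label[nearest[ok]]
    if input_map is not None:
        for label, neuron in input_map.items():
            zone = scheme.zone_of(label)
            zone_of_neuron[neuron] = ZONE_ORDER.index(zone) if zone else -1
    return zone_of_neuron[delta.sources], zone_of_neuron[delta.targets]


def summarize_regions(
    delta: ConnectivityDelta,
    scheme: RegionScheme | None = None,
    input_map: dict[str, int] | None = None,
    montage: Montage | None = None,
    max_distance: float = 40.0,
) -> RegionSummary:
    """Aggregate retained changes into the ten-zone scheme.

    Each retained edge contributes to the (source zone, target zone) cell
    when both endpoints are assigned; the dominance index weighs every
    assigned endpoint by half the edge's absolute change.  When
    ``input_map`` is given, input neurons inherit their channel's zone
    directly instead of going through the nearest-electrode rule.
    """
    scheme = scheme or default_region_scheme()
    if montage is None:
        raise ValueError("summarize_regions needs the montage for electrode positions")
    nz = len(ZONE_ORDER)
    increase = np.zeros((nz, nz))
    decrease = np.zeros((nz, nz))
    left_total = right_total = 0.0
    if delta.retained is not None and delta.retained.any():
        src_zone, tgt_zone = _endpoint_zones(
            delta, scheme, montage, max_distance, input_map
        )
        idx = delta.retained_indices()
        dvals = delta.delta[idx]
        for k, edge in zip(idx, dvals, strict=True):
            zi, zj = src_zone[k], tgt_zone[k]
            if zi >= 0 and zj >= 0:
                if edge > 0:
                    increase[zi, zj] += edge
                else:
                    decrease[zi, zj] += edge
            for z in (zi, zj):
                if z >= 0:
                    if ZONE_ORDER[z].endswith("_l"):
                        left_total += abs(edge) / 2.0
                    else:
                        right_total += abs(edge) / 2.0
    total = left_total + right_total
    dominance = 0.0 if total == 0 else (right_total - left_total) / total
    return RegionSummary(increase, decrease, float(dominance))


def recovery_score(
    summary: RegionSummary,
    planted: tuple[CouplingEdge, ...] | list[CouplingEdge],
    scheme: RegionScheme | None = None,
) -> float:
    """Fraction of planted zone pairs ranking in the top quartile of the
    summary's zone-pair magnitudes."""
    scheme = scheme or default_region_scheme()
    if not planted:
        raise ValueError("no planted coupling metadata")
    pairs = summary.pair_magnitudes()
    ordered = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    top_n = math.ceil(0.25 * len(ordered))
    top = {pair for pair, mag in ordered[:top_n] if mag > 0}

    def as_pair(edge: CouplingEdge) -> tuple[str, str]:
        za = scheme.zone_of(edge.source)
        zb = scheme.zone_of(edge.target)
        if za is None or zb is None:
            raise ValueError(f"planted edge {edge} touches electrodes outside all zones")
        return tuple(sorted((za, zb), key=ZONE_ORDER.index))

    planted_pairs = {as_pair(e) for e in planted}
    hits = sum(1 for p in planted_pairs if p in top)
    return hits / len(planted_pairs)


def mean_delta(deltas: list[ConnectivityDelta]) -> ConnectivityDelta:
    """Group-level delta: mean of per-recording deltas over shared sparsity."""
    if not deltas:
        raise ValueError("no deltas to aggregate")
    first = deltas[0]
    for d in deltas[1:]:
        if not (
            np.array_equal(d.sources, first.sources)
            and np.array_equal(d.targets, first.targets)
        ):
            raise ValueError("deltas have different sparsity patterns")
    return replace(
        first,
        w_pre=np.mean([d.w_pre for d in deltas], axis=0),
        w_post=np.mean([d.w_post for d in deltas], axis=0),
        retained=None,
    )
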