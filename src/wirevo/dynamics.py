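"""Post-hoc characterization of evolved patterns.

Given a trained pattern driven by the oriented-bar probe series, this module
quantifies how the circuit represents stimuli: the map of transfer entropy
from each input unit to each RC-readout unit, subtype-resolved connection
strength distributions, a standardized 3-PC embedding of the dynamics, the
stimulus-separation score (k-means vs true labels, NMI), the box-counting
fractal dimension of the embedded trajectory, and its voxel-occupancy
volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .info import InfoEstimatorConfig, nmi, te_matrix
from .reservoir import ReservoirParams, Trajectory, WiringPattern, run
from .stimuli import BLANK_LABEL, StimulusSeries
from .structure import SUBTYPES


@dataclass
class Embedded3D:
    """Top-3 principal-component scores of a (standardized) trajectory."""

    points: np.ndarray
    cumulative_contribution: np.ndarray
    labels: np.ndarray


@dataclass
class CharacterizationRecord:
    """Summary of one entity's probe response."""

    fd: float
    separation_nmi: float
    volume: float
    te_map: np.ndarray
    cumulative_contribution: np.ndarray


def te_map(
    pattern: WiringPattern,
    W_out: np.ndarray,
    series: StimulusSeries,
    params: ReservoirParams,
    info_cfg: InfoEstimatorConfig = InfoEstimatorConfig(),
    seed: int = 0,
) -> np.ndarray:
    """TE from every input unit's signal to every RC-readout activation.

    Entry (i, j) is the binned transfer entropy from input signal i to
    RC-readout unit j; summing the map reproduces the pattern TE objective
    under sum aggregation.
    """
    traj = run(pattern, W_out, series, params, seed=seed)
    return te_matrix(series.vectors, traj.r[:, pattern.readout_units], info_cfg)


_FORWARD_ORDER = {"input": 0, "hidden": 1, "rc_readout": 2}


def strength_distributions(
    pattern: WiringPattern, n_bins: int = 20, max_strength: float | None = None
) -> dict[str, dict]:
    """|W| histograms of connections, split by subtype group and sign.

    Groups: within-subtype ("input", "hidden", "rc_readout") and directed
    between-subtype paths ("input->hidden", "hidden->input", ...), where
    "a->b" collects entries W[post=b, pre=a]; paths running up the
    input -> hidden -> rc_readout order are forward, the reverse backward.
    Each group maps to counts of excitatory (w > 0) and inhibitory (w < 0)
    connections with shared histogram bin edges over |w|.
    """
    W = pattern.W
    nz = np.abs(W[W != 0])
    hi = max_strength if max_strength is not None else (nz.max() if nz.size else 1.0)
    edges = np.linspace(0.0, hi, n_bins + 1)
    groups: dict[str, dict] = {}

    def add(name: str, weights: np.ndarray, direction: str) -> None:
        w = weights[weights != 0]
        exc, inh = w[w > 0], w[w < 0]
        groups[name] = {
            "direction": direction,
            "count": int(w.size),
            "excitatory": np.histogram(exc, bins=edges)[0],
            "inhibitory": np.histogram(np.abs(inh), bins=edges)[0],
            "bin_edges": edges,
        }

    idx = {s: pattern.units_of(s) for s in SUBTYPES}
    for s in SUBTYPES:
        add(s, W[np.ix_(idx[s], idx[s])], "within")
    for pre in SUBTYPES:
        for post in SUBTYPES:
            if pre == post:
                continue
            direction = (
                "forward"
                if _FORWARD_ORDER[post] > _FORWARD_ORDER[pre]
                else "backward"
            )
            add(f"{pre}->{post}", W[np.ix_(idx[post], idx[pre])], direction)
    return groups


def embed_pca3(
    trajectory: Trajectory,
    which: str = "reservoir",
    pattern: WiringPattern | None = None,
) -> Embedded3D:
    """Standardize the selected dynamics per unit and project onto 3 PCs.

    ``which`` selects the signal: "reservoir" (all units' activations),
    "rc_readout" (RC-readout units' activations; requires ``pattern``), or
    "readout_output" (the linear readout z).  Constant (zero-variance) units
    are dropped with a warning before standardization.
    """
    if which == "reservoir":
        data = trajectory.r
    elif which == "rc_readout":
        if pattern is None:
            raise ValueError("pattern is required to locate RC-readout units")
        data = trajectory.r[:, pattern.readout_units]
    elif which == "readout_output":
        data = trajectory.z
    else:
        raise ValueError(f"unknown selector: {which!r}")
    return embed_points_pca3(data, trajectory.labels)


def embed_points_pca3(data: np.ndarray, labels: np.ndarray) -> Embedded3D:
    """PCA embedding of an arbitrary (T, n_units) signal matrix."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] <= 3:
        raise ValueError("need more than 3 timesteps")
    std = data.std(axis=0)
    keep = std > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant unit(s) before PCA",
            stacklevel=2,
        )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 non-constant units")
    z = (data[:, keep] - data[:, keep].mean(axis=0)) / std[keep]
    pca = PCA(n_components=3, svd_solver="full")
    points = pca.fit_transform(z)
    return Embedded3D(
        points=points,
        cumulative_contribution=np.cumsum(pca.explained_variance_ratio_),
        labels=np.asarray(labels, dtype=object),
    )


def separation_nmi(
    embedded: Embedded3D, n_clusters: int | None = None, seed: int = 0
) -> float:
    """Stimulus-separation score of an embedded trajectory.

    k-means (10 restarts, seeded) clusters the non-blank embedded points
    with k = the number of distinct stimulus labels (or ``n_clusters``);
    the score is the NMI between true labels and cluster labels, in [0, 1].
    """
    mask = embedded.labels != BLANK_LABEL
    pts = embedded.points[mask]
    truth = embedded.labels[mask]
    k = n_clusters if n_clusters is not None else len(np.unique(truth))
    if pts.shape[0] < k:
        raise ValueError("fewer non-blank points than clusters")
    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pts)
    return nmi(truth, pred)


def fractal_dimension(
    points: np.ndarray, epsilons: np.ndarray | None = None
) -> float:
    """Box-counting fractal dimension of a 3-D point set.

    Occupied boxes N(eps) are counted on axis-aligned grids over the
    bounding cube at each box size, and FD is the least-squares slope of
    log N(eps) against log(1/eps).  The default ladder is 8 logarithmically
    spaced sizes between edge/2 and edge/64.  A degenerate point set (all
    points identical) has FD 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a (T, d) array")
    lo = pts.min(axis=0)
    edge = float((pts.max(axis=0) - lo).max())
    if edge == 0:
        return 0.0
    if epsilons is None:
        epsilons = np.geomspace(edge / 2, edge / 64, 8)
    else:
        epsilons = np.asarray(epsilons, dtype=float)
        if epsilons.size < 3:
            raise ValueError("need at least 3 box sizes")
    ranges = pts.max(axis=0) - lo
    counts = []
    for eps in epsilons:
        # grid of ceil(range/eps) boxes per axis exactly covers the bounding
        # box; points on the upper face are clipped into the last box
        n_boxes = np.maximum(np.ceil(ranges / eps), 1).astype(np.int64)
        boxes = np.minimum(np.floor((pts - lo) / eps).astype(np.int64), n_boxes - 1)
        counts.append(len(np.unique(boxes, axis=0)))
    slope = np.polyfit(np.log(1.0 / epsilons), np.log(counts), 1)[0]
    return float(slope)


def trajectory_volume(
    points: np.ndarray,
    voxel_size: float | None = None,
    origin: np.ndarray | None = None,
) -> float:
    """Occupied-voxel volume of a 3-D trajectory.

    Counts distinct voxels visited on a grid of the given size (default:
    bounding-cube edge / 50) and returns count * voxel_size**3.  ``origin``
    anchors the grid so several trajectories can share one grid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a nonempty (T, d) array")
    lo = origin if origin is not None else pts.min(axis=0)
    if voxel_size is None:
        edge = float((pts.max(axis=0) - pts.min(axis=0)).max())
        voxel_size = edge / 50 if edge > 0 else 1.0
    voxels = np.floor((pts - lo) / voxel_size).astype(np.int64)
    return float(len(np.unique(voxels, axis=0)) * voxel_size**3)


def normalized_volumes(
    trajectories: dict[str, np.ndarray], n_voxels_per_edge: int = 50
) -> dict[str, float]:
    """Voxel volumes of several trajectories on one shared grid, divided by
    the maximum so the largest equals 1."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    all_pts = np.vstack(list(trajectories.values()))
    lo = all_pts.min(axis=0)
    edge = float((all_pts.max(axis=0) - lo).max())
    voxel = edge / n_voxels_per_edge if edge > 0 else 1.0
    raw = {
        name: trajectory_volume(pts, voxel_size=voxel, origin=lo)
        for name, pts in trajectories.items()
    }
    top = max(raw.values())
    return {name: (v / top if top > 0 else 0.0) for name, v in raw.items()}


def characterize(
    pattern: WiringPattern,
    W_out: np.ndarray,
    probe_series: StimulusSeries,
    params: ReservoirParams,
    info_cfg: InfoEstimatorConfig = InfoEstimatorConfig(),
    seed: int = 0,
) -> tuple[CharacterizationRecord, Embedded3D]:
    """Full probe characterization of one entity.

    Drives the pattern with the probe series, embeds the whole-reservoir
    activations into 3 PCs, and computes FD, separation NMI, raw voxel
    volume (normalize across entities with :func:`normalized_volumes`), and
    the input-to-readout TE map.
    """
    traj = run(pattern, W_out, probe_series, params, seed=seed)
    emb = embed_pca3(traj, which="reservoir")
    record = CharacterizationRecord(
        fd=fractal_dimension(emb.points),
        separation_nmi=separation_nmi(emb, seed=seed),
        volume=trajectory_volume(emb.points),
        te_map=te_matrix(probe_series.vectors, traj.r[:, pattern.readout_units], info_cfg),
        cumulative_contribution=emb.cumulative_contribution,
    )
    return record, emb
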