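"""Binned information-theoretic estimators: TE, MI, NMI, and the TE objective.

All continuous series are discretized into ``n_bins`` equal-width bins over
their own range and probabilities are estimated by plug-in counting; results
are in bits.  Transfer entropy follows Schreiber's definition

    TE(X -> Y) = sum p(y_{t+1}, y_t^(k), x_t^(l))
                 log2 [ p(y_{t+1} | y_t^(k), x_t^(l)) / p(y_{t+1} | y_t^(k)) ]

i.e. the expected log-ratio over all observed joint states, with history
lengths k (target) and l (source).  TE is zero when X carries no predictive
information about Y beyond Y's own past.

The per-pattern evolution objective aggregates TE from every input unit's
external signal to every RC-readout unit's activation (sum by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class InfoEstimatorConfig:
    """n_bins: equal-width bins per series; k / l: target / source history
    lengths; aggregate: how pattern_te pools the input x readout TE matrix."""

    n_bins: int = 8
    k: int = 1
    l: int = 1
    aggregate: str = "sum"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.k < 1 or self.l < 1:
            raise ValueError("history lengths k, l must be at least 1")
        if self.aggregate not in ("sum", "mean"):
            raise ValueError(f"unknown aggregate: {self.aggregate!r}")


def discretize(series: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of a 1-D series over its own range.

    A constant series (zero range) maps to a single bin (all zeros).
    """
    series = np.asarray(series, dtype=float).ravel()
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros(series.size, dtype=np.int64)
    idx = np.floor((series - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    # summing in sorted order makes the result independent of label
    # arrangement, so e.g. MI is exactly symmetric in its arguments
    p = np.sort(counts[counts > 0]) / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _embed(sym: np.ndarray, order: int, t_max: int, base: int) -> np.ndarray:
    """Codes of the length-``order`` history ending at each t in [order-1, t_max]."""
    code = np.zeros(t_max - order + 2, dtype=np.int64)
    for j in range(order):
        code = code * base + sym[order - 1 - j : t_max + 1 - j]
    return code


def _te_from_codes(
    y_next: np.ndarray, y_hist: np.ndarray, x_hist: np.ndarray, base_y: int
) -> float:
    """Plug-in TE (bits) from aligned symbol arrays.

    H-decomposition: TE = H(y+|y_hist) - H(y+|y_hist,x_hist)
                       = H(y+,yh) - H(yh) - H(y+,yh,xh) + H(yh,xh).
    """
    yh = y_hist
    yxh = y_hist * (x_hist.max() + 1) + x_hist
    y_yh = y_next * (yh.max() + 1) + yh
    y_yxh = y_next * (yxh.max() + 1) + yxh
    h = [
        _entropy_from_counts(np.bincount(arr))
        for arr in (y_yh, yh, y_yxh, yxh)
    ]
    return h[0] - h[1] - h[2] + h[3]


def transfer_entropy(
    x: np.ndarray, y: np.ndarray, cfg: InfoEstimatorConfig = InfoEstimatorConfig()
) -> float:
    """Binned plug-in transfer entropy TE(X -> Y) in bits."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < cfg.k + cfg.l + 2:
        raise ValueError("series too short for the requested histories")
    sx = discretize(x, cfg.n_bins)
    sy = discretize(y, cfg.n_bins)
    m = max(cfg.k, cfg.l)
    t_max = x.size - 2  # histories end at t, target is t+1
    y_next = sy[m : x.size]
    y_hist = _embed(sy, cfg.k, t_max, cfg.n_bins)[m - cfg.k :]
    x_hist = _embed(sx, cfg.l, t_max, cfg.n_bins)[m - cfg.l :]
    te = _te_from_codes(y_next, y_hist, x_hist, cfg.n_bins)
    return max(te, 0.0) if te > -1e-12 else te


def mutual_information(
    x: np.ndarray, y: np.ndarray, cfg: InfoEstimatorConfig = InfoEstimatorConfig()
) -> float:
    """Binned plug-in mutual information I(X;Y) in bits (symmetric, >= 0)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    sx = discretize(x, cfg.n_bins)
    sy = discretize(y, cfg.n_bins)
    joint = sx * cfg.n_bins + sy
    h_x = _entropy_from_counts(np.bincount(sx))
    h_y = _entropy_from_counts(np.bincount(sy))
    h_xy = _entropy_from_counts(np.bincount(joint))
    mi = h_x + h_y - h_xy
    return max(mi, 0.0)


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information of two discrete labelings.

    NMI(C, K) = I(C;K) / sqrt(H(C) H(K)), computed directly from label
    frequencies (no binning); lies in [0, 1] and is invariant to permuting
    class names.  A labeling with a single class (zero entropy) is rejected.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    h_a = _entropy_from_counts(np.bincount(ia))
    h_b = _entropy_from_counts(np.bincount(ib))
    if h_a == 0 or h_b == 0:
        raise ValueError("a labeling with a single class has zero entropy")
    joint = ia * (ib.max() + 1) + ib
    mi = h_a + h_b - _entropy_from_counts(np.bincount(joint))
    return float(min(max(mi, 0.0) / np.sqrt(h_a * h_b), 1.0))


def te_matrix(
    sources: np.ndarray, targets: np.ndarray, cfg: InfoEstimatorConfig
) -> np.ndarray:
    """Pairwise TE from each source column to each target column.

    Returns an (n_sources, n_targets) matrix; columns are discretized once.
    """
    sources = np.asarray(sources, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if sources.shape[0] != targets.shape[0]:
        raise ValueError("sources and targets must share the time axis")
    T = sources.shape[0]
    if T < cfg.k + cfg.l + 2:
        raise ValueError("series too short for the requested histories")
    sx = np.stack([discretize(sources[:, i], cfg.n_bins) for i in range(sources.shape[1])])
    sy = np.stack([discretize(targets[:, j], cfg.n_bins) for j in range(targets.shape[1])])
    m = max(cfg.k, cfg.l)
    t_max = T - 2
    out = np.empty((sources.shape[1], targets.shape[1]))
    x_hists = [
        _embed(sx[i], cfg.l, t_max, cfg.n_bins)[m - cfg.l :] for i in range(sx.shape[0])
    ]
    for j in range(sy.shape[0]):
        y_next = sy[j, m:]
        y_hist = _embed(sy[j], cfg.k, t_max, cfg.n_bins)[m - cfg.k :]
        for i in range(sx.shape[0]):
            te = _te_from_codes(y_next, y_hist, x_hists[i], cfg.n_bins)
            out[i, j] = max(te, 0.0) if te > -1e-12 else te
    return out


def pattern_te(
    pattern,
    W_out: np.ndarray,
    series,
    params,
    cfg: InfoEstimatorConfig = InfoEstimatorConfig(),
    seed: int = 0,
) -> float:
    """The evolution objective: aggregate TE from input signals to RC-readout
    activations over one driven run (sum over the pairs by default)."""
    from .reservoir import run  # local import to avoid a cycle

    traj = run(pattern, W_out, series, params, seed=seed)
    mat = te_matrix(series.vectors, traj.r[:, pattern.readout_units], cfg)
    return float(mat.sum() if cfg.aggregate == "sum" else mat.mean())
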