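"""Subtractive-normalized Hebbian plasticity.

One rule serves two roles: prenatal-style refinement of the reservoir's
internal weights under noise-driven spontaneous activity, and unsupervised
training of the readout weights while the network is driven by the stimulus
series (no supervised target exists).

The rule for the weight vector w of one downstream unit is the ODE

    tau dw/dt = v u - v (n . u) n / N

with v the downstream activity, u the N-vector of upstream activities and n
the all-ones vector.  Subtracting the mean co-activity makes every update
sum to zero over the upstream units, conserving total incoming weight.
Integration is forward Euler, one update per model timestep, so a single
increment is ``(dt / tau) (v u - v mean(u))``.  The default step is
``dt = tau``: forward Euler is only stable for steps no larger than the
rule's time constant, and steps well beyond tau let the Hebbian positive
feedback diverge on the marginally stable (spectral radius 1) reservoir —
a small fraction of tuning runs then blow the weights up by orders of
magnitude, which is not a behavior of the system being modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reservoir import ReservoirParams, WiringPattern, step
from .stimuli import StimulusSeries


@dataclass(frozen=True)
class HebbParams:
    """tau: rule time constant; dt: Euler step per model timestep (default
    dt = tau, the largest numerically stable forward-Euler step);
    T_tune: duration (steps) of the spontaneous-activity tuning phase."""

    tau: float = 0.1
    dt: float = 0.1
    T_tune: int = 100

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.T_tune < 0:
            raise ValueError("T_tune must be nonnegative")

    @property
    def rate(self) -> float:
        return self.dt / self.tau


def hebb_delta(v: float, u: np.ndarray, params: HebbParams) -> np.ndarray:
    """Single subtractive-normalized Hebbian increment.

    Returns ``(dt/tau) * (v*u - v*mean(u))``; the increment sums to zero
    over the upstream units exactly.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("upstream activity vector must be nonempty")
    return params.rate * (v * u - v * u.mean())


def tune_reservoir(
    pattern: WiringPattern,
    params: ReservoirParams,
    hebb: HebbParams,
    seed: int = 0,
    mask_updates: bool = True,
) -> WiringPattern:
    """Refine internal weights under spontaneous (noise-driven) activity.

    Runs ``T_tune`` steps with zero external input; after each step every
    unit's incoming weights receive a Hebbian increment with v = its own
    activation and u = the activation vector of all N = n_units upstream
    units.  By default only entries that were nonzero before tuning are
    updated, so the connection mask — and hence the density — is preserved
    (``mask_updates=False`` lets the rule grow new connections); the
    spectral radius is *not* re-normalized afterwards (normalization
    precedes tuning in the evolutionary pipeline).  With sigma = 0 there is
    no spontaneous activity and W is returned unchanged.
    """
    W = pattern.W.copy()
    mask = (W != 0) if mask_updates else np.ones_like(W, dtype=bool)
    rng = np.random.default_rng(seed)
    n = pattern.n_units
    x = np.zeros(n)
    u_ext = np.zeros(n)
    for _ in range(hebb.T_tune):
        x = step(x, W, u_ext, params, rng)
        r = np.tanh(x)
        # row i of the outer product is v_i * (u - mean(u)) with v_i = r_i
        W += hebb.rate * np.outer(r, r - r.mean()) * mask
    return pattern.with_weights(W)


def train_readout(
    pattern: WiringPattern,
    W_out: np.ndarray,
    series: StimulusSeries,
    params: ReservoirParams,
    hebb: HebbParams,
    seed: int = 0,
    readout_activity: str = "tanh",
) -> np.ndarray:
    """Hebbian training of the readout weights on a driven run.

    The reservoir is driven by ``series``; at every step each readout row i
    is updated by :func:`hebb_delta` with u = the N = n_per_subtype
    RC-readout activations and v = that readout's own output activity.  By
    default v = tanh(z_i) — the same bounded-activation convention used for
    the reservoir rule, which keeps the (purely Hebbian, unsupervised)
    growth of W_out linear rather than exponential; ``readout_activity =
    "linear"`` uses the raw output z_i instead.  Returns the trained copy;
    a zero-length series returns W_out unchanged.
    """
    if readout_activity not in ("tanh", "linear"):
        raise ValueError(f"unknown readout_activity: {readout_activity!r}")
    W_out = np.array(W_out, dtype=float)
    input_idx = pattern.input_units
    readout_idx = pattern.readout_units
    vectors = series.vectors
    if len(vectors) and vectors.shape[1] != input_idx.size:
        raise ValueError("series vector length must match the input unit count")
    rng = np.random.default_rng(seed)
    n = pattern.n_units
    x = np.zeros(n)
    u_ext = np.zeros(n)
    for t in range(len(vectors)):
        u_ext[input_idx] = vectors[t]
        x = step(x, pattern.W, u_ext, params, rng)
        r_hat = (
            np.tanh(x[readout_idx])
            if params.readout_activation == "tanh"
            else x[readout_idx]
        )
        z = W_out @ r_hat
        v = np.tanh(z) if readout_activity == "tanh" else z
        W_out += hebb.rate * np.outer(v, r_hat - r_hat.mean())
    return W_out
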