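"""The circuit model: a leaky-tanh echo-state reservoir with unit subtypes.

The reservoir has ``n_units`` units split evenly into three subtypes: input
units (receive the external stimulus), RC-readout units (project to the
linear readout layer), and hidden units.  No unit both receives input and
feeds the readout.  The internal weight matrix ``W`` — the object the
evolutionary search acts on — is sparse (fraction ``s`` nonzero, values
initially Uniform[-0.5, 0.5]) and is always rescaled to spectral radius 1
before use.

State update (default, ``update_rule="leaky"``)::

    x(t+1) = (1 - alpha) x(t) + alpha (W r(t) + beta u(t) + sigma xi)

with ``r = tanh(x)`` and ``xi`` i.i.d. standard normal per unit per step;
``alpha`` is the decay coefficient, ``beta`` the input gain, ``sigma`` the
noise strength.  ``update_rule="integrator"`` instead applies the pure
accumulator form ``x(t+1) = x(t) + alpha W r + beta u + sigma xi``; that
variant has no leak, so driven states grow without bound and saturate tanh —
it is retained for comparison but is not suitable for the information-flow
experiments (see docs/methods.md).
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse.linalg import eigs as _sparse_eigs

from .stimuli import StimulusSeries
from .structure import SUBTYPES, GridLayout, build_layout


@dataclass(frozen=True)
class ReservoirParams:
    """Fixed circuit parameters.

    alpha : decay / recurrence coefficient (dimensionless).
    beta : input strength.
    sigma : noise strength (std of the per-unit per-step Gaussian noise).
    n_units : total reservoir units; must equal ``3 * n_per_subtype``.
    n_per_subtype : units per subtype (input / hidden / rc_readout).
    sparsity : target fraction of nonzero entries of W at initialization.
    update_rule : "leaky" (default) or "integrator" (see module docstring).
    readout_activation : "tanh" — the readout reads the bounded activations
        r of the RC-readout units (default); "state" reads raw x.
    """

    alpha: float = 0.1
    beta: float = 1.0
    sigma: float = 0.01
    n_units: int = 48
    n_per_subtype: int = 16
    sparsity: float = 0.2
    update_rule: str = "leaky"
    readout_activation: str = "tanh"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.sigma) < 0:
            raise ValueError("alpha, beta, sigma must be nonnegative")
        if self.n_units != 3 * self.n_per_subtype:
            raise ValueError("n_units must equal 3 * n_per_subtype")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if self.update_rule not in ("leaky", "integrator"):
            raise ValueError(f"unknown update_rule: {self.update_rule!r}")
        if self.readout_activation not in ("tanh", "state"):
            raise ValueError(f"unknown readout_activation: {self.readout_activation!r}")


@dataclass
class WiringPattern:
    """An evolving genome: weight matrix plus immutable spatial metadata."""

    W: np.ndarray
    subtype: np.ndarray
    coords: np.ndarray
    id: str

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    def units_of(self, subtype: str) -> np.ndarray:
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype: {subtype!r}")
        return np.flatnonzero(self.subtype == subtype)

    @property
    def input_units(self) -> np.ndarray:
        return self.units_of("input")

    @property
    def hidden_units(self) -> np.ndarray:
        return self.units_of("hidden")

    @property
    def readout_units(self) -> np.ndarray:
        return self.units_of("rc_readout")

    def with_weights(self, W: np.ndarray, new_id: str | None = None) -> "WiringPattern":
        """Copy of this pattern with a new weight matrix (metadata shared)."""
        return replace(self, W=W, id=new_id if new_id is not None else self.id)


@dataclass
class Trajectory:
    """Time-major record of one reservoir run: states, activations, outputs."""

    x: np.ndarray
    r: np.ndarray
    z: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return self.x.shape[0]


def spectral_radius(W: np.ndarray) -> float:
    """Largest eigenvalue magnitude of ``W``."""
    return float(np.abs(np.linalg.eigvals(np.asarray(W, dtype=float))).max())


def spectral_radius_arnoldi(W: np.ndarray) -> float:
    """Spectral radius via sparse Arnoldi iteration (independent route)."""
    val = _sparse_eigs(np.asarray(W, dtype=float), k=1, which="LM",
                       return_eigenvectors=False, maxiter=10_000)
    return float(np.abs(val[0]))


def normalize_spectral_radius(W: np.ndarray) -> np.ndarray:
    """Rescale ``W`` so its spectral radius is exactly 1.

    Raises ``ValueError`` for an all-zero or nilpotent matrix (radius 0).
    """
    W = np.asarray(W, dtype=float)
    rho = spectral_radius(W)
    if rho < 1e-12:
        raise ValueError("spectral radius is zero; cannot normalize")
    return W / rho


def init_pattern(
    params: ReservoirParams,
    seed: int,
    layout: GridLayout | None = None,
    pattern_id: str | None = None,
) -> WiringPattern:
    """Draw a fresh sparse wiring pattern and normalize its spectral radius.

    Nonzero positions are chosen i.i.d. with probability ``params.sparsity``;
    nonzero values are Uniform[-0.5, 0.5] before normalization.
    """
    if layout is None:
        layout = build_layout()
    if layout.n_units != params.n_units:
        raise ValueError("layout size does not match params.n_units")
    rng = np.random.default_rng(seed)
    n = params.n_units
    mask = rng.random((n, n)) < params.sparsity
    raw = rng.uniform(-0.5, 0.5, (n, n)) * mask
    W = normalize_spectral_radius(raw)
    return WiringPattern(
        W=W,
        subtype=layout.subtype.copy(),
        coords=layout.coords.copy(),
        id=pattern_id if pattern_id is not None else f"init-{seed}-{uuid.uuid4().hex[:8]}",
    )


def init_readout_weights(params: ReservoirParams, seed: int) -> np.ndarray:
    """Readout weight matrix, N(0, 1) entries, shape (n_readout, n_per_subtype)."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((params.n_per_subtype, params.n_per_subtype))


def step(
    x: np.ndarray,
    W: np.ndarray,
    u: np.ndarray,
    params: ReservoirParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One state update.  ``u`` is the full-length drive vector (zero outside
    input units); noise is drawn fresh from ``rng`` when ``sigma > 0``."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != u.shape or W.shape != (x.size, x.size):
        raise ValueError("dimension mismatch between x, u and W")
    r = np.tanh(x)
    if params.sigma > 0:
        if rng is None:
            raise ValueError("rng is required when sigma > 0")
        noise = params.sigma * rng.standard_normal(x.size)
    else:
        noise = 0.0
    drive = W @ r + params.beta * u + noise
    if params.update_rule == "leaky":
        return (1.0 - params.alpha) * x + params.alpha * drive
    # integrator: the drive terms add directly onto the running state, with
    # alpha scaling the recurrence only
    return x + params.alpha * (W @ r) + params.beta * u + noise


def run(
    pattern: WiringPattern,
    W_out: np.ndarray,
    series: StimulusSeries,
    params: ReservoirParams,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Drive the reservoir with a stimulus series from ``x(0) = 0``.

    Each series vector is routed one-to-one onto the input-subtype units in
    index order; all other units receive zero external input.  The readout
    ``z(t+1) = W_out x_hat(t+1)`` is computed from the RC-readout units'
    activations (or raw states, per ``params.readout_activation``).
    """
    n = pattern.n_units
    input_idx = pattern.input_units
    readout_idx = pattern.readout_units
    vectors = series.vectors
    if vectors.shape[1] != input_idx.size:
        raise ValueError(
            f"series vectors have length {vectors.shape[1]}, "
            f"expected {input_idx.size} (one per input unit)"
        )
    W_out = np.asarray(W_out, dtype=float)
    T = vectors.shape[0]
    rng = np.random.default_rng(seed)
    xs = np.empty((T, n))
    rs = np.empty((T, n))
    zs = np.empty((T, W_out.shape[0]))
    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    u = np.zeros(n)
    for t in range(T):
        u[input_idx] = vectors[t]
        x = step(x, pattern.W, u, params, rng)
        xs[t] = x
        rs[t] = np.tanh(x)
        x_hat = rs[t, readout_idx] if params.readout_activation == "tanh" else x[readout_idx]
        zs[t] = W_out @ x_hat
    return Trajectory(x=xs, r=rs, z=zs, labels=np.array(series.labels, dtype=object))


def save_pattern(pattern: WiringPattern, path) -> None:
    """Serialize a wiring pattern to an .npz archive."""
    np.savez(
        path,
        W=pattern.W,
        subtype=pattern.subtype.astype(str),
        coords=pattern.coords,
        id=np.array(pattern.id),
    )


def load_pattern(path) -> WiringPattern:
    """Load a wiring pattern saved by :func:`save_pattern`."""
    data = np.load(path, allow_pickle=False)
    return WiringPattern(
        W=data["W"],
        subtype=data["subtype"].astype(object),
        coords=data["coords"],
        id=str(data["id"]),
    )
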