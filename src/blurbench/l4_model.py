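"""Cortical Layer-4 representation: recurrent RBF-like units over LGN space.

Layer 4 is the thalamorecipient input layer of V1.  Each model unit i
stores a prototype LGN pattern w_i (unit Euclidean norm) and obeys the
rate dynamics

    tau dF_i/dt = -F_i + [ g_i + lambda * sum_{k != i} u_ik F_k ]_+ ,

where the feedforward drive

    g_i = ( w_i . x  -  theta * ||x|| ) / (1 - theta)
        = ||x|| (cos(w_i, x) - theta) / (1 - theta)

is a thresholded cosine similarity between the input LGN vector x and the
unit's prototype: units whose prototype is within angular distance
arccos(theta) of the input are driven, all others are silenced by the
rectifier.  The 1/(1-theta) factor normalises a perfect match (x = c w_i)
to drive exactly c.  u_ik are correlation coefficients between unit
outputs, learned from natural input statistics, and lambda scales this
lateral feedback; stability requires lambda * |eig|_max(u) < 1.

Training adapts the prototypes to natural-image LGN vectors by competitive
clustering on the unit sphere: k-means++-style spread-out seeding followed
by medoid updates (spherical k-medoids).  The medoid update keeps every
prototype an actual experienced activity pattern; replacing it with a
cluster mean blurs the fine (orientation-carrying) structure out of the
prototypes and measurably weakens their stimulus selectivity.  The lateral
couplings u_ik are then measured as Pearson correlations of the units'
feedforward outputs across the training corpus.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "L4Network",
    "L4State",
    "feedforward_drive",
    "steady_state",
    "train_l4",
    "l4_represent",
    "save_network",
    "load_network",
]

logger = logging.getLogger(__name__)

#: RBF similarity threshold.  Natural LGN vectors live in a narrow cone
#: (the 0.1 baseline dominates; typical pairwise cosines ~0.92), so the
#: threshold must sit near that level for units to be selective at all.
#: 0.96 is the largest value that leaves almost no input without an active
#: unit while keeping the population code sparse (~25-35% active).
DEFAULT_THETA = 0.96
#: Lateral gain.  The output-correlation couplings carry a strong global
#: co-activation mode (spectral radius ~30-60); gains near the stability
#: bound amplify that mode and swamp the feedforward selectivity, so the
#: default keeps the lateral term a small perturbation (lam * radius << 1).
DEFAULT_LAMBDA = 0.005
DEFAULT_TAU = 4.0  # ms
DEFAULT_DT = 0.5  # ms
DEFAULT_TOL = 1e-6
DEFAULT_MAX_STEPS = 2000


@dataclass(frozen=True)
class L4Network:
    """Afferent prototypes, lateral correlations and dynamics parameters."""

    afferent: np.ndarray  # (n_units, n_inputs), rows unit-norm
    lateral: np.ndarray  # (n_units, n_units), symmetric, zero diagonal
    theta: float
    lam: float
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        aff = np.asarray(self.afferent, dtype=np.float64)
        lat = np.asarray(self.lateral, dtype=np.float64)
        if aff.ndim != 2 or lat.shape != (aff.shape[0], aff.shape[0]):
            raise ConfigError("afferent/lateral matrix shapes are inconsistent")
        norms = np.linalg.norm(aff, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ConfigError("afferent rows must have unit Euclidean norm")
        if not np.allclose(lat, lat.T, atol=1e-10):
            raise ConfigError("lateral matrix must be symmetric")
        if not np.allclose(np.diag(lat), 0.0):
            raise ConfigError("lateral matrix must have zero diagonal")
        if np.abs(lat).max() > 1 + 1e-10:
            raise ConfigError("lateral entries must lie in [-1, 1]")
        if not (0 < self.theta < 1):
            raise ConfigError("theta must lie in (0, 1)")
        if self.lam < 0:
            raise ConfigError("lambda must be >= 0")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.lam > 0 and self.lam * self.spectral_radius >= 1:
            raise ConfigError(
                "unstable network: lambda * |eig|_max(lateral) must be < 1"
            )
        object.__setattr__(self, "afferent", aff)
        object.__setattr__(self, "lateral", lat)

    @property
    def n_units(self) -> int:
        return self.afferent.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvalsh(self.lateral)).max())


@dataclass(frozen=True)
class L4State:
    """Steady-state activities of the units, with convergence bookkeeping."""

    activities: np.ndarray
    converged: bool
    iterations: int


def feedforward_drive(network: L4Network, x: np.ndarray) -> np.ndarray:
    """Thresholded-cosine drive g_i = (w_i.x - theta ||x||) / (1 - theta)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != network.afferent.shape[1]:
        raise ConfigError(
            f"input dimension {x.shape[-1]} does not match network "
            f"({network.afferent.shape[1]})"
        )
    norm = np.linalg.norm(x, axis=-1, keepdims=True) if x.ndim > 1 else np.linalg.norm(x)
    return (x @ network.afferent.T - network.theta * norm) / (1.0 - network.theta)


def _euler_fixed_point(
    network: L4Network,
    g: np.ndarray,
    dt: float,
    tol: float,
    max_steps: int,
) -> tuple[np.ndarray, bool, int]:
    """Explicit-Euler integration of the rate dynamics from F = 0.

    ``g`` may be a single drive vector or a batch (rows); convergence is
    declared when the largest single-step activity change falls below tol.
    """
    if dt >= network.tau:
        raise ConfigError("dt must be smaller than tau for explicit Euler")
    if tol <= 0:
        raise ConfigError("tol must be positive")
    alpha = dt / network.tau
    f = np.zeros_like(g)
    for step in range(1, max_steps + 1):
        rec = g + network.lam * (f @ network.lateral.T)
        f_new = f + alpha * (-f + np.maximum(0.0, rec))
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            return f, True, step
    return f, False, max_steps


def steady_state(
    network: L4Network,
    x: np.ndarray,
    dt: float = DEFAULT_DT,
    tol: float = DEFAULT_TOL,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> L4State:
    """Steady-state response of the network to one LGN vector.

    Non-convergence within ``max_steps`` is flagged on the returned state
    and logged as a warning, not raised.
    """
    g = feedforward_drive(network, np.asarray(x, dtype=np.float64))
    f, converged, steps = _euler_fixed_point(network, g, dt, tol, max_steps)
    if not converged:
        logger.warning("L4 dynamics did not converge within %d steps", max_steps)
    return L4State(activities=f, converged=converged, iterations=steps)


def l4_represent(
    network: L4Network,
    dataset: np.ndarray,
    dt: float = DEFAULT_DT,
    tol: float = DEFAULT_TOL,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> np.ndarray:
    """Steady-state activity rows for a stack of LGN vectors: (n, n_units).

    Identical to calling :func:`steady_state` per row (the Euler map acts
    elementwise across the batch), but vectorised.
    """
    data = np.asarray(dataset, dtype=np.float64)
    if data.ndim != 2:
        raise ConfigError("dataset must be a 2-D array of LGN vectors")
    g = feedforward_drive(network, data)
    f, converged, _ = _euler_fixed_point(network, g, dt, tol, max_steps)
    if not converged:
        logger.warning(
            "L4 dynamics did not converge for at least one of %d inputs", len(data)
        )
    return f


def _kmeanspp_seeds(unit: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding on the unit sphere (squared chordal D2).

    Each step samples several candidates proportionally to their distance
    from the current seeds and keeps the one that most reduces the total
    quantization cost, which makes double-seeding a tight cluster unlikely.
    """
    n = unit.shape[0]
    n_candidates = 2 + int(np.log(max(k, 2)))
    seeds = [int(rng.integers(n))]
    d2 = np.maximum(2.0 - 2.0 * (unit @ unit[seeds[0]]), 0.0)
    for _ in range(k - 1):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a seed
            nxt = int(rng.integers(n))
        else:
            cand = rng.choice(n, size=n_candidates, p=d2 / total)
            costs = [
                np.minimum(d2, np.maximum(2.0 - 2.0 * (unit @ unit[c]), 0.0)).sum()
                for c in cand
            ]
            nxt = int(cand[int(np.argmin(costs))])
        seeds.append(nxt)
        d2 = np.minimum(d2, np.maximum(2.0 - 2.0 * (unit @ unit[nxt]), 0.0))
    return np.asarray(seeds)


def train_l4(
    training_vectors: np.ndarray,
    n_units: int = 182,
    theta: float = DEFAULT_THETA,
    lam: float = DEFAULT_LAMBDA,
    seed: int = 0,
    epochs: int = 10,
    tau: float = DEFAULT_TAU,
) -> L4Network:
    """Adapt prototypes and lateral correlations to a natural-input corpus.

    Prototypes: competitive clustering of the unit-normalised training LGN
    vectors — k-means++-style seeding from distinct training vectors,
    assignment by largest cosine, and a medoid update (each prototype
    becomes its cluster's most central member).  Prototypes therefore
    always remain actual experienced activity patterns; clusters that go
    empty keep their previous prototype.  The loop stops early once no
    medoid moves.

    Lateral couplings: Pearson correlation of the units' rectified
    feedforward outputs (lambda = 0) across the corpus, diagonal zeroed,
    clipped to [-1, 1]; units with zero output variance get zero coupling.
    If the requested lambda violates the spectral stability bound it is
    shrunk to 0.95 / |eig|_max with a logged warning.
    """
    x = np.asarray(training_vectors, dtype=np.float64)
    if x.ndim != 2:
        raise ConfigError("training_vectors must be a 2-D array")
    if not (0 < theta < 1):
        raise ConfigError("theta must lie in (0, 1)")
    norms = np.linalg.norm(x, axis=1)
    nonzero = norms > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} all-zero training vectors",
            stacklevel=2,
        )
        x, norms = x[nonzero], norms[nonzero]
    if x.shape[0] < n_units:
        raise ConfigError(
            f"need at least {n_units} training vectors, got {x.shape[0]}"
        )

    unit = x / norms[:, None]
    rng = np.random.default_rng(seed)
    prototypes = unit[_kmeanspp_seeds(unit, n_units, rng)].copy()

    for _ in range(epochs):
        assign = (unit @ prototypes.T).argmax(axis=1)
        moved = False
        for j in range(n_units):
            idx = np.flatnonzero(assign == j)
            if idx.size == 0:
                continue  # empty cluster keeps its prototype
            members = unit[idx]
            medoid = members[(members @ members.T).mean(axis=1).argmax()]
            if not np.array_equal(medoid, prototypes[j]):
                prototypes[j] = medoid
                moved = True
        if not moved:
            break

    # lateral couplings from feedforward (lambda = 0) output correlations
    g = (x @ prototypes.T - theta * norms[:, None]) / (1.0 - theta)
    f = np.maximum(0.0, g)
    sd = f.std(axis=0)
    active = sd > 0
    lateral = np.zeros((n_units, n_units))
    if active.sum() >= 2:
        c = np.corrcoef(f[:, active].T)
        lateral[np.ix_(active, active)] = c
    lateral = np.clip((lateral + lateral.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(lateral, 0.0)

    rho = float(np.abs(np.linalg.eigvalsh(lateral)).max())
    lam_eff = lam
    if lam > 0 and rho > 0 and lam * rho >= 1:
        lam_eff = 0.95 / rho
        logger.warning(
            "lambda=%.3g violates stability (|eig|max=%.3g); shrunk to %.3g",
            lam, rho, lam_eff,
        )
    return L4Network(afferent=prototypes, lateral=lateral, theta=theta,
                     lam=lam_eff, tau=tau)


def save_network(network: L4Network, path: str | Path, **meta) -> None:
    """Write the network as a single .npz archive with a JSON header."""
    header = dict(theta=network.theta, lam=network.lam, tau=network.tau, **meta)
    np.savez(
        Path(path),
        afferent=network.afferent,
        lateral=network.lateral,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
    )


def load_network(path: str | Path) -> L4Network:
    with np.load(Path(path)) as archive:
        header = json.loads(bytes(archive["header"].tobytes()).decode())
        return L4Network(
            afferent=archive["afferent"],
            lateral=archive["lateral"],
            theta=float(header["theta"]),
            lam=float(header["lam"]),
            tau=float(header["tau"]),
        )
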