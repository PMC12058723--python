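"""Semi-Markov hidden-state sequences and per-state phase-coupling specs.

States follow an embedded Markov chain with a zero-diagonal transition
matrix; dwell times are drawn explicitly from a uniform duration range,
so self-transitions are disallowed (one duration mechanism, not two).
Each state carries a random set of directed phase-coupling edges with a
target phase difference per edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkovSpec",
    "StateSequence",
    "StateCouplingSpec",
    "sample_markov_spec",
    "sample_state_sequence",
    "sample_coupling_specs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkovSpec:
    n_states: int
    transition_matrix: np.ndarray  # (K, K), row-stochastic, zero diagonal
    initial_probs: np.ndarray      # (K,)
    duration_range_ms: tuple[float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.initial_probs, dtype=float)
        if P.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix shape mismatch")
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition_matrix must be row-stochastic")
        if np.any(pi < 0) or abs(pi.sum() - 1) > 1e-12:
            raise ValueError("initial_probs must sum to 1")
        lo, hi = self.duration_range_ms
        if lo > hi or lo <= 0:
            raise ValueError("invalid duration range")
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "initial_probs", pi)


@dataclass
class StateSequence:
    """Ground-truth state labels with occurrence bookkeeping."""

    labels: np.ndarray  # (T,) ints in 0..K-1
    n_states: int
    occurrences: list[tuple[int, int, int]]  # (state, start, end) half-open

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def indicators(self) -> np.ndarray:
        """Binary (K, T) indicator matrix; columns sum to one."""
        ind = np.zeros((self.n_states, self.labels.size), dtype=np.int8)
        ind[self.labels, np.arange(self.labels.size)] = 1
        return ind

    def validate(self) -> None:
        prev_end = 0
        for state, start, end in self.occurrences:
            if start != prev_end or end <= start:
                raise ValueError("occurrences must partition [0, T)")
            if not np.all(self.labels[start:end] == state):
                raise ValueError("labels inconsistent with occurrences")
            prev_end = end
        if prev_end != self.labels.size:
            raise ValueError("occurrences do not cover all samples")


@dataclass(frozen=True)
class StateCouplingSpec:
    """Directed phase-coupling edges of one state.

    Each edge (driver, target, delta_phi) forces the target's
    instantaneous phase to the driver's phase plus delta_phi while the
    state is active.  A source may be the target of at most one edge per
    state, so phase assignments are never contradictory.
    """

    state: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        targets = [t for _, t, _ in self.edges]
        if len(set(targets)) != len(targets):
            raise ValueError("each target may appear at most once per state")
        for drv, tgt, dphi in self.edges:
            if drv == tgt:
                raise ValueError("driver and target must differ")
            if not (-np.pi <= dphi < np.pi):
                raise ValueError("delta_phi must lie in [-pi, pi)")


def sample_markov_spec(n_states: int, duration_range_ms: tuple[float, float],
                       rng: np.random.Generator) -> MarkovSpec:
    """Draw a random transition matrix (flat Dirichlet rows, zero diagonal,
    renormalized) and a flat-Dirichlet initial distribution."""
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    P = rng.dirichlet(np.ones(n_states), size=n_states)
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(n_states))
    return MarkovSpec(n_states=n_states, transition_matrix=P,
                      initial_probs=pi, duration_range_ms=tuple(duration_range_ms))


def _duration_samples(duration_ms: float, fs: float) -> int:
    # round half up, minimum one sample
    return max(1, int(np.floor(duration_ms / 1000.0 * fs + 0.5)))


def sample_state_sequence(spec: MarkovSpec, T: int, fs: float,
                          rng: np.random.Generator) -> StateSequence:
    """Sample a semi-Markov sequence of length T.

    Dwell times are Uniform(duration_range) in milliseconds, rounded to
    samples; the final occurrence is truncated at T.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    lo, hi = spec.duration_range_ms
    if _duration_samples(hi, fs) < 1:
        raise ValueError("duration range shorter than one sample period")
    labels = np.empty(T, dtype=np.int64)
    occurrences: list[tuple[int, int, int]] = []
    state = int(rng.choice(spec.n_states, p=spec.initial_probs))
    t = 0
    while t < T:
        dur = _duration_samples(rng.uniform(lo, hi), fs)
        end = min(t + dur, T)
        labels[t:end] = state
        occurrences.append((state, t, end))
        t = end
        if t < T:
            state = int(rng.choice(spec.n_states, p=spec.transition_matrix[state]))
    seq = StateSequence(labels=labels, n_states=spec.n_states, occurrences=occurrences)
    seq.validate()
    return seq


def max_feasible_edges(n_sources: int) -> int:
    """Unique-target constraint caps the edge count at n_sources - 1."""
    return n_sources - 1


def sample_coupling_specs(n_states: int, n_sources: int,
                          connection_range: tuple[int, int],
                          rng: np.random.Generator) -> list[StateCouplingSpec]:
    """Per state: edge count ~ discrete Uniform(connection_range), targets
    sampled without replacement, one uniform driver per target, and
    delta_phi ~ Uniform[-pi, pi) per edge.

    Edge counts above the unique-target feasibility cap (n_sources - 1)
    are clipped with a logged warning.
    """
    lo, hi = int(connection_range[0]), int(connection_range[1])
    if lo < 1 or lo > hi:
        raise ValueError("invalid connection_range")
    cap = max_feasible_edges(n_sources)
    if lo > cap:
        raise ValueError(f"connection_range infeasible: need >= {lo} unique-target "
                         f"edges but only {cap} are possible with {n_sources} sources")
    if hi > cap:
        logger.warning("connection_range upper bound %d exceeds feasibility cap %d; clipping", hi, cap)
        hi = cap
    specs = []
    for k in range(n_states):
        n_edges = int(rng.integers(lo, hi + 1))
        targets = rng.choice(n_sources, size=n_edges, replace=False)
        edges = []
        for tgt in targets:
            drv = int(rng.integers(n_sources - 1))
            if drv >= tgt:
                drv += 1
            dphi = float(rng.uniform(-np.pi, np.pi))
            edges.append((drv, int(tgt), dphi))
        specs.append(StateCouplingSpec(state=k, edges=edges))
    return specs
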