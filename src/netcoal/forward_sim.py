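"""Forward-in-time simulator of trait dynamics on the population network.

Each generation has two events, in order: every population copies the
previous generation's state of a source population drawn from its row of
the transmission matrix A, then the copied state mutates according to the
mutation matrix Q.  One population holds exactly one state at a time, so
the whole system is a length-``n`` integer state vector.

The simulator generates synthetic datasets: run to (near) stationarity,
then conceal some populations' states to play the role of unobserved or
to-be-inferred populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import MutationMatrix

__all__ = ["ObservationSet", "simulate_forward", "mask_dataset"]


@dataclass
class ObservationSet:
    """Observed states Y plus the target set X of populations to infer.

    ``observed`` maps population index -> state (both 0-based); ``infer_targets``
    lists the populations whose present state is an inference target.  The two
    index sets are disjoint; any remaining populations are ignored entirely.
    ``true_states`` optionally carries the full simulated state vector for
    benchmarking recovery of concealed states.
    """

    n: int
    k: int
    observed: dict[int, int]
    infer_targets: list[int] = field(default_factory=list)
    coords: np.ndarray | None = None
    true_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        m, l = len(self.observed), len(self.infer_targets)
        if m < 1:
            raise ValueError("at least one population must be observed (m >= 1)")
        if len(set(self.infer_targets)) != l:
            raise ValueError("duplicate infer-target indices")
        idx = set(self.observed) | set(self.infer_targets)
        if len(idx) != m + l:
            raise ValueError("observed and infer-target sets must be disjoint")
        if any(not 0 <= i < self.n for i in idx):
            raise ValueError(f"population indices must lie in [0, {self.n})")
        if any(not 0 <= s < self.k for s in self.observed.values()):
            raise ValueError(f"states must lie in [0, {self.k})")

    @property
    def m(self) -> int:
        return len(self.observed)

    @property
    def l(self) -> int:
        return len(self.infer_targets)

    @property
    def leaves(self) -> list[int]:
        """All m + l populations whose lineage enters the genealogy."""
        return sorted(self.observed) + sorted(
            set(self.infer_targets) - set(self.observed)
        )


def _draw_rows(cum: np.ndarray, rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: one sample from each cum[rows[i]]."""
    return (u[:, None] > cum[rows]).sum(axis=1)


def simulate_forward(
    A: np.ndarray,
    Q: MutationMatrix | np.ndarray,
    generations: int,
    init: np.ndarray | str = "random",
    seed: int | np.random.Generator = 0,
    record: bool = False,
) -> np.ndarray:
    """Run the transmission+mutation dynamics for ``generations`` steps.

    Parameters
    ----------
    init
        Initial state vector (0-based states), or "random" for uniform-random
        initial states.  There is no built-in burn-in: to emulate a system at
        stationarity simply request enough generations.
    record
        If True, return the full ``(generations+1, n)`` trajectory including
        the initial state; otherwise only the final state vector.

    Per-generation draw order is fixed (all transmission draws, then all
    mutation draws), so runs are bit-reproducible for a given seed.
    """
    Qm = Q.Q if isinstance(Q, MutationMatrix) else np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = Qm.shape[0]
    if A.shape != (n, n):
        raise ValueError(f"transmission matrix must be square, got {A.shape}")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(init, str):
        if init != "random":
            raise ValueError(f"unknown init mode {init!r}")
        states = rng.integers(0, k, size=n)
    else:
        states = np.asarray(init, dtype=int).copy()
        if states.shape != (n,):
            raise ValueError(
                f"init length {states.shape} does not match network size {n}"
            )
        if np.any((states < 0) | (states >= k)):
            raise ValueError(f"init states must lie in [0, {k})")

    cumA = np.cumsum(A, axis=1)
    cumQ = np.cumsum(Qm, axis=1)
    all_idx = np.arange(n)
    traj = np.empty((generations + 1, n), dtype=int) if record else None
    if record:
        traj[0] = states
    for g in range(generations):
        sources = _draw_rows(cumA, all_idx, rng.random(n))
        copied = states[sources]
        states = _draw_rows(cumQ, copied, rng.random(n))
        if record:
            traj[g + 1] = states
    return traj if record else states


def mask_dataset(
    states: np.ndarray,
    observed_idx,
    infer_idx=(),
    k: int | None = None,
    coords: np.ndarray | None = None,
) -> ObservationSet:
    """Conceal part of a simulated state vector to build a dataset.

    Populations in ``observed_idx`` keep their state as data Y; populations in
    ``infer_idx`` become the inference targets X; everything else is dropped.
    The full vector is retained as ``true_states`` for benchmarking.
    """
    states = np.asarray(states, dtype=int)
    n = len(states)
    observed_idx = list(observed_idx)
    infer_idx = list(infer_idx)
    if k is None:
        k = int(states.max()) + 1
    return ObservationSet(
        n=n,
        k=k,
        observed={int(i): int(states[i]) for i in observed_idx},
        infer_targets=[int(i) for i in infer_idx],
        coords=coords,
        true_states=states.copy(),
    )
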