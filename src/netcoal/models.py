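"""Transmission and mutation model families.

A network of ``n`` populations exchanges a discrete cultural trait.  Each
generation, population ``P_i`` copies the state of ``P_j`` with probability
``a_ij`` (the transmission rate), and the copied state then mutates from
state ``i`` to ``j`` with probability ``q_ij``.  Both events are encoded as
row-stochastic matrices: the ``n x n`` transmission matrix ``A`` and the
``k x k`` mutation matrix ``Q``.

Rather than estimating every ``a_ij`` and ``q_ij`` independently, both
matrices are parameterized by small named families (island model, gravity
kernel, square grid, uniform mutation, two-state mutation, or explicit
user matrices), and inference targets the family parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "TransmissionSpec",
    "MutationSpec",
    "MutationMatrix",
    "transmission_matrix",
    "mutation_matrix",
    "matrix_power",
    "stationary_distribution",
    "grid_coordinates",
    "ValidationError",
]

_ROW_TOL = 1e-12


class ValidationError(ValueError):
    """A model specification violates one of its family's constraints."""


def _check_rows(mat: np.ndarray, what: str) -> None:
    if np.any(mat < 0) or np.any(mat > 1):
        raise ValidationError(f"{what} entries must lie in [0, 1]")
    rowsums = mat.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > _ROW_TOL):
        raise ValidationError(
            f"{what} rows must sum to 1 within {_ROW_TOL}; got row sums {rowsums}"
        )


def grid_coordinates(L: int) -> np.ndarray:
    """(row, col) coordinates of the ``L*L`` grid populations, row-major."""
    r, c = np.divmod(np.arange(L * L), L)
    return np.column_stack([r, c])


def _grid_neighbors(L: int) -> list[list[int]]:
    nbrs: list[list[int]] = []
    for p in range(L * L):
        r, c = divmod(p, L)
        cur = []
        if r > 0:
            cur.append(p - L)
        if r < L - 1:
            cur.append(p + L)
        if c > 0:
            cur.append(p - 1)
        if c < L - 1:
            cur.append(p + 1)
        nbrs.append(cur)
    return nbrs


@dataclass(frozen=True)
class TransmissionSpec:
    """A named transmission-rate family plus its parameters.

    Families
    --------
    island
        Complete graph: ``a_ii = 1 - c``, ``a_ij = c/(n-1)`` otherwise.
    per_population
        Like island but with one learning rate ``c_i`` per population.
    gravity
        Gaussian interaction kernel: ``a_ij`` proportional to
        ``pi_j * exp(-d_ij^2 / (2 sigma^2))`` with per-node sizes ``pi_j``
        and pairwise distances ``d_ij`` (populations learn preferentially
        from large and nearby populations).
    grid
        ``L x L`` square lattice, edges between side-sharing squares;
        ``a_ij = d`` for each neighbour, ``a_ii = 1 - d*deg(P_i)``.
    explicit
        A full user-supplied row-stochastic matrix.
    """

    family: str
    n: int
    params: Mapping[str, float] = field(default_factory=dict)
    # family-specific metadata
    L: int | None = None                    # grid side length
    coords: np.ndarray | None = None        # node coordinates (gravity, I/O)
    sizes: np.ndarray | None = None         # node sizes pi_j (gravity)
    distances: np.ndarray | None = None     # pairwise d_ij (gravity)
    matrix: np.ndarray | None = None        # explicit family

    # -- constructors -------------------------------------------------
    @staticmethod
    def island(n: int, c: float) -> "TransmissionSpec":
        return TransmissionSpec("island", n, {"c": c})

    @staticmethod
    def per_population(cs) -> "TransmissionSpec":
        cs = np.asarray(cs, dtype=float)
        return TransmissionSpec(
            "per_population", len(cs), {f"c{i+1}": c for i, c in enumerate(cs)}
        )

    @staticmethod
    def gravity(sigma: float, sizes, coords=None, distances=None) -> "TransmissionSpec":
        sizes = np.asarray(sizes, dtype=float)
        n = len(sizes)
        if distances is None:
            if coords is None:
                raise ValidationError("gravity family needs coords or distances")
            coords = np.asarray(coords, dtype=float)
            diff = coords[:, None, :] - coords[None, :, :]
            distances = np.sqrt((diff**2).sum(axis=2))
        distances = np.asarray(distances, dtype=float)
        return TransmissionSpec(
            "gravity", n, {"sigma": sigma}, coords=coords, sizes=sizes,
            distances=distances,
        )

    @staticmethod
    def grid(L: int, d: float) -> "TransmissionSpec":
        return TransmissionSpec("grid", L * L, {"d": d}, L=L,
                                coords=grid_coordinates(L))

    @staticmethod
    def explicit(matrix) -> "TransmissionSpec":
        matrix = np.asarray(matrix, dtype=float)
        return TransmissionSpec("explicit", matrix.shape[0], {}, matrix=matrix)

    # -- parameter plumbing (used by samplers drawing theta_tau) ------
    def with_params(self, **updates: float) -> "TransmissionSpec":
        new = dict(self.params)
        new.update(updates)
        return replace(self, params=new)


def transmission_matrix(spec: TransmissionSpec) -> np.ndarray:
    """Realize a :class:`TransmissionSpec` as its row-stochastic matrix A."""
    n = spec.n
    if spec.family == "island":
        c = spec.params["c"]
        if not 0.0 <= c <= 1.0:
            raise ValidationError(f"island model needs 0 <= c <= 1, got c={c}")
        A = np.full((n, n), c / (n - 1) if n > 1 else 0.0)
        np.fill_diagonal(A, 1.0 - c)
    elif spec.family == "per_population":
        cs = np.array([spec.params[f"c{i+1}"] for i in range(n)])
        if np.any(cs < 0) or np.any(cs > 1):
            raise ValidationError("per-population rates must lie in [0, 1]")
        A = np.repeat((cs / (n - 1))[:, None], n, axis=1)
        np.fill_diagonal(A, 1.0 - cs)
    elif spec.family == "gravity":
        sigma = spec.params["sigma"]
        if sigma <= 0:
            raise ValidationError(f"gravity kernel needs sigma > 0, got {sigma}")
        W = spec.sizes[None, :] * np.exp(-spec.distances**2 / (2.0 * sigma**2))
        A = W / W.sum(axis=1, keepdims=True)
    elif spec.family == "grid":
        d = spec.params["d"]
        L = spec.L
        nbrs = _grid_neighbors(L)
        degs = np.array([len(x) for x in nbrs])
        if d < 0 or np.any(1.0 - d * degs < 0):
            raise ValidationError(
                f"grid model needs 1 - d*deg(P_i) >= 0 for every square "
                f"(max degree {degs.max()} implies d <= {1.0/degs.max():g}); got d={d}"
            )
        A = np.zeros((n, n))
        for i, cur in enumerate(nbrs):
            A[i, cur] = d
            A[i, i] = 1.0 - d * len(cur)
    elif spec.family == "explicit":
        A = np.asarray(spec.matrix, dtype=float)
        if A.shape != (n, n):
            raise ValidationError(f"explicit matrix must be {n}x{n}, got {A.shape}")
    else:
        raise ValidationError(f"unknown transmission family {spec.family!r}")
    _check_rows(A, "transmission matrix")
    return A


@dataclass(frozen=True)
class MutationSpec:
    """A named mutation-rate family over ``k`` states plus a root-state prior mode.

    ``uniform``: every ordered state pair mutates at rate ``mu/(k-1)``;
    ``two_state``: ``k=2`` with asymmetric rates ``q12``, ``q21``;
    ``explicit``: a full ``k x k`` row-stochastic matrix.

    ``root_prior`` chooses the prior on the most recent common ancestor's
    state: "stationary" (the chain's stationary distribution, the default),
    "uniform", or "fixed" (with ``root_state``).
    """

    family: str
    k: int
    params: Mapping[str, float] = field(default_factory=dict)
    matrix: np.ndarray | None = None
    root_prior: str = "stationary"
    root_state: int | None = None

    @staticmethod
    def uniform(k: int, mu: float, **kw) -> "MutationSpec":
        return MutationSpec("uniform", k, {"mu": mu}, **kw)

    @staticmethod
    def two_state(q12: float, q21: float, **kw) -> "MutationSpec":
        return MutationSpec("two_state", 2, {"q12": q12, "q21": q21}, **kw)

    @staticmethod
    def explicit(matrix, **kw) -> "MutationSpec":
        matrix = np.asarray(matrix, dtype=float)
        return MutationSpec("explicit", matrix.shape[0], {}, matrix=matrix, **kw)

    def with_params(self, **updates: float) -> "MutationSpec":
        new = dict(self.params)
        new.update(updates)
        return replace(self, params=new)


class MutationMatrix:
    """Realized mutation matrix Q with memoized integer powers.

    Branch lengths are integer generation counts, so only integer powers of
    Q are ever needed.  The two-state family uses the spectral closed form

        Q^t = [[pi1 + pi2*l^t, pi2 - pi2*l^t],
               [pi1 - pi1*l^t, pi2 + pi1*l^t]]

    with ``l = 1 - q12 - q21``, ``pi1 = q21/(q12+q21)``, ``pi2 = q12/(q12+q21)``;
    other families use exact repeated squaring.
    """

    def __init__(self, Q: np.ndarray, spec: MutationSpec | None = None):
        Q = np.asarray(Q, dtype=float)
        _check_rows(Q, "mutation matrix")
        self.Q = Q
        self.k = Q.shape[0]
        self.spec = spec
        self._powers: dict[int, np.ndarray] = {0: np.eye(self.k), 1: Q}
        self._log_powers: dict[int, np.ndarray] = {}
        self._closed_form = (
            spec is not None and spec.family == "two_state"
            and (spec.params["q12"] + spec.params["q21"]) > 0
        )

    def power(self, t: int) -> np.ndarray:
        if t < 0 or t != int(t):
            raise ValueError(f"matrix power needs a nonnegative integer t, got {t}")
        t = int(t)
        cached = self._powers.get(t)
        if cached is not None:
            return cached
        if self._closed_form:
            q12, q21 = self.spec.params["q12"], self.spec.params["q21"]
            lam = 1.0 - q12 - q21
            pi1 = q21 / (q12 + q21)
            pi2 = q12 / (q12 + q21)
            lt = lam**t
            out = np.array([
                [pi1 + pi2 * lt, pi2 - pi2 * lt],
                [pi1 - pi1 * lt, pi2 + pi1 * lt],
            ])
        else:
            # exact binary exponentiation
            half = self.power(t // 2)
            out = half @ half
            if t % 2:
                out = out @ self.Q
        self._powers[t] = out
        return out

    def log_power(self, t: int) -> np.ndarray:
        """Elementwise log of Q^t (cached; -inf where the entry is 0)."""
        out = self._log_powers.get(t)
        if out is None:
            with np.errstate(divide="ignore"):
                out = np.log(np.maximum(self.power(t), 0.0))
            self._log_powers[t] = out
        return out

    def stationary(self) -> np.ndarray:
        return stationary_distribution(self)

    def root_prior_vector(self) -> np.ndarray:
        """Prior over the ancestral state S per the spec's root_prior mode."""
        mode = self.spec.root_prior if self.spec is not None else "stationary"
        if mode == "stationary":
            return self.stationary()
        if mode == "uniform":
            return np.full(self.k, 1.0 / self.k)
        if mode == "fixed":
            v = np.zeros(self.k)
            v[self.spec.root_state] = 1.0
            return v
        raise ValidationError(f"unknown root prior mode {mode!r}")


def mutation_matrix(spec: MutationSpec) -> MutationMatrix:
    """Realize a :class:`MutationSpec` as its row-stochastic matrix Q."""
    k = spec.k
    if spec.family == "uniform":
        mu = spec.params["mu"]
        if not 0.0 <= mu <= 1.0:
            raise ValidationError(f"uniform mutation needs 0 <= mu <= 1, got {mu}")
        Q = np.full((k, k), mu / (k - 1) if k > 1 else 0.0)
        np.fill_diagonal(Q, 1.0 - mu)
    elif spec.family == "two_state":
        q12, q21 = spec.params["q12"], spec.params["q21"]
        if not (0.0 <= q12 <= 1.0 and 0.0 <= q21 <= 1.0):
            raise ValidationError(
                f"two-state rates must lie in [0, 1]; got q12={q12}, q21={q21}"
            )
        Q = np.array([[1.0 - q12, q12], [q21, 1.0 - q21]])
    elif spec.family == "explicit":
        Q = np.asarray(spec.matrix, dtype=float)
        if Q.shape != (k, k):
            raise ValidationError(f"explicit Q must be {k}x{k}, got {Q.shape}")
    else:
        raise ValidationError(f"unknown mutation family {spec.family!r}")
    return MutationMatrix(Q, spec)


def matrix_power(Q: MutationMatrix | np.ndarray, t: int) -> np.ndarray:
    """Q^t for a nonnegative integer t (memoized on MutationMatrix objects)."""
    if not isinstance(Q, MutationMatrix):
        Q = MutationMatrix(Q)
    return Q.power(t)


def stationary_distribution(Q: MutationMatrix | np.ndarray) -> np.ndarray:
    """Stationary distribution pi of Q (dominant left eigenvector, pi Q = pi).

    Raises :class:`ValidationError` when the chain is reducible or absorbing,
    in which case the stationary root prior is undefined and the caller must
    supply a fixed or uniform prior instead.
    """
    mat = Q.Q if isinstance(Q, MutationMatrix) else np.asarray(Q, dtype=float)
    _check_rows(mat, "mutation matrix")
    k = mat.shape[0]
    vals, vecs = np.linalg.eig(mat.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, idx])
    pi = pi / pi.sum()
    # a valid stationary prior must be strictly positive and unique
    ones = np.isclose(np.abs(vals), 1.0, atol=1e-10).sum()
    if ones > 1 or np.any(pi <= 1e-300) or np.any(np.isnan(pi)):
        raise ValidationError(
            "mutation chain is reducible/absorbing; stationary root prior "
            "undefined — supply a fixed or uniform root prior"
        )
    resid = np.max(np.abs(pi @ mat - pi))
    if resid > 1e-8:
        raise ValidationError(f"stationary solve failed (residual {resid:g})")
    return pi
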