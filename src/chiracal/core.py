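"""Scalar-triple-product chirality of an ordered point chain.

The handedness of a discrete curve — here the Calpha trace of a protein
secondary-structure element — is quantified by summing the scalar triple
(mixed) products of consecutive difference vectors:

    chi_total = sum_i  (v_i x v_{i+1}) . v_{i+2}

where ``v_i`` are the vectors between successive reference points.  Each
triple product is the signed volume of the parallelepiped spanned by three
consecutive steps: positive for a right-handed local twist, negative for a
left-handed one, zero when the three steps are coplanar.

``chi_norm`` divides every triple product by the 5th power of the mean
length of its three vectors.  The exponent 5 is the unique choice that keeps
the measure finite and nonzero as the density of reference points on a fixed
helix grows without bound (see :mod:`chiracal.helix` for the derivation's
closed form and the scaling study that pins k = 5).

Units: with coordinates in Angstrom, ``chi_total`` is in A^3 and ``chi_norm``
(k = 5) in A^-2.  Dipole-moment applications (Debye) live in
:mod:`chiracal.dipole`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "PointChain",
    "ChiralityResult",
    "Handedness",
    "difference_vectors",
    "mixed_product",
    "chi_total",
    "normalization_factor",
    "chi_norm",
    "classify_handedness",
    "evaluate_chain",
    "stepwise_chirality",
]

#: Default threshold below which |chi_norm| is called achiral.  The measure
#: of a genuinely chiral structure is many orders of magnitude larger; this
#: only absorbs floating-point noise on exactly planar inputs.
DEFAULT_EPSILON = 1e-9


@dataclass(frozen=True)
class PointChain:
    """Ordered reference points of one structural element.

    Parameters
    ----------
    coords
        Array-like of shape (n, 3): Calpha positions in Angstrom, in chain
        order (N- to C-terminal for proteins).  Order is preserved exactly
        as given; it determines the sign of the measure.
    labels
        Optional per-point residue identifiers, e.g. ``("A", 8, "", "SER")``
        tuples of (chain id, residue number, insertion code, residue name).
    """

    coords: np.ndarray
    labels: tuple = ()

    def __init__(self, coords, labels: Sequence = ()):  # noqa: D107
        arr = np.asarray(coords, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise InvalidInputError(
                f"coords must have shape (n, 3), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("coordinates must be finite")
        if labels and len(labels) != len(arr):
            raise InvalidInputError(
                f"{len(labels)} labels for {len(arr)} points"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)
        object.__setattr__(self, "labels", tuple(labels))

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_triples(self) -> int:
        """Number of consecutive-vector triples: max(n_points - 3, 0)."""
        return max(len(self) - 3, 0)

    def reversed(self) -> "PointChain":
        """Chain traversed in the opposite order.

        The chirality measure is invariant under reversal: each difference
        vector is negated (factor (-1)^3 per triple) and the triple order
        is transposed (factor -1), which cancel — a helix traversed from
        either end has the same handedness.
        """
        return PointChain(self.coords[::-1].copy(), self.labels[::-1])

    def mirrored(self) -> "PointChain":
        """Reflection through the xy-plane (z -> -z): the enantiomer."""
        m = self.coords.copy()
        m[:, 2] *= -1.0
        return PointChain(m, self.labels)


@dataclass(frozen=True)
class Handedness:
    """Sign classification of a chirality value."""

    sign: str    # "positive" | "negative" | "zero"
    symbol: str  # "D" | "L" | "achiral"


@dataclass(frozen=True)
class ChiralityResult:
    """Total and normalized chirality of one element."""

    chi_total: float  # A^3
    chi_norm: float   # A^-2 for k = 5
    n_points: int
    n_triples: int
    sign: str
    symbol: str


def difference_vectors(chain: PointChain) -> np.ndarray:
    """Vectors between successive reference points, ``v_i = p_{i+1} - p_i``.

    Returns an (n-1, 3) array.  Raises :class:`DegenerateGeometryError` if
    any step has zero length (duplicated points), naming the offending index.
    """
    if len(chain) < 2:
        raise InvalidInputError(
            f"need at least 2 points for difference vectors, got {len(chain)}"
        )
    vecs = np.diff(chain.coords, axis=0)
    lengths = np.linalg.norm(vecs, axis=1)
    zero = np.flatnonzero(lengths == 0.0)
    if zero.size:
        i = int(zero[0])
        raise DegenerateGeometryError(
            f"zero-length difference vector at step {i} "
            f"(points {i} and {i + 1} coincide)"
        )
    return vecs


def mixed_product(a, b, c) -> float:
    """Scalar triple product (a x b) . c.

    Signed volume of the parallelepiped on the three vectors; the sign
    encodes the handedness of the frame (right-handed positive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    return float(np.dot(np.cross(a, b), c))


def _triple_products(vecs: np.ndarray) -> np.ndarray:
    """Mixed products of all consecutive vector triples (vectorized)."""
    return np.einsum(
        "ij,ij->i", np.cross(vecs[:-2], vecs[1:-1]), vecs[2:]
    )


def chi_total(chain: PointChain) -> float:
    """Sum of mixed products over consecutive difference-vector triples.

    Exactly 0.0 for chains of fewer than 4 points (no triple exists).
    """
    if len(chain) < 4:
        return 0.0
    return float(_triple_products(difference_vectors(chain)).sum())


def normalization_factor(v_i, v_ip1, v_ip2, k: int = 5) -> float:
    """k-th power of the mean length of three consecutive vectors.

    ``C_i = ((|v_i| + |v_{i+1}| + |v_{i+2}|) / 3) ** k``; strictly positive.
    """
    lengths = [float(np.linalg.norm(np.asarray(v, dtype=float)))
               for v in (v_i, v_ip1, v_ip2)]
    if min(lengths) == 0.0:
        raise DegenerateGeometryError("zero-length vector in normalization")
    return (sum(lengths) / 3.0) ** k


def _norm_factors(vecs: np.ndarray, k: int) -> np.ndarray:
    lengths = np.linalg.norm(vecs, axis=1)
    means = (lengths[:-2] + lengths[1:-1] + lengths[2:]) / 3.0
    return means ** k


def chi_norm(chain: PointChain, k: int = 5) -> float:
    """Normalized chirality: each triple product divided by its own C_i.

    The normalization is per-triple (each mixed product divided by the k-th
    power of the mean length of its three vectors), so chains with uneven
    step lengths — turns and loops — are handled without assuming a common
    step.  On a uniform-step helix this coincides with dividing the total by
    step_length**k.  Returns 0.0 for chains of fewer than 4 points.
    """
    if len(chain) < 4:
        return 0.0
    vecs = difference_vectors(chain)
    return float((_triple_products(vecs) / _norm_factors(vecs, k)).sum())


def classify_handedness(value: float, epsilon: float = DEFAULT_EPSILON) -> Handedness:
    """Map a signed chirality value to (sign, D/L symbol).

    Positive values are right-handed (D), negative left-handed (L); values
    within ``epsilon`` of zero are achiral.
    """
    if epsilon < 0:
        raise InvalidInputError("epsilon must be >= 0")
    if value > epsilon:
        return Handedness("positive", "D")
    if value < -epsilon:
        return Handedness("negative", "L")
    return Handedness("zero", "achiral")


def evaluate_chain(
    chain: PointChain, k: int = 5, epsilon: float = DEFAULT_EPSILON
) -> ChiralityResult:
    """Full chirality evaluation of one element: totals plus classification."""
    total = chi_total(chain)
    norm = chi_norm(chain, k=k)
    hand = classify_handedness(norm, epsilon)
    return ChiralityResult(
        chi_total=total,
        chi_norm=norm,
        n_points=len(chain),
        n_triples=chain.n_triples,
        sign=hand.sign,
        symbol=hand.symbol,
    )


def stepwise_chirality(
    chain: PointChain, normalized: bool = True, k: int = 5
) -> pd.DataFrame:
    """Chirality accumulation over growing prefixes of the chain.

    One row per prefix length 1..n with columns ``n_residues``,
    ``n_vectors``, ``n_triples``, ``step_addition`` (the newly available
    triple's contribution; 0.0 while fewer than 4 points are available) and
    ``running_total`` (cumulative sum).  The last running total equals
    :func:`chi_norm` (or :func:`chi_total`) of the full chain — the sum
    telescopes.  Useful for tracing how an irregular element such as an
    omega-loop alternates between right- and left-handed increments.
    """
    if len(chain) < 1:
        raise InvalidInputError("chain must have at least 1 point")
    n = len(chain)
    additions = np.zeros(n)
    if n >= 4:
        vecs = difference_vectors(chain)
        terms = _triple_products(vecs)
        if normalized:
            terms = terms / _norm_factors(vecs, k)
        additions[3:] = terms
    return pd.DataFrame(
        {
            "n_residues": np.arange(1, n + 1),
            "n_vectors": np.maximum(np.arange(n), 0),
            "n_triples": np.maximum(np.arange(-2, n - 2), 0),
            "step_addition": additions,
            "running_total": np.cumsum(additions),
        }
    )
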