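"""Rating-scale specification and extreme-response-style scoring weights.

A K-point Likert-type scale is described by its category count K (categories
labeled 1..K) and a vector of ERS scoring weights ``s`` that encodes which
categories count as "extreme" versus "middle".  The default weights are the
distance of each category from the scale midpoint, ``s_k = |k - (K+1)/2|``,
which makes a positive ERS trait equivalent to symmetric outward shifts of
the item thresholds (see :func:`erspcm.pcm.shifted_thresholds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RatingScaleSpec", "ers_scoring_weights", "UnidentifiableERSError"]


class UnidentifiableERSError(ValueError):
    """Raised when the ERS dimension cannot be identified on the given scale."""


def ers_scoring_weights(K: int, kind: str = "graded") -> np.ndarray:
    """Return ERS scoring weights for a K-category scale.

    Parameters
    ----------
    K : int
        Number of response categories (labeled 1..K). Must be >= 3; on a
        binary scale every weight vector satisfying the symmetry constraint
        is constant, so the ERS dimension is unidentified.
    kind : {"graded", "binary"}
        "graded" gives distance-from-midpoint weights ``|k - (K+1)/2|``,
        which correspond to unit symmetric threshold shifts per unit of the
        ERS trait. "binary" scores only the two outermost categories 1/K
        with weight 1 and everything else 0.

    Returns
    -------
    numpy.ndarray of shape (K,)
    """
    K = int(K)
    if K < 3:
        raise UnidentifiableERSError(
            f"ERS scoring requires K >= 3 categories (got K={K}); on a binary "
            "scale the symmetric weight vector is constant and the ERS "
            "dimension is unidentified."
        )
    k = np.arange(1, K + 1, dtype=float)
    if kind == "graded":
        return np.abs(k - (K + 1) / 2.0)
    if kind == "binary":
        s = np.zeros(K)
        s[0] = s[-1] = 1.0
        return s
    raise ValueError(f"unknown ERS weight kind: {kind!r}")


@dataclass(frozen=True)
class RatingScaleSpec:
    """K-point rating scale with ERS scoring weights.

    Invariants (checked at construction): symmetry ``s_k == s_{K+1-k}``,
    non-negative weights, non-increasing up to the midpoint with the minimum
    attained there.
    """

    K: int
    s: np.ndarray = field(default=None)  # type: ignore[assignment]
    weight_kind: str = "graded"

    def __post_init__(self) -> None:
        object.__setattr__(self, "K", int(self.K))
        if self.K < 2:
            raise ValueError(f"need at least 2 response categories, got K={self.K}")
        if self.s is None:
            # binary scale: constant (zero) weights — the plain PCM still
            # works, but the ERS dimension is unidentified (see ers_identified)
            s0 = (
                np.zeros(2)
                if self.K == 2
                else ers_scoring_weights(self.K, self.weight_kind)
            )
            object.__setattr__(self, "s", s0)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        self._validate()

    @property
    def ers_identified(self) -> bool:
        """ERS needs K >= 3 and non-constant weights."""
        return self.K >= 3 and float(np.ptp(self.s)) > 0

    def _validate(self) -> None:
        K, s = self.K, self.s
        if s.shape != (K,):
            raise ValueError(f"weight vector has length {s.shape}, expected ({K},)")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("ERS weights must be finite and >= 0")
        if not np.allclose(s, s[::-1]):
            raise ValueError("ERS weights must be symmetric: s_k == s_{K+1-k}")
        mid = (K - 1) // 2  # 0-based index of (lower) midpoint category
        head = s[: mid + 1]
        if np.any(np.diff(head) > 1e-12):
            raise ValueError("ERS weights must be non-increasing up to the midpoint")
        if abs(min(s[mid], s[K - 1 - mid]) - s.min()) > 1e-12:
            raise ValueError("minimum ERS weight must be attained at the midpoint")

    @property
    def n_thresholds(self) -> int:
        """Number of item thresholds J = K - 1."""
        return self.K - 1

    @property
    def categories(self) -> np.ndarray:
        """Category labels 1..K."""
        return np.arange(1, self.K + 1)

    @property
    def extreme_mask(self) -> np.ndarray:
        """Boolean mask of categories with maximal ERS weight (the outer pair)."""
        return self.s == self.s.max()

    def threshold_shift_directions(self) -> np.ndarray:
        """Per-threshold shift direction d_j = s_j - s_{j+1} (length K-1)."""
        return -np.diff(self.s)
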