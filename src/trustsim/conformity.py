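"""Conformity machinery: pairwise belief distances, the distance-weighted group
norm, and the conformity-modulated learning rate.

Under conformity, an agent's learning rate equals the absolute deviation of its
belief from the group norm, where the norm is a weighted average of the group's
beliefs with weights inversely proportional to each member's total absolute
distance from all peers:

    d_i = sum_k |rho_i - rho_k|
    norm = sum_i rho_i / d_i  /  sum_i 1 / d_i

Members whose beliefs sit close to everyone else's carry the most weight, so
behavior is "sticky" around the norm: agents near it have learning rates near
zero and effectively stop updating.

Robustness variants weight by the inverse distance from the arithmetic group
mean or median instead of the full pairwise distance profile.

``total_distance`` and :class:`NormState` evaluate all d_i in one pass over the
sorted belief vector (prefix sums) rather than the O(n^2) all-pairs sum; tests
verify equivalence against the brute-force definition.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "EPS_D",
    "total_distance",
    "all_total_distances",
    "group_norm",
    "learning_rate",
    "NormState",
    "NormStateError",
]

# Floor substituted for vanishing distances (degenerate-weight rule).
EPS_D = 1e-12

_VARIANTS = ("inverse_pairwise_distance", "distance_from_mean", "distance_from_median")


class NormStateError(RuntimeError):
    """Incremental norm state failed a from-scratch consistency audit."""


def _as_beliefs(beliefs) -> np.ndarray:
    arr = np.asarray(beliefs, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("beliefs must be a non-empty 1-d vector")
    return arr


def all_total_distances(beliefs) -> np.ndarray:
    """Vector of d_i = sum_k |b_i - b_k| for every member, in O(n log n)."""
    arr = _as_beliefs(beliefs)
    m = arr.size
    if m == 1 or arr.min() == arr.max():
        return np.zeros(m)
    order = np.argsort(arr, kind="stable")
    srt = arr[order]
    prefix = np.cumsum(srt)
    total = prefix[-1]
    ranks = np.arange(1, m + 1)
    # clamp the cancellation residue the closed form leaves on exact ties
    d_sorted = np.maximum((2.0 * ranks - m) * srt - 2.0 * prefix + total, 0.0)
    d = np.empty(m)
    d[order] = d_sorted
    return d


def total_distance(beliefs, i: int) -> float:
    """Total absolute belief distance of member ``i`` from all group members."""
    arr = _as_beliefs(beliefs)
    if not (0 <= i < arr.size):
        raise IndexError(f"member index {i} out of range for group of {arr.size}")
    return float(all_total_distances(arr)[i])


def group_norm(beliefs, variant: str = "inverse_pairwise_distance") -> float:
    """Distance-weighted average belief of a group (the group norm)."""
    arr = _as_beliefs(beliefs)
    if variant not in _VARIANTS:
        raise ValueError(f"unknown norm variant {variant!r}")
    m = arr.size
    if m == 1:
        return float(arr[0])
    if np.all(arr == arr[0]):
        return float(arr[0])
    if variant == "inverse_pairwise_distance":
        d = np.maximum(all_total_distances(arr), EPS_D)
    else:
        center = np.mean(arr) if variant == "distance_from_mean" else np.median(arr)
        d = np.abs(arr - center) + EPS_D
    w = 1.0 / d
    return float(np.sum(w * arr) / np.sum(w))


def learning_rate(belief: float, norm: float) -> float:
    """Conformity learning rate: absolute deviation of a belief from the norm."""
    if not (0.0 <= belief <= 1.0 and 0.0 <= norm <= 1.0):
        raise ValueError("belief and norm must lie in [0, 1]")
    return abs(belief - norm)


class NormState:
    """Incrementally maintained norm state for one directed group belief vector.

    Keeps the member belief vector together with a sorted copy, so single-member
    updates cost one O(n) memmove and norm/distance queries cost one linear
    prefix-sum pass (the O(n^2) pairwise sum is never formed).

    Parameters
    ----------
    beliefs : array-like
        Initial member beliefs toward the target group.
    variant : str
        Norm variant tag; see :func:`group_norm`.
    """

    def __init__(self, beliefs, variant: str = "inverse_pairwise_distance"):
        if variant not in _VARIANTS:
            raise ValueError(f"unknown norm variant {variant!r}")
        self.beliefs = _as_beliefs(beliefs).copy()
        self.variant = variant
        self._sorted = np.sort(self.beliefs)

    def __len__(self) -> int:
        return self.beliefs.size

    def distances(self) -> np.ndarray:
        """Current vector of total pairwise distances d_i."""
        return all_total_distances(self.beliefs)

    def norm(self) -> float:
        """Current group norm value."""
        arr = self._sorted
        m = arr.size
        if m == 1 or arr[0] == arr[-1]:
            return float(arr[0])
        if self.variant == "inverse_pairwise_distance":
            ranks = np.arange(1, m + 1)
            prefix = np.cumsum(arr)
            d = (2.0 * ranks - m) * arr - 2.0 * prefix + prefix[-1]
            d = np.maximum(d, EPS_D)
        else:
            if self.variant == "distance_from_mean":
                center = float(np.mean(arr))
            else:
                h = m // 2
                center = float(arr[h]) if m % 2 else float(0.5 * (arr[h - 1] + arr[h]))
            d = np.abs(arr - center) + EPS_D
        w = 1.0 / d
        return float(np.sum(w * arr) / np.sum(w))

    def learning_rate(self, member: int) -> float:
        """Conformity learning rate of ``member`` given the current norm."""
        return abs(float(self.beliefs[member]) - self.norm())

    def update(self, member: int, new_belief: float) -> "NormState":
        """Apply a single-member belief change in place; returns self."""
        if not (0 <= member < self.beliefs.size):
            raise IndexError("member index out of range")
        if not (0.0 <= new_belief <= 1.0):
            raise ValueError("belief must lie in [0, 1]")
        old = float(self.beliefs[member])
        if new_belief == old:
            return self
        self.beliefs[member] = new_belief
        srt = self._sorted
        i = int(np.searchsorted(srt, old))
        j = int(np.searchsorted(srt, new_belief))
        if new_belief >= old:
            # target slot after removing the old element at i
            j = j - 1 if j > i else j
            srt[i:j] = srt[i + 1:j + 1]
            srt[j] = new_belief
        else:
            srt[j + 1:i + 1] = srt[j:i]
            srt[j] = new_belief
        return self

    def audit(self) -> None:
        """Verify the sorted copy against a from-scratch recomputation."""
        ref = np.sort(self.beliefs)
        if not np.array_equal(self._sorted, ref):
            raise NormStateError("sorted belief copy diverged from member beliefs")
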