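"""Circular index arithmetic on the face morph wheel.

The stimulus space is a closed continuum of ``n_points`` facial morphs built
by interpolating between three anchor identities (46 intermediate morphs per
segment, 3 + 3 x 46 = 141 images in total).  All stimulus similarity in the
analysis is measured here, in *morph steps* along the wheel: the signed
circular distance between two wheel indices, the signed adjustment error of a
reproduced face, and the close/middle/far distance-range bin of a trial.

Sign convention: clockwise = increasing index modulo ``n_points``.  The wheel
has no intrinsic orientation, so the convention is arbitrary; the behavioral
bias statistic fixes the global sign via its attraction-positive contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MorphWheel",
    "signed_circular_distance",
    "adjustment_error",
    "assign_distance_bin",
    "BIN_EDGES",
]

#: Distance-range bins in absolute morph steps (inclusive bounds).
#: Each bin spans 23 absolute distances; |delta| = 0 and |delta| >= 70 are
#: excluded so that the three bins are even.
BIN_EDGES = {"close": (1, 23), "middle": (24, 46), "far": (47, 69)}


@dataclass(frozen=True)
class MorphWheel:
    """The circular morph continuum.

    Parameters
    ----------
    n_points : int
        Number of morphs on the wheel.  Must be odd so that no pair of
        indices is exactly antipodal (which would make the sign of the
        circular distance ambiguous).
    anchor_indices : tuple of int
        Indices of the original (non-morphed) identities; equally spaced.
    """

    n_points: int = 141
    anchor_indices: tuple[int, ...] = (0, 47, 94)

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.n_points % 2 == 0:
            raise ValueError(
                "even wheel sizes are unsupported: antipodal pairs have no "
                "unique signed distance"
            )
        anchors = np.asarray(self.anchor_indices)
        if np.any((anchors < 0) | (anchors >= self.n_points)):
            raise ValueError("anchor indices out of range")
        if len(anchors) > 1:
            spacing = np.diff(np.sort(anchors))
            if not np.all(spacing == self.n_points // len(anchors)):
                raise ValueError("anchors must be equally spaced on the wheel")

    @property
    def max_distance(self) -> int:
        """Largest attainable absolute signed distance, floor(n/2)."""
        return self.n_points // 2

    def distance(self, a, b):
        """Signed circular distance from ``b`` to ``a`` on this wheel."""
        return signed_circular_distance(a, b, self.n_points)


def _check_indices(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{name} must contain integer wheel indices")
        arr = arr.astype(np.int64)
    if np.any((arr < 0) | (arr >= n)):
        raise ValueError(f"{name} out of range [0, {n})")
    return arr.astype(np.int64)


def signed_circular_distance(a, b, n: int = 141):
    """Minimal signed displacement from index ``b`` to index ``a`` on a wheel.

    Positive values are clockwise (increasing index), negative counter-
    clockwise.  The result lies in ``[-(n//2), n//2]``; for odd ``n`` the
    shorter arc is unique, so ``distance(a, b) == -distance(b, a)`` whenever
    ``a != b``.

    Parameters
    ----------
    a, b : int or array-like of int
        Wheel indices in ``[0, n)``.
    n : int
        Wheel size; must be odd.

    Returns
    -------
    int or ndarray of int
        ``((a - b + n//2) mod n) - n//2``.
    """
    if n % 2 == 0:
        raise ValueError("even wheel sizes are unsupported (antipodal ties)")
    half = n // 2
    aa = _check_indices(a, n, "a")
    bb = _check_indices(b, n, "b")
    delta = np.mod(aa - bb + half, n) - half
    if np.isscalar(a) and np.isscalar(b):
        return int(delta)
    return delta


def adjustment_error(response, target, n: int = 141):
    """Signed adjustment error of a reproduced face, in morph steps.

    The error is the signed circular distance from the target to the
    response: zero iff the response equals the target, positive if the
    response lies clockwise of it.
    """
    return signed_circular_distance(response, target, n)


def assign_distance_bin(delta, n: int = 141):
    """Map signed distances to distance-range bins.

    ``close`` is |delta| in 1..23, ``middle`` 24..46, ``far`` 47..69;
    |delta| = 0 (no inducer-target separation, hence no clockwise /
    counterclockwise direction) and |delta| >= 70 (trimmed so the three bins
    are even) are ``excluded``.

    Parameters
    ----------
    delta : int or array-like of int
        Signed distances with ``|delta| <= n // 2``.

    Returns
    -------
    str or ndarray of str
    """
    arr = np.abs(np.asarray(delta, dtype=np.int64))
    if np.any(arr > n // 2):
        raise ValueError(f"|delta| exceeds the wheel's maximum distance {n // 2}")
    out = np.full(arr.shape, "excluded", dtype="U8")
    for label, (lo, hi) in BIN_EDGES.items():
        out[(arr >= lo) & (arr <= hi)] = label
    if np.isscalar(delta) or np.ndim(delta) == 0:
        return str(out[()])
    return out
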