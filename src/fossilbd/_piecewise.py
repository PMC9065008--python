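"""Piecewise-constant functions of geological age.

Ages are in Ma before present (present = 0, larger = older).  A step
function is defined by strictly decreasing interior break ages and one
value per segment, ordered old -> young.  Segments are half-open
``(younger_break, older_break]`` — i.e. a break age belongs to the
segment on its *younger* side, matching the time-bin convention used
throughout the package (an age equal to a bin boundary falls in the bin
whose older edge it is).  Age 0 always belongs to the youngest segment.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = ["StepFunction", "bin_index", "one_myr_bins", "CENOZOIC_EPOCHS"]

#: Cenozoic epoch boundaries in Ma (Holocene merged into the Pleistocene).
CENOZOIC_EPOCHS = (66.0, 56.0, 33.9, 23.03, 5.333, 2.58, 0.0)


class StepFunction:
    """Piecewise-constant function of age.

    Parameters
    ----------
    breaks_desc : array-like
        Strictly decreasing interior break ages (Ma); may be empty.
    values_desc : array-like
        Segment values ordered oldest segment first; ``len(values) ==
        len(breaks) + 1``.  ``values_desc[0]`` applies for ages older
        than ``breaks_desc[0]``; ``values_desc[-1]`` for ages at or
        below ``breaks_desc[-1]``.
    """

    __slots__ = ("breaks_desc", "values_desc", "_asc", "_vals_asc")

    def __init__(self, breaks_desc, values_desc):
        b = np.atleast_1d(np.asarray(breaks_desc, dtype=float))
        v = np.atleast_1d(np.asarray(values_desc, dtype=float))
        if b.size == 0:
            b = b.reshape(0)
        if b.size and np.any(np.diff(b) >= 0):
            raise DomainError("break ages must be strictly decreasing")
        if v.size != b.size + 1:
            raise DomainError(
                f"need exactly {b.size + 1} values for {b.size} breaks, got {v.size}"
            )
        self.breaks_desc = b
        self.values_desc = v
        self._asc = b[::-1].copy()
        self._vals_asc = v[::-1].copy()

    @classmethod
    def constant(cls, value: float) -> "StepFunction":
        return cls(np.empty(0), [value])

    def at(self, t):
        """Evaluate at age(s) ``t`` (scalar or array)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._asc, t, side="left")
        out = self._vals_asc[idx]
        return out if out.ndim else float(out)

    def integral(self, lo, hi):
        """Exact integral over the age interval ``[lo, hi]`` (lo <= hi)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        return self._cumulative(hi) - self._cumulative(lo)

    def _cumulative(self, t):
        """Integral from age 0 up to age t (vectorized)."""
        asc = self._asc
        vals = self._vals_asc
        edges = np.concatenate([[0.0], asc])
        widths = np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(vals[: asc.size] * widths)])
        idx = np.searchsorted(asc, t, side="left")
        base = cum[idx]
        lower = edges[idx]
        return base + vals[idx] * (t - lower)

    def __eq__(self, other):
        if not isinstance(other, StepFunction):
            return NotImplemented
        return np.array_equal(self.breaks_desc, other.breaks_desc) and np.array_equal(
            self.values_desc, other.values_desc
        )

    def __repr__(self):
        return f"StepFunction(breaks={self.breaks_desc!r}, values={self.values_desc!r})"


def merge_step(f: StepFunction, g: StepFunction, op) -> StepFunction:
    """Combine two step functions with a binary operation, exactly."""
    breaks = np.union1d(f.breaks_desc, g.breaks_desc)[::-1]
    edges = np.concatenate([[np.inf], breaks, [0.0]])
    mids = np.where(
        np.isinf(edges[:-1]), edges[1:] + 1.0, 0.5 * (edges[:-1] + edges[1:])
    )
    # midpoint of each segment identifies it unambiguously
    values = op(f.at(mids), g.at(mids))
    return StepFunction(breaks, values)


def bin_index(ages, bounds_desc):
    """Map ages to time-bin indices.

    ``bounds_desc`` are strictly decreasing bin boundaries; bin ``i``
    (counted 0 = youngest) spans ``(bounds_asc[i], bounds_asc[i+1]]``,
    with the youngest bin closed at both ends so that the youngest
    boundary (usually 0) is included.

    Returns integer indices relative to the *ascending* boundary order.
    Raises :class:`DomainError` for ages outside the boundary span.
    """
    bounds = np.asarray(bounds_desc, dtype=float)
    if np.any(np.diff(bounds) >= 0):
        raise DomainError("bin boundaries must be strictly decreasing")
    asc = bounds[::-1]
    a = np.asarray(ages, dtype=float)
    if np.any(a < asc[0]) or np.any(a > asc[-1]):
        raise DomainError("age outside bin boundary span")
    idx = np.searchsorted(asc, a, side="left") - 1
    idx = np.maximum(idx, 0)
    return idx


def one_myr_bins(max_age: float):
    """Descending 1-Myr bin boundaries from ``ceil(max_age)`` down to 0."""
    top = int(np.ceil(max_age))
    if top <= 0:
        raise DomainError("max_age must be positive")
    return np.arange(top, -1, -1, dtype=float)
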