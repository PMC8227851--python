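"""Quantitative eye-colour scores and their categorisation.

The PIE-score (pixel index of the eye) summarises an iris photograph as
``(blue - brown) / (blue + brown)`` pixel counts, so 1 is a fully blue iris
and -1 a fully brown one.  For modelling, the bounded score ``r`` is mapped
to an unbounded working scale by ``y = logit(0.5 + 0.499 r)``; the 0.499
factor keeps the logit argument inside [0.001, 0.999] so the endpoints map
to finite values (``y(1) = ln 999``) and the map has an exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "pie_from_pixel_counts",
    "transform_pie",
    "inverse_transform",
    "CategorySystem",
    "TWO_CATEGORY",
    "THREE_CATEGORY",
    "categorise_pie",
]

_SQUEEZE = 0.499


def pie_from_pixel_counts(blue_pixels, brown_pixels):
    """PIE-score from blue/brown pixel counts of a segmented iris image.

    Parameters
    ----------
    blue_pixels, brown_pixels : int or array-like
        Non-negative pixel counts; at least one must be positive.

    Returns
    -------
    float or ndarray
        ``(blue - brown) / (blue + brown)`` in [-1, 1].
    """
    b = np.asarray(blue_pixels, dtype=float)
    w = np.asarray(brown_pixels, dtype=float)
    if np.any(b < 0) or np.any(w < 0):
        raise ValueError("pixel counts must be non-negative")
    total = b + w
    if np.any(total == 0):
        raise ValueError("PIE-score undefined: no blue or brown pixels")
    out = (b - w) / total
    return float(out) if out.ndim == 0 else out


def _check_pie_domain(r: np.ndarray) -> None:
    if np.any(r < -1.0) or np.any(r > 1.0):
        raise ValueError("PIE-score outside [-1, 1]")


def transform_pie(r):
    """Map PIE-score(s) ``r`` in [-1, 1] to the unbounded working scale.

    ``y = logit(0.5 + 0.499 r)`` with the natural logarithm; finite for the
    whole closed interval, ``transform_pie(0) == 0``.
    """
    arr = np.asarray(r, dtype=float)
    _check_pie_domain(arr)
    q = 0.5 + _SQUEEZE * arr
    y = np.log(q) - np.log1p(-q)
    return float(y) if y.ndim == 0 else y


def inverse_transform(y):
    """Inverse of :func:`transform_pie`; maps any real ``y`` into (-1, 1).

    (The closed endpoints +/-1 are recovered exactly for y = +/- ln 999.)
    """
    arr = np.asarray(y, dtype=float)
    q = 1.0 / (1.0 + np.exp(-arr))  # expit
    r = (q - 0.5) / _SQUEEZE
    r = np.clip(r, -1.0, 1.0)  # guard 1/0.499 overshoot for |y| > ln 999
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class CategorySystem:
    """A reporting system: ordered labels and PIE-score boundaries.

    ``categorise`` is total on [-1, 1]; boundary conventions are closed
    exactly as defined (two-category: r <= 0.2 is brown; three-category:
    blue iff r > 0.8, brown iff r < -0.5, intermediate in between,
    endpoints included).
    """

    name: str
    labels: tuple = ()
    thresholds: tuple = ()

    def categorise(self, r) -> "str | np.ndarray":
        arr = np.asarray(r, dtype=float)
        _check_pie_domain(arr)
        if self.name == "two_category":
            out = np.where(arr > self.thresholds[0], "blue", "brown")
        elif self.name == "three_category":
            hi, lo = self.thresholds
            out = np.where(arr > hi, "blue", np.where(arr < lo, "brown", "intermediate"))
        else:  # pragma: no cover - constructed systems only
            raise ValueError(f"unknown category system {self.name!r}")
        return str(out) if out.ndim == 0 else out


TWO_CATEGORY = CategorySystem("two_category", ("blue", "brown"), (0.2,))
THREE_CATEGORY = CategorySystem(
    "three_category", ("blue", "intermediate", "brown"), (0.8, -0.5)
)

_SYSTEMS = {s.name: s for s in (TWO_CATEGORY, THREE_CATEGORY)}


def get_category_system(name: str) -> CategorySystem:
    try:
        return _SYSTEMS[name]
    except KeyError:
        raise ValueError(f"unknown category system {name!r}") from None


def categorise_pie(r, system: "CategorySystem | str"):
    """Categorise PIE-score(s) under a reporting system (object or name)."""
    if isinstance(system, str):
        system = get_category_system(system)
    return system.categorise(r)
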