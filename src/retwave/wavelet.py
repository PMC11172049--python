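"""Exact 2-D Haar multiresolution analysis.

A single analysis level splits a plane ``X`` into four half-resolution
sub-bands by separable filtering with an orthonormal two-tap pair followed
by dyadic downsampling (keep even indices, 0-based)::

    X_l,t+1 = (X_l,t * k_l) |2      (approximation / scaling path)
    X_h,t+1 = (X_l,t * k_h) |2      (detail / wavelet path)

Conventions, fixed once and used everywhere in the package:

* Filters are orthonormal: taps of magnitude ``1/sqrt(2)``, so Parseval's
  identity holds exactly (sub-band energy equals input energy) and the
  inverse transform is the transpose.
* Filtering is correlation with the two-tap kernel anchored at the even
  sample: ``y[n] = (x[2n] + x[2n+1]) / sqrt(2)`` on the low-pass path and
  ``y[n] = (x[2n] - x[2n+1]) / sqrt(2)`` on the high-pass path.
* Sub-band naming is (row filter, column filter): ``lh`` is low-pass along
  rows (axis 0) and high-pass along columns (axis 1); ``hl`` the converse.
* Only even-sized planes are legal; iterated decomposition to depth ``T``
  requires both dimensions divisible by ``2**T``.  No padding is ever
  applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterPair",
    "SubbandSet",
    "MultiresolutionStack",
    "haar_filter_pair",
    "dwt_level",
    "decompose",
    "reconstruct",
    "decompose_multichannel",
]

_ATOL = 1e-12


@dataclass(frozen=True)
class FilterPair:
    """An orthonormal low-pass / high-pass analysis filter pair."""

    kl: np.ndarray
    kh: np.ndarray

    def __post_init__(self) -> None:
        kl = np.asarray(self.kl, dtype=np.float64)
        kh = np.asarray(self.kh, dtype=np.float64)
        object.__setattr__(self, "kl", kl)
        object.__setattr__(self, "kh", kh)
        if kl.ndim != 1 or kh.ndim != 1 or kl.size != kh.size:
            raise ValueError("kl and kh must be 1-D and of equal length")
        if abs(np.dot(kl, kl) - 1.0) > _ATOL or abs(np.dot(kh, kh) - 1.0) > _ATOL:
            raise ValueError("filters must have unit energy (orthonormal convention)")
        if abs(np.dot(kl, kh)) > _ATOL:
            raise ValueError("kl and kh must be orthogonal")


@dataclass
class SubbandSet:
    """The four sub-band planes produced by one analysis level.

    ``ll`` is the approximation X_l,t; ``lh``/``hl``/``hh`` jointly form the
    detail X_h,t.
    """

    level: int
    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be a positive integer")
        shapes = {p.shape for p in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValueError(f"sub-band planes have inconsistent shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ll.shape


@dataclass
class MultiresolutionStack:
    """The full analysis hierarchy: the level-0 plane plus T sub-band sets."""

    original: np.ndarray
    levels: list[SubbandSet] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.levels)


def haar_filter_pair() -> FilterPair:
    """Return the orthonormal Haar pair: kl = (1, 1)/sqrt(2), kh = (1, -1)/sqrt(2)."""
    s = 1.0 / np.sqrt(2.0)
    return FilterPair(kl=np.array([s, s]), kh=np.array([s, -s]))


def _analyze_axis(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Filter-then-downsample along one axis: y[n] = sum_k taps[k] x[2n+k]."""
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    if n % 2:
        raise ValueError(f"axis {axis} has odd length {n}; only even sizes are legal")
    y = sum(taps[k] * x[k::2][: n // 2] for k in range(taps.size))
    # two taps and even length: x[0::2] and x[1::2] both have n//2 samples
    return np.moveaxis(y, 0, axis)


def _synthesize_axis(lo: np.ndarray, hi: np.ndarray, filters: FilterPair, axis: int) -> np.ndarray:
    """Invert :func:`_analyze_axis` for the two-tap orthonormal pair."""
    lo = np.moveaxis(lo, axis, 0)
    hi = np.moveaxis(hi, axis, 0)
    n = lo.shape[0] * 2
    out = np.empty((n,) + lo.shape[1:], dtype=np.result_type(lo, hi))
    # transpose of the analysis operator (orthonormal => inverse)
    out[0::2] = filters.kl[0] * lo + filters.kh[0] * hi
    out[1::2] = filters.kl[1] * lo + filters.kh[1] * hi
    return np.moveaxis(out, 0, axis)


def dwt_level(plane: np.ndarray, filters: FilterPair | None = None, *, level: int = 1) -> SubbandSet:
    """One separable 2-D analysis level: plane -> (ll, lh, hl, hh), each half-sized.

    Parameters
    ----------
    plane
        Real matrix with even height and width (each >= 2).
    filters
        Analysis pair; defaults to the Haar pair.
    level
        Level index recorded on the result (bookkeeping only).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got ndim={plane.ndim}")
    for ax, name in ((0, "height"), (1, "width")):
        if plane.shape[ax] < 2 or plane.shape[ax] % 2:
            raise ValueError(
                f"{name} (axis {ax}) is {plane.shape[ax]}; must be even and >= 2 "
                "(no silent padding is performed)"
            )
    if filters is None:
        filters = haar_filter_pair()
    lo_r = _analyze_axis(plane, filters.kl, axis=0)
    hi_r = _analyze_axis(plane, filters.kh, axis=0)
    return SubbandSet(
        level=level,
        ll=_analyze_axis(lo_r, filters.kl, axis=1),
        lh=_analyze_axis(lo_r, filters.kh, axis=1),
        hl=_analyze_axis(hi_r, filters.kl, axis=1),
        hh=_analyze_axis(hi_r, filters.kh, axis=1),
    )


def max_depth(shape: tuple[int, int]) -> int:
    """Largest T such that both dimensions are divisible by 2**T."""
    t = 0
    h, w = shape
    while h % 2 == 0 and w % 2 == 0 and h >= 2 and w >= 2:
        t += 1
        h //= 2
        w //= 2
    return t


def decompose(plane: np.ndarray, T: int, filters: FilterPair | None = None) -> MultiresolutionStack:
    """Iterate :func:`dwt_level` T times, always recursing on the ``ll`` plane."""
    plane = np.asarray(plane, dtype=np.float64)
    if T < 0:
        raise ValueError("T must be non-negative")
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got ndim={plane.ndim}")
    feasible = max_depth(plane.shape)
    if T > feasible:
        raise ValueError(
            f"shape {plane.shape} is not divisible by 2**{T}; "
            f"maximum feasible depth is T={feasible}"
        )
    stack = MultiresolutionStack(original=plane)
    current = plane
    for t in range(1, T + 1):
        sb = dwt_level(current, filters, level=t)
        stack.levels.append(sb)
        current = sb.ll
    return stack


def reconstruct(stack: MultiresolutionStack, filters: FilterPair | None = None) -> np.ndarray:
    """Invert every level of the stack; returns a matrix shaped like ``original``.

    With orthonormal filters this is exact (perfect reconstruction) and is
    used in the test suite as the round-trip oracle.
    """
    if filters is None:
        filters = haar_filter_pair()
    if not stack.levels:
        return np.array(stack.original, copy=True)
    current = stack.levels[-1].ll
    for sb in reversed(stack.levels):
        if sb.lh.shape != current.shape or sb.hl.shape != current.shape or sb.hh.shape != current.shape:
            raise ValueError(
                f"level {sb.level}: detail planes {sb.lh.shape} do not match "
                f"approximation {current.shape}"
            )
        lo_r = _synthesize_axis(current, sb.lh, filters, axis=1)
        hi_r = _synthesize_axis(sb.hl, sb.hh, filters, axis=1)
        current = _synthesize_axis(lo_r, hi_r, filters, axis=0)
    if current.shape != stack.original.shape:
        raise ValueError(
            f"reconstruction shape {current.shape} does not match original "
            f"{stack.original.shape}"
        )
    return current


def decompose_multichannel(image: np.ndarray, T: int, filters: FilterPair | None = None) -> list[np.ndarray]:
    """Decompose each channel of an H x W x C image independently.

    Returns one array per level t = 1..T of shape ``(4*C, H/2^t, W/2^t)``
    with band-major ordering ``[ll_0..ll_{C-1}, lh_*, hl_*, hh_*]`` —
    the layout consumed by the network's injection points.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError(f"expected H x W x C image, got ndim={image.ndim}")
    stacks = [decompose(image[:, :, c], T, filters) for c in range(image.shape[2])]
    out = []
    for t in range(T):
        planes = [np.stack([getattr(s.levels[t], band) for s in stacks]) for band in ("ll", "lh", "hl", "hh")]
        out.append(np.concatenate(planes, axis=0))
    return out
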