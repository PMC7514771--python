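"""Parametric scattering-coefficient fields.

A medium is the scattering coefficient sigma(x) of the tissue: a positive
baseline plus piecewise-constant inclusions (intervals in 1-D, disks in 2-D).
Inclusions model tissue components whose optical properties differ sharply
from the background, which is the standard idealization in optical
tomography test problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "Media1D",
    "DiskMedia2D",
    "AdmissibilityBounds",
    "AdmissibilityReport",
    "EXAMPLE2_CENTERS",
    "evaluate_sigma",
    "three_bump_medium",
    "make_example_media",
    "check_admissibility",
    "media_to_dict",
    "media_from_dict",
]


@dataclass(frozen=True)
class Media1D:
    """Piecewise-constant medium on [0, 1].

    ``bumps`` is a sequence of ``(a, b, h)`` triples: sigma gains height
    ``h >= 0`` on the closed interval ``[a, b] ⊆ [0, 1]``.
    """

    baseline: float = 1.0
    bumps: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be positive, got {self.baseline}")
        for a, b, h in self.bumps:
            if not (0.0 <= a <= b <= 1.0):
                raise ValueError(f"bump interval [{a}, {b}] not within [0, 1]")
            if h < 0:
                raise ValueError(f"bump height must be nonnegative, got {h}")

    @property
    def dim(self) -> int:
        return 1


@dataclass(frozen=True)
class DiskMedia2D:
    """Disk-inclusion medium on the unit square.

    ``disks`` is a sequence of ``(cx, cy, r, h)``: sigma gains height
    ``h >= 0`` strictly inside the disk |x - c| < r.  Points on the circle
    itself take the baseline value (strict inequality).
    """

    baseline: float = 1.0
    disks: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"baseline must be positive, got {self.baseline}")
        for cx, cy, r, h in self.disks:
            if r < 0:
                raise ValueError(f"disk radius must be nonnegative, got {r}")
            if h < 0:
                raise ValueError(f"disk height must be nonnegative, got {h}")

    @property
    def dim(self) -> int:
        return 2


Media = Union[Media1D, DiskMedia2D]


@dataclass(frozen=True)
class AdmissibilityBounds:
    """Uniform bound C* on sigma, 1/sigma and grad(1/sigma)."""

    c_star: float

    def __post_init__(self) -> None:
        if self.c_star <= 0:
            raise ValueError(f"c_star must be positive, got {self.c_star}")


@dataclass(frozen=True)
class AdmissibilityReport:
    """Discrete-grid check of the admissible-set bound.

    The three sup-norms are evaluated at grid nodes only (the gradient by
    centered differences); media with jumps are not W^{1,inf}, so this is a
    verification aid rather than a gate.
    """

    sigma_inf: float
    inv_sigma_inf: float
    grad_inv_sigma_inf: float
    c_star: float

    @property
    def max_norm(self) -> float:
        return max(self.sigma_inf, self.inv_sigma_inf, self.grad_inv_sigma_inf)

    @property
    def passed(self) -> bool:
        return self.max_norm < self.c_star


#: Fixed disk centers of the five-inclusion benchmark medium.
EXAMPLE2_CENTERS: tuple[tuple[float, float], ...] = (
    (0.5, 0.5),
    (0.2, 0.35),
    (0.75, 0.2),
    (0.8, 0.85),
    (0.3, 0.8),
)

#: True (height, radius) pairs of the five-inclusion benchmark medium.
EXAMPLE2_TRUTH: tuple[tuple[float, float], ...] = (
    (5.0, 0.19),
    (1.0, 0.1),
    (7.0, 0.09),
    (4.0, 0.13),
    (10.0, 0.04),
)


def three_bump_medium() -> Media1D:
    """The 1-D benchmark medium 1 + 9·χ[.05,.15] + 19·χ[.35,.45] + 29·χ[.75,.85]."""
    return Media1D(baseline=1.0, bumps=((0.05, 0.15, 9.0), (0.35, 0.45, 19.0), (0.75, 0.85, 29.0)))


def evaluate_sigma(media: Media, points: Sequence | np.ndarray) -> np.ndarray:
    """Evaluate sigma at points in the domain.

    Parameters
    ----------
    media
        A :class:`Media1D` or :class:`DiskMedia2D`.
    points
        For 1-D media an array of shape ``(n,)``; for 2-D media ``(n, 2)``.

    Returns
    -------
    Array of shape ``(n,)`` with sigma >= baseline everywhere.
    """
    pts = np.asarray(points, dtype=float)
    if isinstance(media, Media1D):
        pts = np.atleast_1d(pts)
        if pts.ndim != 1:
            raise ValueError(f"1-D media expect points of shape (n,), got {pts.shape}")
        if np.any((pts < 0.0) | (pts > 1.0)):
            raise ValueError("points outside the domain [0, 1]")
        sigma = np.full(pts.shape, media.baseline)
        for a, b, h in media.bumps:
            sigma += h * ((pts >= a) & (pts <= b))
        return sigma
    if isinstance(media, DiskMedia2D):
        pts = np.atleast_2d(pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"2-D media expect points of shape (n, 2), got {pts.shape}")
        if np.any((pts < 0.0) | (pts > 1.0)):
            raise ValueError("points outside the domain [0, 1]^2")
        sigma = np.full(pts.shape[0], media.baseline)
        for cx, cy, r, h in media.disks:
            inside = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 < r**2
            sigma += h * inside
        return sigma
    raise TypeError(f"unsupported media type {type(media)!r}")


def make_example_media(example_id: int, parameters: Sequence[float]) -> DiskMedia2D:
    """Build one of the two benchmark disk media from its parameter vector.

    Example 1 takes ``(r, h)`` for a single disk centered at (0.5, 0.5).
    Example 2 takes ``(h1..h5, r1..r5)`` for five disks at the fixed centers
    :data:`EXAMPLE2_CENTERS`.
    """
    theta = np.asarray(parameters, dtype=float)
    if example_id == 1:
        if theta.shape != (2,):
            raise ValueError(f"example 1 takes (r, h), got shape {theta.shape}")
        r, h = theta
        if r < 0:
            raise ValueError(f"radius must be nonnegative, got {r}")
        return DiskMedia2D(baseline=1.0, disks=((0.5, 0.5, float(r), float(h)),))
    if example_id == 2:
        if theta.shape != (10,):
            raise ValueError(f"example 2 takes (h1..h5, r1..r5), got shape {theta.shape}")
        heights, radii = theta[:5], theta[5:]
        if np.any(radii < 0):
            raise ValueError("radii must be nonnegative")
        disks = tuple(
            (cx, cy, float(r), float(h))
            for (cx, cy), r, h in zip(EXAMPLE2_CENTERS, radii, heights)
        )
        return DiskMedia2D(baseline=1.0, disks=disks)
    raise ValueError(f"example_id must be 1 or 2, got {example_id}")


def example2_truth_vector() -> np.ndarray:
    """True parameter vector (h1..h5, r1..r5) of the five-disk medium."""
    h = [h for h, _ in EXAMPLE2_TRUTH]
    r = [r for _, r in EXAMPLE2_TRUTH]
    return np.array(h + r)


def check_admissibility(media: Media, grid_axes, bounds: AdmissibilityBounds) -> AdmissibilityReport:
    """Check the uniform bound max{|sigma|, |1/sigma|, |grad(1/sigma)|} < C* on a grid.

    ``grid_axes`` is the x-array for 1-D media or an ``(x, y)`` pair of axes
    for 2-D media; the gradient of 1/sigma is taken by centered finite
    differences on the tensor grid.
    """
    if isinstance(media, Media1D):
        x = np.asarray(grid_axes, dtype=float)
        sigma = evaluate_sigma(media, x)
        inv = 1.0 / sigma
        grad = np.gradient(inv, x)
        grad_inf = float(np.max(np.abs(grad)))
    else:
        x, y = (np.asarray(a, dtype=float) for a in grid_axes)
        X, Y = np.meshgrid(x, y, indexing="ij")
        sigma = evaluate_sigma(media, np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)
        inv = 1.0 / sigma
        gx, gy = np.gradient(inv, x, y)
        grad_inf = float(np.max(np.hypot(gx, gy)))
    return AdmissibilityReport(
        sigma_inf=float(np.max(sigma)),
        inv_sigma_inf=float(np.max(1.0 / sigma)),
        grad_inv_sigma_inf=grad_inf,
        c_star=bounds.c_star,
    )


def media_to_dict(media: Media) -> dict:
    """JSON-serializable description of a medium."""
    if isinstance(media, Media1D):
        return {
            "baseline": media.baseline,
            "bumps": [{"a": a, "b": b, "h": h} for a, b, h in media.bumps],
        }
    return {
        "baseline": media.baseline,
        "disks": [{"cx": cx, "cy": cy, "r": r, "h": h} for cx, cy, r, h in media.disks],
    }


def media_from_dict(d: dict) -> Media:
    """Inverse of :func:`media_to_dict`."""
    if "bumps" in d:
        return Media1D(
            baseline=float(d.get("baseline", 1.0)),
            bumps=tuple((float(b["a"]), float(b["b"]), float(b["h"])) for b in d["bumps"]),
        )
    if "disks" in d:
        return DiskMedia2D(
            baseline=float(d.get("baseline", 1.0)),
            disks=tuple(
                (float(k["cx"]), float(k["cy"]), float(k["r"]), float(k["h"])) for k in d["disks"]
            ),
        )
    raise ValueError("media dict must contain 'bumps' or 'disks'")
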