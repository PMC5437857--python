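"""Isometric log-ratio geometry for three-part benthic compositions.

Benthic cover of hard substrate is summarized as a point on the 3-part
simplex (hard coral, macroalgae, other).  All modelling happens in 2-D
isometric log-ratio (ilr) coordinates, an orthonormal log-ratio basis in
which the first coordinate contrasts algae against coral and the second
contrasts "other" against the geometric mean of algae and coral:

    y1 = (1/sqrt 2) * ln(algae / coral)
    y2 = sqrt(2/3)  * ln(other / sqrt(coral * algae))

Any other orthonormal ilr basis differs only by a rotation/reflection of
the (y1, y2) plane, so every back-transformed quantity is invariant to
the choice.  This module provides the forward/inverse maps, the closure
and zero-replacement step applied to raw transect covers, and the coral
iso-cover line in ilr coordinates used by the risk integrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Composition3",
    "DEFAULT_ZERO_FLOOR",
    "close_composition",
    "ilr_forward",
    "ilr_inverse",
    "coral_isoline",
    "ilr_basis_matrix",
]

#: Half the minimum recordable patch fraction (3 cm on a 10 m line).
DEFAULT_ZERO_FLOOR = 0.0015

_SQRT2 = np.sqrt(2.0)
_SQRT23 = np.sqrt(2.0 / 3.0)
_SQRT32 = np.sqrt(1.5)


@dataclass(frozen=True)
class Composition3:
    """A point on the open 3-part simplex (coral, algae, other)."""

    coral: float
    algae: float
    other: float

    def __post_init__(self) -> None:
        parts = np.array([self.coral, self.algae, self.other], dtype=float)
        if not np.all(np.isfinite(parts)):
            raise ValueError("composition parts must be finite")
        if np.any(parts <= 0.0):
            raise ValueError(
                "composition parts must be strictly positive; apply "
                "close_composition to handle zeros"
            )
        if abs(parts.sum() - 1.0) > 1e-12:
            raise ValueError(f"parts must sum to 1 (got {parts.sum()!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.coral, self.algae, self.other], dtype=float)


def ilr_basis_matrix() -> np.ndarray:
    """The 2x3 contrast matrix V with y = V @ log(c), rows orthonormal
    and orthogonal to (1, 1, 1).  Column order (coral, algae, other)."""
    return np.array(
        [
            [-1.0 / _SQRT2, 1.0 / _SQRT2, 0.0],
            [-1.0 / np.sqrt(6.0), -1.0 / np.sqrt(6.0), 2.0 / np.sqrt(6.0)],
        ]
    )


def close_composition(
    coral: float,
    algae: float,
    other: float,
    sand_seagrass: float = 0.0,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> Composition3:
    """Close raw covers over hard substrate and replace zeros.

    Sand and seagrass are dropped (the analysis is restricted to hard
    substrate), the remaining three covers are renormalized to sum to 1,
    and any zero part is replaced multiplicatively: zeros become
    ``zero_floor`` and the nonzero parts are scaled down by the total
    mass assigned to floors, preserving their ratios.

    Parameters
    ----------
    coral, algae, other : float
        Non-negative raw covers (any common unit).
    sand_seagrass : float
        Raw cover of excluded soft-substrate categories; only used for
        validation, never enters the closed composition.
    zero_floor : float
        Replacement proportion for zero parts, in (0, 0.01].
    """
    raw = np.array([coral, algae, other], dtype=float)
    if not np.all(np.isfinite(raw)) or not np.isfinite(sand_seagrass):
        raise ValueError("raw covers must be finite")
    if np.any(raw < 0.0) or sand_seagrass < 0.0:
        raise ValueError("raw covers must be non-negative")
    if not (0.0 < zero_floor <= 0.01):
        raise ValueError("zero_floor must lie in (0, 0.01]")
    total = raw.sum()
    if total <= 0.0:
        raise ValueError("empty transect: no hard-substrate cover recorded")
    closed = raw / total
    zero = closed == 0.0
    if zero.any():
        n_zero = int(zero.sum())
        closed = np.where(zero, zero_floor, closed * (1.0 - n_zero * zero_floor))
    return Composition3(*closed)


def ilr_forward(comp: Composition3 | np.ndarray) -> np.ndarray:
    """Map composition(s) to ilr coordinates.

    Accepts a :class:`Composition3` or an array of shape (..., 3) with
    strictly positive parts in (coral, algae, other) order; returns an
    array of shape (..., 2).
    """
    c = comp.as_array() if isinstance(comp, Composition3) else np.asarray(comp, float)
    if c.shape[-1] != 3:
        raise ValueError("expected 3 parts in the last axis")
    if np.any(c <= 0.0):
        raise ValueError("zero or negative part: close the composition first")
    coral, algae, other = c[..., 0], c[..., 1], c[..., 2]
    y1 = np.log(algae / coral) / _SQRT2
    y2 = _SQRT23 * np.log(other / np.sqrt(coral * algae))
    return np.stack([y1, y2], axis=-1)


def ilr_inverse(y: np.ndarray) -> np.ndarray:
    """Map ilr coordinate(s) of shape (..., 2) back to the open simplex.

    Returns an array of shape (..., 3) in (coral, algae, other) order.
    The computation goes through softmax-style normalization of the
    centred log-ratios and is stable for large coordinates.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != 2:
        raise ValueError("expected 2 ilr coordinates in the last axis")
    if not np.all(np.isfinite(y)):
        raise ValueError("ilr coordinates must be finite")
    clr = np.einsum("...i,ij->...j", y, ilr_basis_matrix())
    clr -= clr.max(axis=-1, keepdims=True)
    expclr = np.exp(clr)
    return expclr / expclr.sum(axis=-1, keepdims=True)


def coral_isoline(kappa: float, y2: float | np.ndarray) -> np.ndarray:
    """The y1 threshold g(y2) on which coral cover equals ``kappa``.

    Coral cover is strictly decreasing in y1 at fixed y2, so the event
    {coral <= kappa} equals {y1 >= g(y2)}.  Writing b = exp(sqrt(3/2) y2)
    and R = 1/kappa - 1, the defining condition

        exp(sqrt2 * y1) + b * exp(y1 / sqrt2) = R

    is a quadratic in u = exp(y1 / sqrt2) with positive root
    u = 2R / (b + sqrt(b^2 + 4R)), hence g(y2) = sqrt2 * ln u.
    """
    if not (0.0 < kappa < 1.0):
        raise ValueError("kappa must lie in (0, 1)")
    y2 = np.asarray(y2, dtype=float)
    r = 1.0 / kappa - 1.0
    # log-scale evaluation keeps b finite-friendly for |y2| up to ~500
    logb = _SQRT32 * y2
    b = np.exp(logb)
    with np.errstate(over="ignore"):
        disc = np.sqrt(b * b + 4.0 * r)
    log_u = np.where(
        np.isfinite(disc),
        np.log(2.0 * r) - np.log(b + disc),
        np.log(r) - logb,  # b^2 >> 4R limit
    )
    return _SQRT2 * log_u
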