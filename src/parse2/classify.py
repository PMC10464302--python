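"""Window labeling and classifier distance.

Each 25-residue window is placed in one of three classes from its mean
properties:

* ``F`` (folded-like): mean hydrophobicity ``phi`` above a cutoff.  Folded
  and disordered training regions separate best on this single scale.
* ``D`` (disordered, non-phase-separating): low ``phi`` but high helix
  propensity ``alpha`` and high scaling exponent ``v_model``.
* ``P`` (phase-separating disordered): low ``phi``, low ``alpha`` and low
  ``v_model``.

The P/D decision is a straight line in the (alpha, v_model) plane,
``v_model = -0.244 * alpha + 0.789``, fit to bisect the disordered and
phase-separating training distributions.  The *classifier distance* is a
confidence proxy: how far a window sits inside its sector, normalized so
that 1.0 corresponds to the training-set mean of that class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassifierConstants",
    "DEFAULT_CONSTANTS",
    "label_window",
    "perpendicular_foot",
    "classifier_distance",
    "label_windows_arrays",
]


@dataclass(frozen=True)
class ClassifierConstants:
    """Published constants of the window classifier.

    ``phi_cutoff``
        F threshold on mean hydrophobicity (windows with ``phi`` strictly
        above are F).
    ``phi_folded_mean``
        Mean ``phi`` of the folded training set; F distances are normalized
        so this maps to 1.0.
    ``boundary_slope``, ``boundary_intercept``
        P/D boundary line ``v_model = slope * alpha + intercept``.
    ``pd_normalizer``
        Euclidean distance in the (alpha, v_model) plane from the boundary
        to either training-set mean; P/D distances are divided by it.
    """

    phi_cutoff: float = 0.08
    phi_folded_mean: float = 0.1164
    boundary_slope: float = -0.244
    boundary_intercept: float = 0.789
    pd_normalizer: float = 0.019


DEFAULT_CONSTANTS = ClassifierConstants()


def _check_finite(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not math.isfinite(val):
            raise ValueError(f"non-finite {name}: {val!r}")


def label_window(
    phi: float,
    alpha: float,
    v_model: float,
    constants: ClassifierConstants = DEFAULT_CONSTANTS,
) -> str:
    """Assign ``F``, ``P`` or ``D`` to one window.

    F iff ``phi`` is strictly above the cutoff.  Otherwise the window is D
    when ``v_model`` lies strictly above the P/D boundary line and P when on
    or below it (points exactly on the boundary are P, at distance 0).
    """
    _check_finite(phi=phi, alpha=alpha, v_model=v_model)
    if phi > constants.phi_cutoff:
        return "F"
    boundary = constants.boundary_slope * alpha + constants.boundary_intercept
    return "D" if v_model > boundary else "P"


def perpendicular_foot(
    alpha: float,
    v_model: float,
    constants: ClassifierConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float]:
    """Foot of the perpendicular from (alpha, v_model) to the P/D boundary.

    Uses the slope-form projection: with boundary
    ``v = m * x + b`` and ``m = -0.244``, the foot is
    ``x = (alpha / 0.244 + b - v_model) / (0.244 + 1 / 0.244)`` and
    ``y = (x - alpha) / 0.244 + v_model``.  Returned as (x, y) in
    (alpha, v_model) coordinates; (x, y) always satisfies the line
    equation.
    """
    _check_finite(alpha=alpha, v_model=v_model)
    m = -constants.boundary_slope  # 0.244
    b = constants.boundary_intercept
    x = (alpha / m + b - v_model) / (m + 1.0 / m)
    y = (x - alpha) / m + v_model
    return x, y


def classifier_distance(
    label: str,
    phi: float,
    alpha: float,
    v_model: float,
    constants: ClassifierConstants = DEFAULT_CONSTANTS,
) -> float:
    """Normalized distance of a window into its classifier sector.

    F windows: ``(phi - cutoff) / (folded_mean - cutoff)``.  P and D
    windows: Euclidean distance to the perpendicular foot on the P/D
    boundary divided by the boundary-to-mean normalizer.  A value of 1.0
    therefore means "as far from the boundary as the training-set mean of
    this class"; values below 1 flag windows inside the overlap of the
    training distributions.

    Raises
    ------
    ValueError
        If ``label`` is inconsistent with what :func:`label_window` would
        assign, guarding against mislabeled reuse.
    """
    expected = label_window(phi, alpha, v_model, constants)
    if label != expected:
        raise ValueError(
            f"label {label!r} inconsistent with coordinates "
            f"(phi={phi}, alpha={alpha}, v_model={v_model}); "
            f"classifier assigns {expected!r}"
        )
    if label == "F":
        return (phi - constants.phi_cutoff) / (
            constants.phi_folded_mean - constants.phi_cutoff
        )
    x, y = perpendicular_foot(alpha, v_model, constants)
    return math.hypot(alpha - x, v_model - y) / constants.pd_normalizer


def label_windows_arrays(
    phi: np.ndarray,
    alpha: np.ndarray,
    v_model: np.ndarray,
    constants: ClassifierConstants = DEFAULT_CONSTANTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized labels and distances for arrays of window properties.

    Same decision rules and the same foot-of-perpendicular arithmetic as
    the scalar functions, evaluated element-wise.  Returns ``(labels,
    distances)`` with labels as a unicode array over {'F', 'P', 'D'}.
    """
    phi = np.asarray(phi, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    v_model = np.asarray(v_model, dtype=float)
    if not (
        np.isfinite(phi).all()
        and np.isfinite(alpha).all()
        and np.isfinite(v_model).all()
    ):
        raise ValueError("non-finite window property encountered")

    boundary = constants.boundary_slope * alpha + constants.boundary_intercept
    is_f = phi > constants.phi_cutoff
    is_d = ~is_f & (v_model > boundary)
    labels = np.where(is_f, "F", np.where(is_d, "D", "P"))

    m = -constants.boundary_slope
    x = (alpha / m + constants.boundary_intercept - v_model) / (m + 1.0 / m)
    y = (x - alpha) / m + v_model
    pd_dist = np.hypot(alpha - x, v_model - y) / constants.pd_normalizer
    f_dist = (phi - constants.phi_cutoff) / (
        constants.phi_folded_mean - constants.phi_cutoff
    )
    distances = np.where(is_f, f_dist, pd_dist)
    return labels, distances
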