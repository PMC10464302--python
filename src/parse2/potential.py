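"""Phase-separation potential of a sequence, base and expanded forms.

The base potential is simply the summed classifier distance over all
windows labeled P: many confident P windows mean a long, strongly
phase-separation-prone disordered region.

Two per-window interaction terms extend the base score with physics the
property classifier does not see:

* ``U_pi`` rewards aromatic and cation-pi pairing capacity.  Following the
  experimental rank order Tyr-Arg > Tyr-Lys ~ Phe-Arg > Phe-Lys, pair terms
  are weighted 3:2:2:1 with Phe-Tyr counted like Phe-Lys, and each pair
  term is ``#A * #B / max(|#A - #B|, 1)`` so balanced partner counts score
  highest (the divisor is forced to 1 when the counts tie, avoiding an
  infinite potential).
* ``U_q = b * SCD + c * |NCPR|`` captures charge patterning: SCD (sequence
  charge decoration) is large in magnitude for blocky charge arrangements,
  NCPR is the net charge per residue.

The weights (a, b, c) were fit previously against condensate
thermodynamics (enthalpy, entropy, free energy of transfer) or saturation
concentrations at 4 degrees C; all four published presets are provided and
``csat`` is the default.

In the expanded potential, the per-window interaction energy U is added to
the distance of P windows, and a D window is *promoted* to P when U
exceeds its classifier distance, contributing ``U - distance``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .scales import load_scale

__all__ = [
    "PotentialParams",
    "PRESETS",
    "ps_potential",
    "u_pi",
    "scd",
    "ncpr",
    "u_q",
    "expanded_potential",
    "window_contributions",
]

_CHARGE = load_scale("charge")

#: (residue_a, residue_b, weight) terms of the pi-interaction score.
PI_PAIR_WEIGHTS: tuple[tuple[str, str, float], ...] = (
    ("Y", "R", 3.0),
    ("Y", "K", 2.0),
    ("F", "R", 2.0),
    ("F", "K", 1.0),
    ("F", "Y", 1.0),
)


@dataclass(frozen=True)
class PotentialParams:
    """Fitted weights for the expanded potential.

    ``a`` scales U_pi; ``b`` and ``c`` weight SCD and |NCPR| in U_q.
    ``trained_on`` records which experimental observable the weights were
    optimized against.
    """

    a: float
    b: float
    c: float
    trained_on: str


#: Published weight sets, keyed by the training target.
PRESETS: Mapping[str, PotentialParams] = {
    "delta_h": PotentialParams(a=0.14, b=8.4, c=5.6, trained_on="delta_h"),
    "delta_s": PotentialParams(a=0.08, b=4.6, c=7.0, trained_on="delta_s"),
    "delta_g": PotentialParams(a=0.11, b=5.2, c=5.4, trained_on="delta_g"),
    "csat": PotentialParams(a=0.28, b=-16.0, c=33.0, trained_on="csat"),
}

DEFAULT_PARAMS = PRESETS["csat"]


def _charges(window: str) -> np.ndarray:
    seq = window.upper()
    try:
        return np.array([_CHARGE.values[aa] for aa in seq])
    except KeyError:
        for pos, aa in enumerate(seq, start=1):
            if aa not in _CHARGE.values:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {pos}"
                ) from None
        raise


def u_pi(window: str, a: float = DEFAULT_PARAMS.a) -> float:
    """Pi-interaction potential of one window (non-negative).

    ``a * sum_w w * #A * #B / max(|#A - #B|, 1)`` over the weighted pairs
    Tyr-Arg (3), Tyr-Lys (2), Phe-Arg (2), Phe-Lys (1), Phe-Tyr (1).
    """
    seq = window.upper()
    _charges(window)  # residue validation
    counts = {aa: seq.count(aa) for aa in "YRFK"}
    total = 0.0
    for res_a, res_b, weight in PI_PAIR_WEIGHTS:
        ca, cb = counts[res_a], counts[res_b]
        total += weight * ca * cb / max(abs(ca - cb), 1)
    return a * total


def scd(window: str) -> float:
    """Sequence charge decoration of one window.

    ``N^-1 * sum_i sum_{j>i} q_i q_j |j - i|^(1/2)`` with q the formal
    residue charge.  Negative for well-mixed polyampholytes; large
    magnitude for segregated charge blocks.
    """
    q = _charges(window)
    n = len(q)
    idx = np.nonzero(q)[0]
    if idx.size < 2:
        return 0.0
    qi = q[idx]
    sep = np.abs(idx[:, None] - idx[None, :])
    pair = qi[:, None] * qi[None, :] * np.sqrt(sep)
    return float(np.triu(pair, k=1).sum() / n)


def ncpr(window: str) -> float:
    """Net charge per residue: ((#K + #R) - (#E + #D)) / N, in [-1, 1]."""
    q = _charges(window)
    return float(q.sum() / len(q))


def u_q(
    scd_value: float,
    ncpr_value: float,
    params: PotentialParams = DEFAULT_PARAMS,
) -> float:
    """Charge-interaction potential ``b * SCD + c * |NCPR|`` (any sign)."""
    return params.b * scd_value + params.c * abs(ncpr_value)


def _column(windows, name: str, dtype) -> np.ndarray:
    if hasattr(windows, "columns"):  # pandas DataFrame
        return windows[name].to_numpy(dtype=dtype)
    return np.array([getattr(w, name) for w in windows], dtype=dtype)


def ps_potential(windows: Iterable) -> float:
    """Base potential: summed classifier distance over P-labeled windows."""
    windows = windows if hasattr(windows, "columns") else list(windows)
    labels = _column(windows, "label", "U1")
    if labels.size == 0:
        return 0.0
    dist = _column(windows, "distance", float)
    # sum over the full window axis (zeros elsewhere) so that the
    # expanded potential with all extensions off reduces to this value
    # bit-exactly, not merely within rounding
    return float(np.where(labels == "P", dist, 0.0).sum())


def window_contributions(
    windows: Iterable,
    params: PotentialParams | None = None,
    include_pi: bool = True,
    include_q: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window contributions to the expanded potential.

    Returns ``(contributions, promoted)`` where ``promoted`` marks D
    windows whose interaction energy U exceeds their classifier distance.
    With both flags enabled a single combined ``U = U_pi + U_q`` drives one
    promotion decision per window (a window has one label, so the two
    extensions are not promoted independently).

    With ``params=None`` the per-window ``u_pi``/``u_q`` fields are used as
    computed when the windows were built; passing explicit ``params``
    re-weights from the stored raw ingredients (``pi_raw``, ``scd``,
    ``ncpr``) instead.
    """
    windows = windows if hasattr(windows, "columns") else list(windows)
    labels = _column(windows, "label", "U1")
    if labels.size == 0:
        return np.zeros(0), np.zeros(0, dtype=bool)
    dist = _column(windows, "distance", float)
    if params is None:
        upi = _column(windows, "u_pi", float)
        uq = _column(windows, "u_q", float)
    else:
        upi = params.a * _column(windows, "pi_raw", float)
        uq = params.b * _column(windows, "scd", float) + params.c * np.abs(
            _column(windows, "ncpr", float)
        )
    u = np.zeros_like(dist)
    if include_pi:
        u = u + upi
    if include_q:
        u = u + uq
    contrib = np.zeros_like(dist)
    is_p = labels == "P"
    contrib[is_p] = dist[is_p] + u[is_p]
    promoted = (labels == "D") & (u > dist)
    contrib[promoted] = u[promoted] - dist[promoted]
    return contrib, promoted


def expanded_potential(
    windows: Iterable,
    params: PotentialParams | None = None,
    include_pi: bool = True,
    include_q: bool = True,
) -> float:
    """Expanded potential including U_pi and/or U_q contributions.

    P windows contribute ``distance + U``; promoted D windows (U greater
    than their classifier distance) contribute ``U - distance``; all other
    windows contribute 0.  With both flags off this reduces exactly to
    :func:`ps_potential`.
    """
    contrib, _ = window_contributions(windows, params, include_pi, include_q)
    return float(contrib.sum())
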