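"""Sliding-window sequence properties.

Every contiguous 25-residue window of a protein is reduced to a handful of
intrinsic properties:

* ``phi`` — mean hydrophobicity (Bastolla interactivity scale),
* ``alpha`` — mean intrinsic alpha-helix propensity (Tanaka-Scheraga),
* ``f_ppii`` — mean polyproline-II propensity (Elam),
* ``q_net`` — integer net charge, (#K + #R) - (#E + #D),
* ``r_h`` — model hydrodynamic radius of the window treated as a
  disordered chain of N = 25 residues (Angstroms),
* ``v_model`` — the polymer scaling exponent implied by that radius,
  ``log(r_h / R0) / log(N)`` with R0 = 2.16 A.

The hydrodynamic-radius model, calibrated on monomeric intrinsically
disordered proteins, is

    r_h = 2.16 * N**(0.503 - 0.11 * ln f_PPII) + 0.26 * |Q_net|
          - 0.29 * N**0.5

The charge term uses the magnitude of the net charge: charge of either
sign expands a disordered chain.  The model does not apply to folded
proteins; for F-labeled windows ``r_h``/``v_model`` are still reported but
only feed the P/D geometry, which such windows never reach.

Each window additionally carries its classifier label and distance
(:mod:`parse2.classify`) and the interaction ingredients SCD, NCPR and the
weighted ``u_pi``/``u_q`` terms (:mod:`parse2.potential`).

The window size is configurable (the classification is fairly insensitive
to it) but every published constant assumes 25, so other sizes emit a
warning.  Sequences must be strictly longer than one window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classify
from .potential import PI_PAIR_WEIGHTS, DEFAULT_PARAMS, PotentialParams
from .scales import CANONICAL_RESIDUES, PropertyScale, load_scale

__all__ = [
    "WindowProperties",
    "WINDOW_SIZE",
    "RH_PREFACTOR",
    "mean_property",
    "net_charge",
    "fraction_ppii",
    "hydrodynamic_radius",
    "scaling_exponent",
    "window_table",
    "compute_window_properties",
]

#: Default window length; all published classifier constants assume it.
WINDOW_SIZE = 25

#: R0 of the scaling-exponent model, Angstroms.
RH_PREFACTOR = 2.16
_NU_BASE = 0.503
_NU_PPII = 0.11
_RH_CHARGE = 0.26
_RH_SHIFT = 0.29

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}

_PHI = load_scale("hydrophobicity")
_ALPHA = load_scale("helix_propensity")
_PPII = load_scale("ppii_propensity")
_CHARGE = load_scale("charge")

_PHI_VEC = np.array([_PHI.values[aa] for aa in CANONICAL_RESIDUES])
_ALPHA_VEC = np.array([_ALPHA.values[aa] for aa in CANONICAL_RESIDUES])
_PPII_VEC = np.array([_PPII.values[aa] for aa in CANONICAL_RESIDUES])
_CHARGE_VEC = np.array(
    [_CHARGE.values[aa] for aa in CANONICAL_RESIDUES], dtype=np.int64
)

# The property tables are exact 4-decimal values, so window sums are exact
# multiples of 1e-4.  Summing them as scaled integers makes every window
# mean independent of summation order and, crucially, makes comparisons
# against the decimal classifier cutoffs deterministic: a window whose
# mean hydrophobicity is mathematically equal to 0.08 must compare equal,
# not fall on either side depending on float accumulation.
MEAN_SCALE = 10_000
_PHI_INT = np.round(_PHI_VEC * MEAN_SCALE).astype(np.int64)
_ALPHA_INT = np.round(_ALPHA_VEC * MEAN_SCALE).astype(np.int64)
_PPII_INT = np.round(_PPII_VEC * MEAN_SCALE).astype(np.int64)


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer-encode a protein string; reject non-canonical residues.

    Lowercase is normalized to uppercase.  The error names the offending
    character and its 1-based position.
    """
    seq = sequence.upper()
    codes = np.fromiter(
        (_AA_INDEX.get(aa, -1) for aa in seq), dtype=np.int64, count=len(seq)
    )
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-canonical residue {seq[pos]!r} at position {pos + 1}"
        )
    return codes


@dataclass(frozen=True)
class WindowProperties:
    """All per-window quantities for one window.

    ``start`` is the 1-based index of the window's first residue; the
    window spans ``start .. start + window_size - 1``.
    """

    start: int
    phi: float
    alpha: float
    f_ppii: float
    q_net: int
    r_h: float
    v_model: float
    label: str
    distance: float
    scd: float
    ncpr: float
    u_pi: float
    u_q: float
    pi_raw: float = 0.0  # unweighted pi pair sum (u_pi / a)


def _check_window(window: str, window_size: int | None = None) -> np.ndarray:
    codes = encode_sequence(window)
    if window_size is not None and codes.size != window_size:
        raise ValueError(
            f"expected a {window_size}-residue window, got {codes.size}"
        )
    return codes


def mean_property(window: str, scale: PropertyScale) -> float:
    """Arithmetic mean of per-residue scale values over the window."""
    codes = _check_window(window)
    vec = np.array([scale.values[aa] for aa in CANONICAL_RESIDUES])
    return float(vec[codes].sum() / codes.size)


def net_charge(window: str) -> int:
    """Integer net charge (#K + #R) - (#E + #D); histidine is neutral."""
    codes = _check_window(window)
    return int(_CHARGE_VEC[codes].sum())


def fraction_ppii(window: str) -> float:
    """Mean PPII propensity of the window, in (0, 1]."""
    codes = _check_window(window)
    return float(_PPII_VEC[codes].sum() / codes.size)


def hydrodynamic_radius(n: int, f_ppii: float, q_net: float) -> float:
    """Model hydrodynamic radius (Angstroms) of a disordered chain.

    ``2.16 * n**(0.503 - 0.11 * ln f_ppii) + 0.26 * |q_net|
    - 0.29 * sqrt(n)``.  Valid for ``f_ppii`` in (0, 1]; the magnitude of
    the net charge is used because charge of either sign expands the
    chain.
    """
    if n < 1:
        raise ValueError(f"chain length must be >= 1, got {n}")
    if not 0.0 < f_ppii <= 1.0:
        raise ValueError(
            f"f_ppii must be in (0, 1] (ln undefined otherwise), got {f_ppii}"
        )
    exponent = _NU_BASE - _NU_PPII * math.log(f_ppii)
    return (
        RH_PREFACTOR * n**exponent
        + _RH_CHARGE * abs(q_net)
        - _RH_SHIFT * math.sqrt(n)
    )


def scaling_exponent(r_h: float, n: int) -> float:
    """Apparent polymer scaling exponent ``log(r_h / 2.16) / log(n)``.

    Base-independent ratio of logarithms; ``r_h`` equal to the prefactor
    gives 0, and an ideal-chain radius ``2.16 * sqrt(n)`` gives 0.5.
    """
    if r_h <= 0:
        raise ValueError(f"r_h must be positive, got {r_h}")
    if n < 2:
        raise ValueError(f"chain length must be >= 2, got {n}")
    return math.log(r_h / RH_PREFACTOR) / math.log(n)


def _sliding_sum_int(arr: np.ndarray, width: int) -> np.ndarray:
    """Exact sliding-window sums of an integer array (cumsum trick)."""
    cs = np.concatenate(([0], np.cumsum(arr, dtype=np.int64)))
    return cs[width:] - cs[:-width]


def window_table(
    sequence: str,
    window_size: int = WINDOW_SIZE,
    params: PotentialParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Vectorized per-window property table for one sequence.

    Returns a DataFrame with one row per window (``len(sequence) -
    window_size + 1`` rows, in order) and columns ``start`` (1-based),
    ``phi``, ``alpha``, ``f_ppii``, ``q_net``, ``r_h``, ``v_model``,
    ``label``, ``distance``, ``scd``, ``ncpr``, ``pi_raw``, ``u_pi``,
    ``u_q``.  ``u_pi``/``u_q`` are weighted with ``params`` (default: the
    csat preset).

    Raises ``ValueError`` for sequences not strictly longer than the
    window and for non-canonical residues.
    """
    if window_size < 2:
        raise ValueError(f"window size must be >= 2, got {window_size}")
    if window_size != WINDOW_SIZE:
        warnings.warn(
            f"window size {window_size} != {WINDOW_SIZE}: published "
            "classifier constants were calibrated for 25-residue windows",
            stacklevel=2,
        )
    codes = encode_sequence(sequence)
    n = codes.size
    w = window_size
    if n <= w:
        raise ValueError(
            f"sequence too short: length {n} requires > {w} residues"
        )

    phi = _sliding_sum_int(_PHI_INT[codes], w) / (MEAN_SCALE * w)
    alpha = _sliding_sum_int(_ALPHA_INT[codes], w) / (MEAN_SCALE * w)
    f_ppii = _sliding_sum_int(_PPII_INT[codes], w) / (MEAN_SCALE * w)
    q = _CHARGE_VEC[codes]
    q_net = _sliding_sum_int(q, w)

    exponent = _NU_BASE - _NU_PPII * np.log(f_ppii)
    r_h = (
        RH_PREFACTOR * float(w) ** exponent
        + _RH_CHARGE * np.abs(q_net)
        - _RH_SHIFT * math.sqrt(w)
    )
    v_model = np.log(r_h / RH_PREFACTOR) / math.log(w)

    labels, distances = classify.label_windows_arrays(phi, alpha, v_model)

    # SCD by charge-pair lag: for lag d, every window sums q_i*q_{i+d}
    # over its w-d in-window pairs; weight sqrt(d), normalize by w.
    scd_arr = np.zeros(n - w + 1)
    for lag in range(1, w):
        prod = q[:-lag] * q[lag:]
        scd_arr += math.sqrt(lag) * _sliding_sum_int(prod, w - lag)
    scd_arr /= w
    ncpr_arr = q_net / w

    # Pi pair terms from sliding residue counts.
    counts = {
        aa: _sliding_sum_int((codes == _AA_INDEX[aa]).astype(np.int64), w)
        for aa in "YRFK"
    }
    pi_raw = np.zeros(n - w + 1)
    for res_a, res_b, weight in PI_PAIR_WEIGHTS:
        ca, cb = counts[res_a], counts[res_b]
        pi_raw += weight * ca * cb / np.maximum(np.abs(ca - cb), 1)
    u_pi_arr = params.a * pi_raw
    u_q_arr = params.b * scd_arr + params.c * np.abs(ncpr_arr)

    return pd.DataFrame(
        {
            "start": np.arange(1, n - w + 2, dtype=np.int64),
            "phi": phi,
            "alpha": alpha,
            "f_ppii": f_ppii,
            "q_net": q_net,
            "r_h": r_h,
            "v_model": v_model,
            "label": labels,
            "distance": distances,
            "scd": scd_arr,
            "ncpr": ncpr_arr,
            "pi_raw": pi_raw,
            "u_pi": u_pi_arr,
            "u_q": u_q_arr,
        }
    )


def compute_window_properties(
    sequence: str,
    window_size: int = WINDOW_SIZE,
    params: PotentialParams = DEFAULT_PARAMS,
) -> list[WindowProperties]:
    """Per-window properties as a list of :class:`WindowProperties`.

    Thin object view over :func:`window_table`; both produce identical
    numbers.
    """
    table = window_table(sequence, window_size=window_size, params=params)
    return [
        WindowProperties(
            start=int(row.start),
            phi=float(row.phi),
            alpha=float(row.alpha),
            f_ppii=float(row.f_ppii),
            q_net=int(row.q_net),
            r_h=float(row.r_h),
            v_model=float(row.v_model),
            label=str(row.label),
            distance=float(row.distance),
            scd=float(row.scd),
            ncpr=float(row.ncpr),
            u_pi=float(row.u_pi),
            u_q=float(row.u_q),
            pi_raw=float(row.pi_raw),
        )
        for row in table.itertuples(index=False)
    ]
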