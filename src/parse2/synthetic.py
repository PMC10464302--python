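"""Synthetic sequences with designed class architecture, plus oracles.

The generator draws residues from class-biased pools (hydrophobic-rich for
F, proline/glycine/serine-rich low-helix pools for P, charged high-helix
pools for D) and then *verifies* the produced sequence against the actual
window classifier, resampling until every window carries the target label.
The pools are tuning details; the contract is only the post-verification,
so the ground truth of a fixture is defined by the classifier itself and
not by assumptions about composition.

Two brute-force oracles live here for use in tests: a naive per-window
recomputation of all window properties (no sliding/incremental updates)
and an exhaustive-interval region finder that applies the region rules
literally to every O(n^2) interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import classify
from .potential import PI_PAIR_WEIGHTS, DEFAULT_PARAMS, PotentialParams
from .scales import load_scale
from .segment import LABEL_TO_CLASS, Region
from .windows import (
    WINDOW_SIZE,
    WindowProperties,
    hydrodynamic_radius,
    scaling_exponent,
    window_table,
)

__all__ = [
    "ArchitectureSpec",
    "ArchitectureFixture",
    "CLASS_POOLS",
    "generate_class_sequence",
    "generate_architecture",
    "oracle_window_props",
    "oracle_regions",
]

#: Residue pools biased toward each window class (residue -> weight).
CLASS_POOLS: dict[str, dict[str, float]] = {
    "F": {"L": 0.20, "A": 0.20, "V": 0.15, "I": 0.15, "F": 0.10,
          "T": 0.10, "W": 0.05, "Y": 0.05},
    "P": {"P": 0.40, "G": 0.30, "S": 0.20, "T": 0.10},
    "D": {"E": 0.30, "K": 0.25, "A": 0.15, "R": 0.10, "Q": 0.10,
          "D": 0.10},
}

#: Central-residue assignment smears class boundaries by up to half a
#: window; expected fixture junctions carry this tolerance.
JUNCTION_TOLERANCE = (WINDOW_SIZE - 1) // 2


def _pool_sampler(target: str, rng: np.random.Generator, length: int) -> str:
    pool = CLASS_POOLS[target]
    residues = list(pool)
    weights = np.array([pool[r] for r in residues])
    weights = weights / weights.sum()
    return "".join(rng.choice(residues, size=length, p=weights))


def generate_class_sequence(
    target: str,
    length: int,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1000,
) -> str:
    """A sequence of ``length`` whose every window is labeled ``target``.

    Seeded rejection sampling from the class pool, verified against the
    window classifier before return; deterministic for a fixed seed.

    Raises ``RuntimeError`` if no sequence passes within ``max_attempts``
    resamplings (signals a miscalibrated pool).
    """
    if target not in CLASS_POOLS:
        raise ValueError(f"unknown target class {target!r}; use F, P or D")
    if length < WINDOW_SIZE:
        raise ValueError(
            f"length must be >= {WINDOW_SIZE} to contain a window"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for _ in range(max_attempts):
        seq = _pool_sampler(target, rng, length)
        if length == WINDOW_SIZE:
            # single window: classify it directly via a padded table
            labels = window_table(seq + seq[-1])["label"].to_numpy()[:1]
        else:
            labels = window_table(seq)["label"].to_numpy()
        if (labels == target).all():
            return seq
    raise RuntimeError(
        f"failed to generate an all-{target} sequence of length {length} "
        f"within {max_attempts} attempts; class pool may be miscalibrated"
    )


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered (class, segment length) layout for a fixture sequence."""

    segments: tuple[tuple[str, int], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        for klass, length in self.segments:
            if klass not in CLASS_POOLS:
                raise ValueError(f"unknown segment class {klass!r}")
            if length < 1:
                raise ValueError(f"segment length must be >= 1, got {length}")
        if self.total_length <= WINDOW_SIZE:
            raise ValueError(
                f"total length {self.total_length} must exceed one window "
                f"({WINDOW_SIZE} residues)"
            )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)


@dataclass(frozen=True)
class ArchitectureFixture:
    """Generated sequence plus its expected post-segmentation layout.

    ``expected`` holds (region class, nominal start, nominal end) in
    1-based inclusive coordinates; predicted region boundaries are
    expected to match within ``tolerance`` residues at internal junctions
    (window-center smearing).
    """

    sequence: str
    expected: tuple[tuple[str, int, int], ...]
    spec: ArchitectureSpec
    tolerance: int = JUNCTION_TOLERANCE


def generate_architecture(spec: ArchitectureSpec) -> ArchitectureFixture:
    """Concatenate class-biased segments into one fixture sequence.

    Segments are drawn from the class pools with the spec's seed (one
    shared stream, so the whole fixture is seed-deterministic).  Adjacent
    same-class segments are merged in the expected layout; segments
    shorter than the 20-residue region minimum are generated but carry no
    layout expectation.
    """
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    merged: list[list] = []  # [klass, start, end]
    cursor = 1
    for klass, length in spec.segments:
        parts.append(_pool_sampler(klass, rng, length))
        end = cursor + length - 1
        if merged and merged[-1][0] == klass:
            merged[-1][2] = end
        else:
            merged.append([klass, cursor, end])
        cursor = end + 1
    expected = tuple(
        (LABEL_TO_CLASS[klass], start, end)
        for klass, start, end in merged
        if end - start + 1 >= 20
    )
    return ArchitectureFixture(
        sequence="".join(parts), expected=expected, spec=spec
    )


# ---------------------------------------------------------------------------
# Brute-force oracles (test-only reference paths)
# ---------------------------------------------------------------------------

_PHI = load_scale("hydrophobicity").values
_ALPHA = load_scale("helix_propensity").values
_PPII = load_scale("ppii_propensity").values
_CHARGE = load_scale("charge").values

# exact integer representations of the 4-decimal tables (see
# parse2.windows.MEAN_SCALE): window means are order-independent and
# cutoff ties are decided identically in oracle and main path
_SCALE = 10_000
_PHI_I = {aa: round(v * _SCALE) for aa, v in _PHI.items()}
_ALPHA_I = {aa: round(v * _SCALE) for aa, v in _ALPHA.items()}
_PPII_I = {aa: round(v * _SCALE) for aa, v in _PPII.items()}


def oracle_window_props(
    sequence: str,
    window_size: int = WINDOW_SIZE,
    params: PotentialParams = DEFAULT_PARAMS,
) -> list[WindowProperties]:
    """Naive direct per-window recomputation of every window property.

    Each window is evaluated from scratch with plain per-residue sums --
    no sliding reuse between windows -- so this path is an independent
    check on the vectorized implementation.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= window_size:
        raise ValueError(
            f"sequence too short: length {n} requires > {window_size}"
        )
    for pos, aa in enumerate(seq, start=1):
        if aa not in _PHI:
            raise ValueError(f"non-canonical residue {aa!r} at position {pos}")

    w = window_size
    sep_sqrt = np.sqrt(
        np.abs(np.arange(w)[:, None] - np.arange(w)[None, :])
    )
    out: list[WindowProperties] = []
    for s in range(n - w + 1):
        win = seq[s : s + w]
        phi = sum(_PHI_I[aa] for aa in win) / (_SCALE * w)
        alpha = sum(_ALPHA_I[aa] for aa in win) / (_SCALE * w)
        f_ppii = sum(_PPII_I[aa] for aa in win) / (_SCALE * w)
        q_net = int(sum(_CHARGE[aa] for aa in win))
        r_h = hydrodynamic_radius(w, f_ppii, q_net)
        v_model = scaling_exponent(r_h, w)
        label = classify.label_window(phi, alpha, v_model)
        distance = classify.classifier_distance(label, phi, alpha, v_model)

        q = np.array([_CHARGE[aa] for aa in win])
        scd = float(
            np.triu(q[:, None] * q[None, :] * sep_sqrt, k=1).sum() / w
        )
        ncpr = q_net / w
        counts = {aa: win.count(aa) for aa in "YRFK"}
        pi_raw = sum(
            weight * counts[a] * counts[b] / max(abs(counts[a] - counts[b]), 1)
            for a, b, weight in PI_PAIR_WEIGHTS
        )
        out.append(
            WindowProperties(
                start=s + 1,
                phi=phi,
                alpha=alpha,
                f_ppii=f_ppii,
                q_net=q_net,
                r_h=r_h,
                v_model=v_model,
                label=label,
                distance=distance,
                scd=scd,
                ncpr=ncpr,
                u_pi=params.a * pi_raw,
                u_q=params.b * scd + params.c * abs(ncpr),
                pi_raw=pi_raw,
            )
        )
    return out


def oracle_regions(
    labels,
    min_length: int = 20,
    min_purity: float = 0.9,
) -> list[Region]:
    """Exhaustive-interval region finder (quadratic; labels length <= 500).

    Applies the region ruleset literally: every interval is tested for
    length, endpoint labels and purity; inclusion-maximal qualifying
    intervals per label are kept; same-label overlaps are resolved longest
    first then leftmost; cross-label overlaps between adjacent selections
    are split evenly with the extra residue to the N-terminal region, a
    region fully inside its predecessor being dropped.
    """
    lab = "".join(labels)
    n = len(lab)
    if n > 500:
        raise ValueError("oracle_regions is quadratic; use length <= 500")
    if set(lab) - set("FPD"):
        raise ValueError(f"unknown label symbol(s): {sorted(set(lab) - set('FPD'))}")

    selected: list[Region] = []
    for label in "PDF":
        flags = np.array([c == label for c in lab])
        counts = np.concatenate(([0], np.cumsum(flags)))
        # widest qualifying interval per start (exhaustive end scan)
        max_end: dict[int, int] = {}
        for i in range(n):
            if not flags[i]:
                continue
            ends = np.arange(i + min_length - 1, n)
            if ends.size == 0:
                continue
            length = ends - i + 1
            hits = counts[ends + 1] - counts[i]
            if abs(min_purity - 0.9) < 1e-12:
                pure = 10 * hits >= 9 * length
            else:
                pure = hits >= min_purity * length
            ok = ends[flags[ends] & pure]
            if ok.size:
                max_end[i] = int(ok.max())
        # an interval is inclusion-maximal iff no earlier (or equal) start
        # reaches at least as far right
        maximal: list[tuple[int, int]] = []
        best = -1
        for i in sorted(max_end):
            if max_end[i] > best:
                maximal.append((i, max_end[i]))
                best = max_end[i]
        chosen: list[tuple[int, int]] = []
        for i, j in sorted(maximal, key=lambda c: (-(c[1] - c[0]), c[0])):
            if all(j < a or i > b for a, b in chosen):
                chosen.append((i, j))
        for i, j in sorted(chosen):
            purity = float((counts[j + 1] - counts[i]) / (j - i + 1))
            selected.append(
                Region(i + 1, j + 1, LABEL_TO_CLASS[label], purity)
            )

    selected.sort(key=lambda r: (r.start, r.end, r.klass))
    result: list[Region] = []
    from dataclasses import replace

    for region in selected:
        if not result:
            result.append(region)
            continue
        prev = result[-1]
        overlap = prev.end - region.start + 1
        if overlap <= 0:
            result.append(region)
        elif region.end <= prev.end:
            continue
        else:
            new_prev = replace(prev, end=prev.end - overlap // 2)
            new_cur = replace(region, start=region.start + (overlap + 1) // 2)
            if new_prev.end >= new_prev.start:
                result[-1] = new_prev
            else:
                result.pop()
            if new_cur.start <= new_cur.end:
                result.append(new_cur)
    return result
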