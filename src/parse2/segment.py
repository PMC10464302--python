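"""Residue-level annotation and region extraction.

Window labels are mapped back onto residues: each window's label (and
classifier distance) is assigned to its central residue, and the terminal
residues that are never a window center inherit the first and last
window's label.  Contiguous stretches of predominantly one label are then
reported as regions:

* a region is a run of residues of length >= 20 that is >= 90 % one label,
  with both endpoint residues carrying that label;
* when adjacent regions of different classes overlap (the up-to-10 % label
  mixing allows it), the overlap is split evenly between them, the
  N-terminal region receiving the extra residue when the overlap is odd.

Label P maps to region class ``PS_ID``, D to ``ID``, F to ``FOLDED``.
Stretches whose labels are too mixed to qualify are simply not covered by
any region.

The published ruleset defines what qualifies as a region but not an
extraction order, so the concrete algorithm here is pinned down as: per
label, enumerate qualifying intervals that are inclusion-maximal; resolve
same-label overlaps greedily by length (longest first, then leftmost);
then split cross-label overlaps as above.  Purity and the minimum length
are enforced before splitting (a split may shorten a region below 20
residues; it is kept).  An exhaustive-enumeration oracle in
:mod:`parse2.synthetic` mirrors these rules for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "MIN_REGION_LENGTH",
    "MIN_REGION_PURITY",
    "LABEL_TO_CLASS",
    "residue_labels",
    "residue_annotation",
    "find_regions",
    "longest_region_per_class",
]

MIN_REGION_LENGTH = 20
MIN_REGION_PURITY = 0.9

LABEL_TO_CLASS = {"P": "PS_ID", "D": "ID", "F": "FOLDED"}
CLASS_TO_LABEL = {v: k for k, v in LABEL_TO_CLASS.items()}


@dataclass(frozen=True)
class Region:
    """A contiguous predicted region, 1-based inclusive coordinates.

    ``purity`` is the majority-label fraction measured before overlap
    splitting; coordinates reflect any splitting applied afterwards.
    """

    start: int
    end: int
    klass: str
    purity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        return CLASS_TO_LABEL[self.klass]


def _central_offset(window_size: int) -> int:
    return (window_size - 1) // 2


def _window_values_to_residues(
    values: np.ndarray, n: int, window_size: int
) -> np.ndarray:
    n_windows = n - window_size + 1
    if values.shape[0] != n_windows:
        raise ValueError(
            f"window list inconsistent with sequence length: got "
            f"{values.shape[0]} windows, expected {n_windows} for n={n}"
        )
    offset = _central_offset(window_size)
    out = np.empty(n, dtype=values.dtype)
    # window starting at residue s (1-based) annotates residue s + offset
    out[offset : offset + n_windows] = values
    out[:offset] = values[0]
    out[offset + n_windows :] = values[-1]
    return out


def _labels_distances(windows) -> tuple[np.ndarray, np.ndarray, int]:
    if hasattr(windows, "columns"):
        labels = windows["label"].to_numpy(dtype="U1")
        dist = windows["distance"].to_numpy(dtype=float)
    else:
        rows = list(windows)
        labels = np.array([w.label for w in rows], dtype="U1")
        dist = np.array([w.distance for w in rows], dtype=float)
    return labels, dist, labels.shape[0]


def residue_labels(windows, n: int, window_size: int = 25) -> np.ndarray:
    """Per-residue label array of length ``n`` (1-based residue i at
    index i-1), by central-residue assignment with terminal fill."""
    labels, _, _ = _labels_distances(windows)
    return _window_values_to_residues(labels, n, window_size)


def residue_annotation(
    windows, sequence: str, window_size: int = 25
) -> pd.DataFrame:
    """Residue table: position, residue, label, distance.

    The distance column is the classifier distance of the window whose
    center is that residue (terminal residues copy the first/last
    window), i.e. the per-residue confidence profile.
    """
    labels, dist, _ = _labels_distances(windows)
    n = len(sequence)
    res_labels = _window_values_to_residues(labels, n, window_size)
    res_dist = _window_values_to_residues(dist, n, window_size)
    return pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "residue": list(sequence.upper()),
            "label": res_labels,
            "distance": res_dist,
        }
    )


def _maximal_candidates(
    is_label: np.ndarray, min_length: int, min_purity: float
) -> list[tuple[int, int]]:
    """Inclusion-maximal intervals [i, j] (0-based, inclusive) whose
    endpoints carry the label and whose label fraction is >= min_purity.

    Works on the score +1 (label) / -(p/(1-p)) (other): purity >= p is
    equivalent to a non-negative interval score.  For each label position
    i the rightmost feasible end j is found by binary search on the
    non-increasing suffix maximum of the prefix-score array; candidates
    whose end does not extend past every earlier candidate's end are
    contained in one of them and dropped.
    """
    pos = np.nonzero(is_label)[0]
    if pos.size == 0 or pos.size < 1:
        return []
    # integer-exact score for purity 0.9: +1 / -9, scaled for general p
    # only rational p supported exactly; default 0.9 -> weights (1, -9)
    if abs(min_purity - 0.9) < 1e-12:
        w_in, w_out = 1, 9
    else:  # fall back to a float score; fine for exploratory use
        w_in, w_out = 1.0 - min_purity, min_purity
    score = np.where(is_label, w_in, -w_out)
    prefix = np.concatenate(([0], np.cumsum(score)))  # prefix[k] = S(0..k-1)

    # suffix max of prefix[j + 1] over label positions j
    s_at_pos = prefix[pos + 1]
    suffix_max = np.maximum.accumulate(s_at_pos[::-1])[::-1]

    candidates: list[tuple[int, int]] = []
    best_end = -1
    for i in pos:
        v = prefix[i]
        k0 = np.searchsorted(pos, i + min_length - 1)
        if k0 >= pos.size or suffix_max[k0] < v:
            continue
        # rightmost k >= k0 with prefix[pos[k]+1] >= v; the feasible set
        # is a prefix of k because suffix_max is non-increasing
        t = np.searchsorted(-suffix_max, -v, side="right")
        k = t - 1
        if k < k0:
            continue
        j = int(pos[k])
        if j > best_end:
            candidates.append((int(i), j))
            best_end = j
    return candidates


def _greedy_select(
    candidates: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Resolve same-label overlaps: longest first, then leftmost."""
    ordered = sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0]))
    chosen: list[tuple[int, int]] = []
    for i, j in ordered:
        if all(j < a or i > b for a, b in chosen):
            chosen.append((i, j))
    return sorted(chosen)


def find_regions(
    labels,
    min_length: int = MIN_REGION_LENGTH,
    min_purity: float = MIN_REGION_PURITY,
) -> list[Region]:
    """Extract folded/ID/PS-ID regions from a per-residue label string.

    ``labels`` is a string or sequence over {F, P, D}.  Returns post-split
    regions, pairwise disjoint and ordered by position, with 1-based
    inclusive coordinates and pre-split purity.
    """
    lab = np.asarray(list(labels), dtype="U1")
    unknown = set(lab.tolist()) - set("FPD")
    if unknown:
        raise ValueError(f"unknown label symbol(s): {sorted(unknown)}")

    selected: list[Region] = []
    for label in "PDF":
        is_label = lab == label
        cands = _maximal_candidates(is_label, min_length, min_purity)
        for i, j in _greedy_select(cands):
            purity = float(is_label[i : j + 1].sum() / (j - i + 1))
            selected.append(
                Region(
                    start=i + 1,
                    end=j + 1,
                    klass=LABEL_TO_CLASS[label],
                    purity=purity,
                )
            )
    selected.sort(key=lambda r: (r.start, r.end, r.klass))

    # split cross-label overlaps between adjacent regions
    result: list[Region] = []
    for region in selected:
        if not result:
            result.append(region)
            continue
        prev = result[-1]
        overlap = prev.end - region.start + 1
        if overlap <= 0:
            result.append(region)
        elif region.end <= prev.end:
            continue  # fully contained in the previous region: dropped
        else:
            new_prev = replace(prev, end=prev.end - overlap // 2)
            new_cur = replace(
                region, start=region.start + (overlap + 1) // 2
            )
            if new_prev.end >= new_prev.start:
                result[-1] = new_prev
            else:
                result.pop()
            if new_cur.start <= new_cur.end:
                result.append(new_cur)
    return result


def longest_region_per_class(regions) -> dict[str, int]:
    """Post-split maximum region length per class; 0 when absent."""
    longest = {klass: 0 for klass in LABEL_TO_CLASS.values()}
    for region in regions:
        longest[region.klass] = max(longest[region.klass], region.length)
    return longest
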