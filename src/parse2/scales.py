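"""Amino-acid property scales used by the window classifier.

Four per-residue tables drive every downstream computation:

``hydrophobicity``
    Interactivity/hydrophobicity scale of Bastolla et al. (2005), derived
    from the principal eigenvector of contact matrices of globular protein
    structures.  High values mark residues enriched in folded cores.
``helix_propensity``
    Intrinsic alpha-helix propensity of Tanaka & Scheraga (1977), computed
    from X-ray structures of native proteins (normalized frequencies).
``ppii_propensity``
    Experimental polyproline-II propensities measured for unfolded peptides
    by Elam et al. (2013).  Used to predict hydrodynamic size of disordered
    chains.
``charge``
    Formal side-chain charge at neutral pH in elementary-charge units:
    K, R -> +1; D, E -> -1; everything else (including histidine) -> 0.

The three propensity tables are transcribed constants from the cited
primary sources; unit tests pin them with checksums so silent edits fail.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "CANONICAL_RESIDUES",
    "PropertyScale",
    "ScaleValidationReport",
    "load_scale",
    "validate_scale",
    "available_scales",
]

#: The 20 canonical one-letter residue codes, alphabetical.
CANONICAL_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# Bastolla et al. (2005) interactivity scale ("hydrophobicity", phi).
_HYDROPHOBICITY = {
    "A": 0.0728, "C": 0.3557, "D": -0.0552, "E": -0.0295, "F": 0.4201,
    "G": -0.0589, "H": 0.0874, "I": 0.3805, "K": -0.0053, "L": 0.3819,
    "M": 0.1613, "N": -0.0390, "P": -0.0492, "Q": -0.0287, "R": 0.0394,
    "S": -0.0282, "T": 0.0239, "V": 0.2947, "W": 0.4114, "Y": 0.3113,
}

# Tanaka & Scheraga (1977) normalized alpha-helix frequencies (alpha).
_HELIX_PROPENSITY = {
    "A": 1.36, "C": 0.82, "D": 1.04, "E": 1.48, "F": 1.05,
    "G": 0.63, "H": 1.11, "I": 1.08, "K": 1.22, "L": 1.21,
    "M": 1.45, "N": 0.89, "P": 0.52, "Q": 1.14, "R": 1.00,
    "S": 0.74, "T": 0.81, "V": 0.94, "W": 0.97, "Y": 0.79,
}

# Elam et al. (2013) experimental PPII propensities (P_PPII).
_PPII_PROPENSITY = {
    "A": 0.37, "C": 0.25, "D": 0.30, "E": 0.42, "F": 0.17,
    "G": 0.13, "H": 0.20, "I": 0.39, "K": 0.56, "L": 0.24,
    "M": 0.36, "N": 0.27, "P": 1.00, "Q": 0.53, "R": 0.38,
    "S": 0.24, "T": 0.32, "V": 0.39, "W": 0.25, "Y": 0.25,
}

# Formal charge; only K, R, E, D carry charge in this model (H neutral).
_CHARGE = {aa: 0.0 for aa in CANONICAL_RESIDUES}
_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})


@dataclass(frozen=True)
class PropertyScale:
    """A named 20-entry mapping from one-letter residue code to a number."""

    name: str
    values: Mapping[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, residue: str) -> float:
        return self.values[residue.upper()]

    def value(self, residue: str) -> float:
        """Scale value for ``residue`` (case-insensitive)."""
        return self.values[residue.upper()]

    def checksum(self) -> str:
        """SHA-256 of the canonical serialization; pins transcribed tables."""
        payload = ";".join(
            f"{aa}={self.values[aa]!r}" for aa in sorted(self.values)
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_tsv(self) -> str:
        """Two-column TSV (residue, value) for audit, alphabetical order."""
        lines = ["residue\tvalue"]
        lines += [f"{aa}\t{self.values[aa]!r}" for aa in sorted(self.values)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, name: str = "") -> "PropertyScale":
        values: dict[str, float] = {}
        for line in text.strip().splitlines()[1:]:
            aa, val = line.split("\t")
            values[aa] = float(val)
        return cls(name=name, values=values)


_SCALES = {
    "hydrophobicity": PropertyScale(
        "hydrophobicity", _HYDROPHOBICITY,
        citation="Bastolla et al. (2005) Proteins 58:22-30",
    ),
    "helix_propensity": PropertyScale(
        "helix_propensity", _HELIX_PROPENSITY,
        citation="Tanaka & Scheraga (1977) Macromolecules 10:9-20",
    ),
    "ppii_propensity": PropertyScale(
        "ppii_propensity", _PPII_PROPENSITY,
        citation="Elam et al. (2013) Protein Sci 22:405-417",
    ),
    "charge": PropertyScale(
        "charge", _CHARGE,
        citation="formal side-chain charge at neutral pH; H treated neutral",
    ),
}


def available_scales() -> tuple[str, ...]:
    return tuple(_SCALES)


def load_scale(name: str) -> PropertyScale:
    """Return one of the four built-in property scales by identifier.

    Parameters
    ----------
    name
        One of ``hydrophobicity``, ``helix_propensity``, ``ppii_propensity``,
        ``charge``.

    Raises
    ------
    KeyError
        If ``name`` is not a known scale identifier; the message lists the
        valid identifiers.
    """
    try:
        return _SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; valid identifiers: "
            + ", ".join(sorted(_SCALES))
        ) from None


@dataclass
class ScaleValidationReport:
    """Outcome of :func:`validate_scale`; failures listed, never raised."""

    scale_name: str
    passed: bool
    failures: list[str] = field(default_factory=list)


def validate_scale(scale: PropertyScale) -> ScaleValidationReport:
    """Check a scale for the structural invariants every table must satisfy.

    Verifies exactly one finite entry per canonical residue, no extras, and
    for the charge scale a {-1, 0, +1} codomain.
    """
    failures: list[str] = []
    keys = set(scale.values)
    for aa in CANONICAL_RESIDUES:
        if aa not in keys:
            failures.append(f"missing residue {aa}")
    for extra in sorted(keys - set(CANONICAL_RESIDUES)):
        failures.append(f"unexpected key {extra!r}")
    for aa in sorted(keys & set(CANONICAL_RESIDUES)):
        if not math.isfinite(scale.values[aa]):
            failures.append(f"non-finite value for residue {aa}")
    if scale.name == "charge":
        for aa in sorted(keys & set(CANONICAL_RESIDUES)):
            if scale.values[aa] not in (-1.0, 0.0, 1.0):
                failures.append(
                    f"charge value for {aa} outside {{-1, 0, +1}}: "
                    f"{scale.values[aa]!r}"
                )
    return ScaleValidationReport(
        scale_name=scale.name, passed=not failures, failures=failures
    )
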