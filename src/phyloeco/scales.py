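"""Amino-acid attribute scales.

A scale assigns one real number to each of the 20 canonical residues
(e.g. a hydropathy index, a secondary-structure propensity, a count of
hydrogen-bond donors).  Proteome featurization averages such scales over
the residues of each protein.  Scales can be parsed from AAindex-style
flat files or from TSV, and a default 50-scale bundle is provided.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

#: Canonical residue order used by the AAindex flat-file format.
AAINDEX_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

#: The 20 canonical one-letter codes.
CANONICAL_RESIDUES = frozenset(AAINDEX_ORDER)


class ScaleParseError(ValueError):
    """Raised when a scale bundle is malformed."""


@dataclass(frozen=True)
class AminoAcidScale:
    """One named amino-acid attribute: a residue -> value mapping.

    Parameters
    ----------
    scale_id:
        Short unique identifier (AAindex-accession-like).
    description:
        Free-text description of the attribute.
    values:
        Mapping from each of the 20 canonical one-letter codes to a
        finite real number.
    """

    scale_id: str
    description: str
    values: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != CANONICAL_RESIDUES:
            missing = sorted(CANONICAL_RESIDUES - keys)
            extra = sorted(keys - CANONICAL_RESIDUES)
            raise ScaleParseError(
                f"scale {self.scale_id!r}: residue set invalid "
                f"(missing {missing}, unexpected {extra})"
            )
        for res, val in self.values.items():
            if not np.isfinite(val):
                raise ScaleParseError(
                    f"scale {self.scale_id!r}: non-finite value for residue {res}"
                )

    def as_vector(self, order: tuple[str, ...] = AAINDEX_ORDER) -> np.ndarray:
        """Return the values as a vector in the given residue order."""
        return np.array([self.values[r] for r in order], dtype=float)


def _parse_aaindex(text: str) -> list[AminoAcidScale]:
    scales: list[AminoAcidScale] = []
    for raw_record in text.split("//"):
        record = raw_record.strip()
        if not record:
            continue
        scale_id = None
        description = ""
        numbers: list[float] = []
        in_values = False
        for line in record.splitlines():
            if line.startswith("H "):
                scale_id = line[2:].strip()
                in_values = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_values = False
            elif line.startswith("I "):
                in_values = True
            elif in_values and line[:1].isspace():
                for tok in line.split():
                    try:
                        numbers.append(float(tok))
                    except ValueError as exc:
                        raise ScaleParseError(
                            f"scale {scale_id!r}: non-numeric value {tok!r}"
                        ) from exc
            else:
                in_values = False
        if scale_id is None:
            raise ScaleParseError("AAindex record without an H (identifier) line")
        if len(numbers) != 20:
            raise ScaleParseError(
                f"scale {scale_id!r}: expected 20 values, found {len(numbers)}"
            )
        scales.append(
            AminoAcidScale(scale_id, description, dict(zip(AAINDEX_ORDER, numbers)))
        )
    return scales


def _parse_tsv(text: str) -> list[AminoAcidScale]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].rstrip("\n").split("\t")
    residues = header[1:]
    has_description = residues and residues[0].lower() == "description"
    if has_description:
        residues = residues[1:]
    if set(residues) != CANONICAL_RESIDUES or len(residues) != 20:
        raise ScaleParseError(
            "TSV scale header must list exactly the 20 canonical residues"
        )
    scales = []
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        scale_id = fields[0]
        description = ""
        vals = fields[1:]
        if has_description:
            description, vals = vals[0], vals[1:]
        if len(vals) != 20:
            raise ScaleParseError(
                f"scale {scale_id!r}: expected 20 values, found {len(vals)}"
            )
        try:
            numbers = [float(v) for v in vals]
        except ValueError as exc:
            raise ScaleParseError(f"scale {scale_id!r}: non-numeric value") from exc
        scales.append(
            AminoAcidScale(scale_id, description, dict(zip(residues, numbers)))
        )
    return scales


def parse_scale_bundle(source) -> list[AminoAcidScale]:
    """Parse a bundle of amino-acid scales.

    Accepts either the AAindex flat-file dialect (``H``/``D``/``I`` lines,
    values in the canonical ``ARNDCQEGHILKMFPSTWYV`` order, records
    terminated by ``//``) or a TSV with a ``scale_id`` column, an optional
    ``description`` column, and one column per canonical residue.

    Parameters
    ----------
    source:
        A string of file content, an open text handle, or a path.

    Returns
    -------
    list of :class:`AminoAcidScale` in file order.

    Raises
    ------
    ScaleParseError
        On missing or non-numeric values, wrong residue sets, or
        duplicate scale identifiers.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.startswith(("H ", "scale_id")):
            with open(text) as fh:
                text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("H "):
        scales = _parse_aaindex(text)
    else:
        scales = _parse_tsv(text)
    seen: set[str] = set()
    for s in scales:
        if s.scale_id in seen:
            raise ScaleParseError(f"duplicate scale_id {s.scale_id!r}")
        seen.add(s.scale_id)
    return scales


# ---------------------------------------------------------------------------
# Default bundle
# ---------------------------------------------------------------------------

# Chou & Fasman beta-sheet conformational propensities.
_BETA_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

# Extended-structure (strand-region) propensities; a synthetic table built
# as a smoothed variant of the strand propensity ranking (branched and
# aromatic residues high, charged/turn-formers low).
_EXTENDED = {
    "A": 0.90, "R": 0.90, "N": 0.76, "D": 0.72, "C": 1.16,
    "Q": 0.98, "E": 0.75, "G": 0.61, "H": 0.93, "I": 1.57,
    "L": 1.24, "K": 0.82, "M": 1.10, "F": 1.33, "P": 0.62,
    "S": 0.92, "T": 1.18, "W": 1.24, "Y": 1.31, "V": 1.64,
}

# Side-chain hydrogen-bond donor counts.
_HBOND_DONORS = {
    "A": 0.0, "R": 5.0, "N": 2.0, "D": 0.0, "C": 1.0,
    "Q": 2.0, "E": 0.0, "G": 0.0, "H": 2.0, "I": 0.0,
    "L": 0.0, "K": 3.0, "M": 0.0, "F": 0.0, "P": 0.0,
    "S": 1.0, "T": 1.0, "W": 1.0, "Y": 1.0, "V": 0.0,
}

# Kyte & Doolittle hydropathy index.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Residue (monoisotopic-rounded) masses within a peptide chain, Da.
_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}

_NAMED_SCALES = [
    ("BETA_SHEET_FREQ", "Normalized frequency of beta-sheet (unweighted)", _BETA_SHEET),
    ("EXTENDED_FREQ", "Normalized frequency of extended structure (synthetic table)", _EXTENDED),
    ("HBOND_DONORS", "Number of side-chain hydrogen bond donors", _HBOND_DONORS),
    ("HYDROPATHY_KD", "Hydropathy index (Kyte-Doolittle)", _HYDROPATHY),
    ("RESIDUE_MASS", "Residue mass within a peptide chain (Da)", _RESIDUE_MASS),
]

def default_scale_bundle() -> list[AminoAcidScale]:
    """Return the default bundle of 50 amino-acid attribute scales.

    The first five are literal, documented attribute tables for the
    features most relevant to environmental adaptation signatures
    (beta-sheet propensity, extended-structure propensity, hydrogen-bond
    donor count, hydropathy, residue mass).  The other 45 are synthetic
    AAindex-style attributes, shipped as a fixed table: like the real
    attribute database, they fall into redundant families (acidity/charge,
    hydrophobicity/thermostability, small-polar content) — exactly the
    correlation structure the decorrelation step downstream is designed
    to prune.  Users with real AAindex data swap the bundle via
    :func:`parse_scale_bundle`.
    """
    from importlib import resources

    text = resources.files("phyloeco.data").joinpath("default_scales.tsv").read_text()
    return parse_scale_bundle(text)
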