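"""Per-proteome physicochemical descriptors.

Each proteome (the full set of proteins of one species) is summarized by
a vector of features.  Every feature is evaluated per protein and then
averaged, unweighted, over all proteins of the proteome — so a short
protein contributes as much as a long one.  Feature kinds:

``scale_mean``
    Mean of an amino-acid attribute scale over the protein's residues.
``class_fraction``
    Fraction of residues belonging to a residue class (polar, acidic, ...).
``charged_uncharged_ratio``
    Count of charged residues (D, E, K, R) over all other residues.
``mean_protein_length``
    Raw protein length.

Composition features (everything except the length) count only the 20
canonical residues: pyrrolysine (O), selenocysteine (U) and the
ambiguity codes B, Z, X, J are skipped there but do count toward the
protein length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import AAINDEX_ORDER, CANONICAL_RESIDUES, AminoAcidScale, default_scale_bundle

logger = logging.getLogger(__name__)

#: Residues countable toward composition features, in fixed order.
_CANONICAL = AAINDEX_ORDER
#: Residues allowed in input sequences but excluded from composition.
NONCANONICAL_RESIDUES = frozenset("OUBZXJ")
ALLOWED_RESIDUES = CANONICAL_RESIDUES | NONCANONICAL_RESIDUES

#: Residue classes used by the composition features.  "polar" is the
#: uncharged-polar set; histidine is counted there because at the
#: near-neutral cytoplasmic pH of the organisms of interest its side
#: chain is mostly unprotonated.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "polar": frozenset("STNQYCH"),
    "hydrophobic": frozenset("AVLIMFWC"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KR"),
    "aromatic": frozenset("FWY"),
    "aliphatic": frozenset("AVLI"),
    "charged": frozenset("DEKR"),
}

CHARGED_RESIDUES = RESIDUE_CLASSES["charged"]

_VALID_KINDS = {
    "scale_mean",
    "class_fraction",
    "charged_uncharged_ratio",
    "mean_protein_length",
}


class FeatureError(ValueError):
    """Raised on invalid feature definitions or undefined feature values."""


@dataclass(frozen=True)
class FeatureDefinition:
    """One proteome descriptor: what to compute and from which residues."""

    feature_id: str
    kind: str
    scale_id: str | None = None
    residue_class: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise FeatureError(f"unknown feature kind {self.kind!r}")
        if self.kind == "scale_mean" and not self.scale_id:
            raise FeatureError(f"feature {self.feature_id!r}: scale_mean needs a scale_id")
        if self.kind == "class_fraction":
            if not self.residue_class:
                raise FeatureError(
                    f"feature {self.feature_id!r}: class_fraction needs a residue class"
                )
            bad = set(self.residue_class) - CANONICAL_RESIDUES
            if bad:
                raise FeatureError(
                    f"feature {self.feature_id!r}: non-canonical residues in class: {sorted(bad)}"
                )


@dataclass(frozen=True)
class ProteomeRecord:
    """All protein sequences of one species."""

    species_id: str
    protein_sequences: tuple[str, ...] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.protein_sequences) == 0:
            raise FeatureError(f"proteome {self.species_id!r}: no proteins")
        for i, seq in enumerate(self.protein_sequences):
            if len(seq) == 0:
                raise FeatureError(f"proteome {self.species_id!r}: empty protein #{i}")
            bad = set(seq) - ALLOWED_RESIDUES
            if bad:
                raise FeatureError(
                    f"proteome {self.species_id!r}, protein #{i}: "
                    f"invalid residues {sorted(bad)}"
                )


def default_feature_definitions(
    scales: list[AminoAcidScale] | None = None,
    include_length: bool = True,
) -> tuple[list[FeatureDefinition], dict[str, AminoAcidScale]]:
    """Build the default registry of 58 proteome descriptors.

    50 scale-mean features (one per scale of the default bundle), seven
    further composition features — six residue-class fractions (polar,
    nonpolar, acidic, basic, aromatic, aliphatic) plus the
    charged/uncharged ratio (the charged *fraction* is a monotone
    transform of the ratio and is left out of the default registry) —
    and, if ``include_length``, the mean protein length: 58 features
    total with the default bundle.  The registry is configuration, not a
    constant: pass a different bundle, drop the length, or build custom
    definitions to realize other counts.

    Returns the definitions plus a scale lookup keyed by scale_id.
    """
    if scales is None:
        scales = default_scale_bundle()
    defs = [
        FeatureDefinition(f"scale:{s.scale_id}", "scale_mean", scale_id=s.scale_id)
        for s in scales
    ]
    defs += [
        FeatureDefinition(f"frac:{name}", "class_fraction", residue_class=cls)
        for name, cls in RESIDUE_CLASSES.items()
        if name != "charged"
    ]
    defs.append(FeatureDefinition("charged_uncharged_ratio", "charged_uncharged_ratio"))
    if include_length:
        defs.append(FeatureDefinition("mean_protein_length", "mean_protein_length"))
    seen: set[str] = set()
    for d in defs:
        if d.feature_id in seen:
            raise FeatureError(f"duplicate feature_id {d.feature_id!r}")
        seen.add(d.feature_id)
    return defs, {s.scale_id: s for s in scales}


# ---------------------------------------------------------------------------
# Per-protein computation
# ---------------------------------------------------------------------------

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _r in enumerate(_CANONICAL):
    _CODE[ord(_r)] = _i

_CHARGED_MASK = np.array([r in CHARGED_RESIDUES for r in _CANONICAL])


def _count_matrix(sequences: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein canonical-residue counts (n_proteins x 20) and raw lengths."""
    counts = np.zeros((len(sequences), 20), dtype=np.int64)
    lengths = np.zeros(len(sequences), dtype=np.int64)
    for i, seq in enumerate(sequences):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = _CODE[arr]
        codes = codes[codes >= 0]
        counts[i] = np.bincount(codes, minlength=20)
        lengths[i] = arr.size
    return counts, lengths


def protein_feature(
    sequence: str,
    fd: FeatureDefinition,
    scales: dict[str, AminoAcidScale] | None = None,
) -> float:
    """Evaluate one feature on a single protein sequence.

    Raises :class:`FeatureError` if the feature is undefined for the
    sequence: a composition feature on a sequence without canonical
    residues, or the charged/uncharged ratio on an all-charged sequence.
    """
    counts, lengths = _count_matrix((sequence,))
    n_countable = int(counts.sum())
    if fd.kind == "mean_protein_length":
        return float(lengths[0])
    if n_countable == 0:
        raise FeatureError(
            f"feature {fd.feature_id!r} undefined: no countable residues in sequence"
        )
    if fd.kind == "scale_mean":
        if scales is None or fd.scale_id not in scales:
            raise FeatureError(f"unknown scale {fd.scale_id!r}")
        vec = scales[fd.scale_id].as_vector(_CANONICAL)
        return float(counts[0] @ vec / n_countable)
    if fd.kind == "class_fraction":
        mask = np.array([r in fd.residue_class for r in _CANONICAL])
        return float(counts[0, mask].sum() / n_countable)
    # charged_uncharged_ratio
    charged = int(counts[0, _CHARGED_MASK].sum())
    uncharged = n_countable - charged
    if uncharged == 0:
        raise FeatureError(
            f"feature {fd.feature_id!r} undefined: zero uncharged residues (ratio-undefined)"
        )
    return charged / uncharged


def proteome_features(
    proteome: ProteomeRecord,
    defs: list[FeatureDefinition],
    scales: dict[str, AminoAcidScale] | None = None,
) -> np.ndarray:
    """Feature vector of one proteome: per-protein values averaged unweighted.

    This is deliberately *not* the pooled-residue statistic: averaging
    per-protein values weights each protein equally regardless of its
    length.  Proteins for which a feature is undefined (no countable
    residues, or a zero-uncharged denominator for the ratio) are excluded
    from that feature's mean and logged; if a feature is undefined for
    every protein, a :class:`FeatureError` names it.
    """
    if not defs:
        raise FeatureError("no feature definitions supplied")
    counts, lengths = _count_matrix(proteome.protein_sequences)
    n_countable = counts.sum(axis=1)
    countable_ok = n_countable > 0
    if not countable_ok.all():
        logger.info(
            "proteome %s: %d protein(s) without canonical residues excluded "
            "from composition features",
            proteome.species_id,
            int((~countable_ok).sum()),
        )
    charged = counts[:, _CHARGED_MASK].sum(axis=1)
    uncharged = n_countable - charged

    out = np.empty(len(defs), dtype=float)
    safe_n = np.where(countable_ok, n_countable, 1)
    for j, fd in enumerate(defs):
        if fd.kind == "mean_protein_length":
            out[j] = lengths.mean()
            continue
        if fd.kind == "scale_mean":
            if scales is None or fd.scale_id not in scales:
                raise FeatureError(f"unknown scale {fd.scale_id!r}")
            vec = scales[fd.scale_id].as_vector(_CANONICAL)
            vals = counts @ vec / safe_n
            mask = countable_ok
        elif fd.kind == "class_fraction":
            cmask = np.array([r in fd.residue_class for r in _CANONICAL])
            vals = counts[:, cmask].sum(axis=1) / safe_n
            mask = countable_ok
        else:  # charged_uncharged_ratio
            mask = countable_ok & (uncharged > 0)
            if (countable_ok & ~mask).any():
                logger.info(
                    "proteome %s: %d protein(s) ratio-undefined (no uncharged "
                    "residues), excluded from %s",
                    proteome.species_id,
                    int((countable_ok & ~mask).sum()),
                    fd.feature_id,
                )
            vals = np.divide(charged, uncharged, out=np.zeros(len(lengths)), where=mask)
        if not mask.any():
            raise FeatureError(
                f"proteome {proteome.species_id!r}: feature {fd.feature_id!r} "
                "undefined for every protein"
            )
        out[j] = vals[mask].mean()
    return out


def build_feature_matrix(
    proteomes: list[ProteomeRecord],
    defs: list[FeatureDefinition],
    scales: dict[str, AminoAcidScale] | None = None,
) -> pd.DataFrame:
    """Species x feature matrix; rows in input order, columns in defs order.

    Raises on duplicate species ids or fewer than two proteomes.
    """
    if len(proteomes) < 2:
        raise FeatureError("need at least two proteomes")
    ids = [p.species_id for p in proteomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FeatureError(f"duplicate species_id(s): {dupes}")
    rows = np.vstack([proteome_features(p, defs, scales) for p in proteomes])
    m = pd.DataFrame(rows, index=ids, columns=[d.feature_id for d in defs])
    if not np.isfinite(m.to_numpy()).all():
        raise FeatureError("non-finite feature values produced")
    return m
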