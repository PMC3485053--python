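"""Synthetic data with known ground truth.

Two generators make the whole pipeline testable without external
downloads: archetype-structured proteomes (each environment archetype
fixes a Dirichlet prior over amino-acid composition and a protein-length
law; each species draws its own composition from the prior and its
proteins i.i.d. from that composition) and Jukes-Cantor sequence
evolution along a given ultrametric tree (the oracle for the 16S arm).
All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
import yaml

from .features import ProteomeRecord
from .phylo import AlignedSequences, PhyloError
from .scales import AAINDEX_ORDER

_MAX_SEED = 2**31 - 1


class SimulationError(ValueError):
    """Raised on invalid generator parameters."""


@dataclass(frozen=True)
class Archetype:
    """One environment archetype: composition prior, length law,
    proteome-size law and a coherent phenotype profile.

    ``intensity_law`` (optional) gives each species its own adaptation
    intensity u: the species' expected composition is the archetype
    profile moved along its log-contrast against a baseline composition
    by the factor u, so species differ in how extreme their adaptation
    is.  Without it, every species' composition is drawn from
    Dirichlet(residue_weights) directly.
    """

    name: str
    residue_weights: dict[str, float] = field(hash=False)
    length_law: dict = field(hash=False)
    n_proteins_law: tuple[int, int] = (120, 180)
    phenotype: dict[str, str] = field(default_factory=dict, hash=False)
    intensity_law: dict | None = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if set(self.residue_weights) != set(AAINDEX_ORDER):
            raise SimulationError(
                f"archetype {self.name!r}: weights must cover the 20 canonical residues"
            )
        if any(w <= 0 for w in self.residue_weights.values()):
            raise SimulationError(f"archetype {self.name!r}: weights must be positive")
        family = self.length_law.get("family")
        if family not in ("lognormal", "negative-binomial"):
            raise SimulationError(f"archetype {self.name!r}: unknown length law {family!r}")
        if self.length_law.get("min_length", 30) < 30:
            raise SimulationError(f"archetype {self.name!r}: min_length must be >= 30")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.residue_weights[r] for r in AAINDEX_ORDER], dtype=float)

    @property
    def expected_composition(self) -> dict[str, float]:
        w = self.weight_vector
        return dict(zip(AAINDEX_ORDER, w / w.sum()))

    def expected_class_fraction(self, residues: str | set[str]) -> float:
        comp = self.expected_composition
        return sum(comp[r] for r in residues)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth bookkeeping for one simulated dataset."""

    archetype_of: dict[str, str] = field(hash=False)
    seed: int | None = None
    archetypes: tuple[Archetype, ...] = ()

    def labels(self, ids: list[str] | tuple[str, ...]) -> np.ndarray:
        names = [a.name for a in self.archetypes]
        return np.array([names.index(self.archetype_of[i]) + 1 for i in ids])


def _load_config() -> dict:
    text = resources.files("phyloeco.data").joinpath("archetypes.yaml").read_text()
    return yaml.safe_load(text)


def default_archetypes() -> list[Archetype]:
    """Load the three default archetypes from the versioned config file.

    hyperthermophile-like: elevated charged and branched-hydrophobic
    residues, depleted small-polar residues, short proteins;
    halophile-like: strongly acidic composition (D, E up; K, R down),
    reduced hydrophobicity, intermediate lengths;
    mesophile-methanogen-like: baseline composition, long proteins.  By
    construction the expected acidic fraction orders halophile >
    hyperthermophile > mesophile, and the expected mean length
    mesophile > halophile > hyperthermophile.
    """
    cfg = _load_config()
    out = []
    for a in cfg["archetypes"]:
        out.append(
            Archetype(
                name=a["name"],
                residue_weights={k: float(v) for k, v in a["residue_weights"].items()},
                length_law=a["length_law"],
                n_proteins_law=(a["n_proteins_law"]["min"], a["n_proteins_law"]["max"]),
                phenotype=a["phenotype"],
                intensity_law=a.get("intensity_law"),
            )
        )
    return out


def default_baseline() -> dict[str, float]:
    """Dataset baseline composition weights (the anchor for the
    per-species adaptation-intensity interpolation)."""
    return {k: float(v) for k, v in _load_config()["baseline_weights"].items()}


def _draw_lengths(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    family = law["family"]
    min_length = int(law.get("min_length", 30))
    if family == "lognormal":
        raw = rng.lognormal(mean=law["meanlog"], sigma=law["sdlog"], size=n)
        lengths = np.maximum(np.rint(raw).astype(int), min_length)
    else:  # negative-binomial, shifted to min_length
        lengths = min_length + rng.negative_binomial(law["size"], law["prob"], size=n)
    return lengths


def simulate_proteome(
    archetype: Archetype,
    n_proteins: int,
    seed: int | None = None,
    baseline: dict[str, float] | None = None,
) -> ProteomeRecord:
    """Simulate one species' proteome.

    The species composition is a single Dirichlet draw from the
    archetype's weights; protein lengths follow the archetype's length
    law; residues are i.i.d. from the species composition.  When the
    archetype carries an ``intensity_law`` and a ``baseline`` is given,
    the Dirichlet mean is first moved along the archetype's log-contrast
    against the baseline by a per-species intensity factor.  Species id
    defaults to the archetype name (callers usually relabel).
    """
    if n_proteins < 1:
        raise SimulationError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    weights = archetype.weight_vector
    if archetype.intensity_law is not None and baseline is not None:
        law = archetype.intensity_law
        u = float(
            np.clip(
                rng.normal(law.get("mean", 1.0), law.get("sd", 0.0)),
                law.get("min", 0.0),
                law.get("max", np.inf),
            )
        )
        b = np.array([baseline[r] for r in AAINDEX_ORDER], dtype=float)
        b = b / b.sum()
        profile = weights / weights.sum()
        mean = b * (profile / b) ** u
        weights = weights.sum() * mean / mean.sum()
    composition = rng.dirichlet(weights)
    lengths = _draw_lengths(archetype.length_law, n_proteins, rng)
    total = int(lengths.sum())
    residues = rng.choice(np.array(list(AAINDEX_ORDER)), size=total, p=composition)
    seqs = []
    pos = 0
    for L in lengths:
        seqs.append("".join(residues[pos : pos + L]))
        pos += L
    return ProteomeRecord(archetype.name, tuple(seqs))


def simulate_dataset(
    archetypes: list[Archetype] | None = None,
    species_per_archetype: int = 20,
    seed: int | None = None,
    baseline: dict[str, float] | None = None,
) -> tuple[list[ProteomeRecord], SyntheticTruth, pd.DataFrame]:
    """Simulate a full labelled dataset.

    Returns the proteomes (ids like ``HYP01``), the ground truth, and a
    phenotype table assigning each species its archetype's coherent
    habitat profile so phenotype-abundance summaries have known expected
    structure.  With the default archetypes, the default baseline
    composition anchors the per-species adaptation intensity.
    """
    if archetypes is None:
        archetypes = default_archetypes()
        if baseline is None:
            baseline = default_baseline()
    if species_per_archetype < 2:
        raise SimulationError("species_per_archetype must be >= 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(archetypes) * species_per_archetype)
    proteomes: list[ProteomeRecord] = []
    archetype_of: dict[str, str] = {}
    phenotype_rows = {}
    idx = 0
    for arch in archetypes:
        prefix = arch.name[:3].upper()
        for s in range(species_per_archetype):
            child = np.random.default_rng(children[idx])
            idx += 1
            n_proteins = int(child.integers(arch.n_proteins_law[0], arch.n_proteins_law[1] + 1))
            sub_seed = int(child.integers(_MAX_SEED))
            record = simulate_proteome(arch, n_proteins, sub_seed, baseline=baseline)
            species_id = f"{prefix}{s + 1:02d}"
            proteomes.append(ProteomeRecord(species_id, record.protein_sequences))
            archetype_of[species_id] = arch.name
            phenotype_rows[species_id] = dict(arch.phenotype)
    truth = SyntheticTruth(archetype_of, seed, tuple(archetypes))
    phenotypes = pd.DataFrame.from_dict(phenotype_rows, orient="index")
    phenotypes.index.name = "species_id"
    return proteomes, truth, phenotypes


# ---------------------------------------------------------------------------
# Sequence evolution along a tree (Jukes-Cantor)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def jc_substitution_probability(t: float) -> float:
    """Probability that a site differs from its ancestor after branch
    length t (expected substitutions/site): (3/4)(1 - exp(-4t/3))."""
    if t < 0:
        raise SimulationError("branch length must be non-negative")
    return float(0.75 * (1.0 - np.exp(-4.0 * t / 3.0)))


def simulate_alignment(
    tree: str, length: int, seed: int | None = None
) -> AlignedSequences:
    """Evolve nucleotide sequences along a Newick tree under Jukes-Cantor.

    The root sequence is uniform over {A, C, G, T}; along each branch of
    length t every site independently substitutes, with probability
    (3/4)(1 - e^(-4t/3)), to a base chosen uniformly among the other
    three.  Leaves are returned in tree (preorder) order.
    """
    if length < 1:
        raise SimulationError("alignment length must be >= 1")
    try:
        t = dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    rng = np.random.default_rng(seed)
    root_states = rng.integers(4, size=length)
    t.seed_node.states = root_states
    ids: list[str] = []
    seqs: list[str] = []
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            states = node.states
        else:
            branch = node.edge.length or 0.0
            q = jc_substitution_probability(float(branch))
            parent_states = node.parent_node.states
            hit = rng.random(length) < q
            # uniform among the 3 other bases: parent + 1..3 mod 4
            shift = rng.integers(1, 4, size=length)
            states = np.where(hit, (parent_states + shift) % 4, parent_states)
            node.states = states
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"leaf{len(ids)}"
            ids.append(label.replace(" ", "_"))
            seqs.append("".join(_BASES[states]))
    return AlignedSequences(tuple(ids), tuple(seqs))
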