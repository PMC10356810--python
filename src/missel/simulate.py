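"""Synthetic data generation: transcripts, mutations, ∆∆G values, structures.

Every generator is a pure function of its parameters and a seed, and writes
(through :mod:`missel.io`) the same formats the real-data path reads, so
synthetic and real inputs are interchangeable.

Mutation sets are drawn from a selection scenario: each catalogue entry's
neutral probability is multiplied by the enrichment factor of every layer
whose predicate it matches (factors compose multiplicatively across
overlapping layers), the weights are renormalised, and the requested number
of mutations is drawn multinomially. Factor 1 is neutral; factor 0 models
complete negative selection; the shipped ``fig1`` scenario plants a strong
(x3) and a weak (x2) enrichment on disjoint 20% partitions of the region,
the configuration under which exclude-and-retest unmasks the weak layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import CODON_TO_AA, ObservedMutationSet, SnvCatalogue
from .errors import DegenerateNullError
from .spectrum import BASES, Transcript
from .structure import StructureModel, TargetSelection

__all__ = [
    "SelectionScenario",
    "fig1_scenario",
    "simulate_transcript",
    "simulate_mutations",
    "simulate_ddg",
    "simulate_structure",
    "plant_partition_features",
]

_STOP_CODONS = {c for c, aa in CODON_TO_AA.items() if aa == "*"}


@dataclass(frozen=True)
class SelectionScenario:
    """Planted selection: (predicate expression, enrichment factor) layers."""

    layers: tuple[tuple[str, float], ...]
    n_mutations: int
    seed: int | None = None

    def __post_init__(self):
        for expr, factor in self.layers:
            if not np.isfinite(factor) or factor < 0:
                raise ValueError(f"layer {expr!r}: invalid factor {factor}")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be non-negative")


def fig1_scenario(n_mutations: int = 300, seed: int | None = None) -> SelectionScenario:
    """The strong/weak two-layer masking scenario.

    A "strong" feature enriched threefold and a "weak" feature enriched
    twofold, defined on disjoint partitions of the region (see
    :func:`plant_partition_features`, which marks 20% of entries strong and
    a disjoint 20% weak).
    """
    return SelectionScenario(
        layers=(("strong", 3.0), ("weak", 2.0)),
        n_mutations=n_mutations,
        seed=seed,
    )


def plant_partition_features(
    catalogue: SnvCatalogue,
    fractions: Sequence[tuple[str, float]] = (("strong", 0.2), ("weak", 0.2)),
    seed: int | np.random.Generator | None = None,
    by_residue: bool = True,
) -> SnvCatalogue:
    """Add disjoint Boolean partition columns covering given null-mass shares.

    Partitions are built greedily over (shuffled) residues until each
    feature's null probability mass reaches its requested fraction, so the
    planted features mimic contiguous structural categories. Remaining
    entries belong to no partition.
    """
    rng = np.random.default_rng(seed)
    entries = catalogue.entries.copy()
    probs = catalogue.prob
    if by_residue:
        units = entries["residue"].to_numpy()
    else:
        units = np.arange(len(entries))
    uniq = np.unique(units)
    order = rng.permutation(uniq)
    unit_mass = {u: probs[units == u].sum() for u in uniq}

    assigned: dict[str, set] = {}
    cursor = 0
    for name, frac in fractions:
        chosen: set = set()
        mass = 0.0
        while cursor < len(order) and mass < frac:
            u = order[cursor]
            chosen.add(u)
            mass += unit_mass[u]
            cursor += 1
        assigned[name] = chosen
    for name, chosen in assigned.items():
        entries[name] = np.isin(units, list(chosen))
    return SnvCatalogue(
        region_id=catalogue.region_id,
        entries=entries,
        class_filter=catalogue.class_filter,
        excluded_lookup=catalogue.excluded_lookup,
        exclusions=catalogue.exclusions,
    )


def simulate_transcript(
    n_codons: int,
    gc_bias: float = 0.5,
    seed: int | np.random.Generator | None = None,
    gene_id: str = "GSYN",
    transcript_id: str = "TSYN",
) -> Transcript:
    """Random CDS starting with ATG and free of internal stop codons.

    ``gc_bias`` is the marginal probability of drawing G or C at each
    position (split evenly between the two), before stop-codon rejection.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if not 0 < gc_bias < 1:
        raise ValueError("gc_bias must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    codons = ["ATG"]
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(BASES), size=3, p=p))
        if codon in _STOP_CODONS:
            continue
        codons.append(codon)
    flanks = rng.choice(list(BASES), size=2, p=p)
    return Transcript(
        gene_id=gene_id,
        transcript_id=transcript_id,
        cds_sequence="".join(codons),
        upstream_flank=str(flanks[0]),
        downstream_flank=str(flanks[1]),
    )


def simulate_mutations(
    catalogue: SnvCatalogue,
    scenario: SelectionScenario,
    seed: int | np.random.Generator | None = None,
) -> ObservedMutationSet:
    """Draw an observed mutation set with planted selection.

    Entry weights are null probability times the product of the factors of
    all matching layers, renormalised; ``scenario.n_mutations`` mutations
    are drawn multinomially (each clone an independent origination).
    """
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    weights = catalogue.prob.astype(float).copy()
    for expr, factor in scenario.layers:
        mask = catalogue.eval_predicate(expr)
        weights[mask] *= factor
    total = weights.sum()
    if total <= 0:
        raise DegenerateNullError("all selection weights are zero")
    counts = rng.multinomial(scenario.n_mutations, weights / total)
    return ObservedMutationSet(region_id=catalogue.region_id, counts=counts)


def simulate_ddg(
    catalogue: SnvCatalogue,
    seed: int | np.random.Generator | None = None,
    tail_weight: float = 0.25,
    benign_loc: float = 0.3,
    benign_scale: float = 0.6,
    tail_loc: float = 3.5,
    tail_scale: float = 1.2,
    core_residues: Sequence[int] | None = None,
    core_tail_weight: float = 0.8,
) -> np.ndarray:
    """Synthetic per-entry ∆∆G values (kcal/mol).

    Values are drawn from a two-component Gaussian mixture — a near-zero
    "benign" mode and a destabilising tail — mimicking the spread of
    FoldX-style predictions over a folded domain. Entries at designated
    "core" residues draw from the tail with elevated probability. Amino-acid
    changes reachable by several nucleotide paths share a single value.
    """
    if not 0 <= tail_weight <= 1:
        raise ValueError("tail_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    entries = catalogue.entries
    keys = list(zip(entries["residue"], entries["aa_ref"], entries["aa_alt"]))
    uniq_keys = sorted(set(keys))
    core = set(int(r) for r in core_residues) if core_residues else set()
    values: dict[tuple, float] = {}
    for key in uniq_keys:
        residue = int(key[0])
        w = core_tail_weight if residue in core else tail_weight
        if rng.random() < w:
            values[key] = rng.normal(tail_loc, tail_scale)
        else:
            values[key] = rng.normal(benign_loc, benign_scale)
    return np.array([values[k] for k in keys])


def simulate_structure(
    n_residues: int,
    seed: int | np.random.Generator | None = None,
    attach_residue: int = 1,
    target_offset: float = 5.0,
    target_size: int = 3,
    target_spacing: float = 1.0,
) -> StructureModel:
    """Idealised helical Cα trace plus a pseudo-ligand at known distances.

    The protein is chain A: one Cα per residue on an ideal α-helix (2.3 Å
    radius, 1.5 Å rise, 100° twist per residue). The target is chain L:
    ``target_size`` pseudo-atoms on the radial ray through
    ``attach_residue``'s Cα at distances ``target_offset``,
    ``target_offset + target_spacing``, ... — so the minimum distance from
    ``attach_residue`` is exactly ``target_offset`` by construction.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    rng = np.random.default_rng(seed)  # reserved for future jitter options
    del rng
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    idx = np.arange(n_residues)
    ca = np.column_stack(
        [radius * np.cos(twist * idx), radius * np.sin(twist * idx), rise * idx]
    )
    rows = [
        ("A", int(i + 1), "ALA", "CA", "C", False, *ca[i]) for i in range(n_residues)
    ]
    anchor = ca[attach_residue - 1]
    radial = anchor.copy()
    radial[2] = 0.0
    direction = radial / np.linalg.norm(radial)
    for j in range(target_size):
        pos = anchor + direction * (target_offset + j * target_spacing)
        rows.append(("L", j + 1, "LIG", f"X{j + 1}", "C", True, *pos))
    atoms = pd.DataFrame(
        rows,
        columns=["chain", "resnum", "resname", "atom", "element", "hetero",
                 "x", "y", "z"],
    )
    return StructureModel(atoms=atoms, target=TargetSelection(chains=["L"]))
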