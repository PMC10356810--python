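"""Structural feature scoring: ∆∆G tables, residue sets, and 3-D distances.

Three kinds of score can be attached to a catalogue of possible SNVs:

* ∆∆G (kcal/mol), the predicted change in folding free energy of the
  mutation, parsed from FoldX PositionScan output. Mutations with
  ∆∆G > 2 kcal/mol are classed destabilising by default.
* Boolean membership of a named residue set (ligand-binding interface,
  calcium-binding residues, ...).
* Minimum Euclidean distance (Å) from the mutated residue's heavy atoms to a
  declared binding partner (ligand peptide, DNA, substrate); residues within
  8 Å are classed functional-site by default.

Scores defined at amino-acid level are copied onto every nucleotide-level
catalogue entry producing that substitution. Entries without structure
coverage are left NaN ("unscored") and are excluded — from null and observed
alike — by the tests that use the affected feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .catalogue import SnvCatalogue
from .errors import CoverageError, FormatError

logger = logging.getLogger(__name__)

DDG_DESTABILISING_THRESHOLD = 2.0  # kcal/mol
FUNCTIONAL_SITE_CUTOFF = 8.0  # Å

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

__all__ = [
    "DDG_DESTABILISING_THRESHOLD",
    "FUNCTIONAL_SITE_CUTOFF",
    "DdgTable",
    "ResidueSet",
    "StructureModel",
    "TargetSelection",
    "parse_foldx_positionscan",
    "write_positionscan",
    "classify_destabilising",
    "in_residue_set",
    "read_structure",
    "write_pdb",
    "attach_features",
]


# --------------------------------------------------------------------------
# ∆∆G tables

@dataclass
class DdgTable:
    """Per-mutation ∆∆G values keyed by (chain, residue, aa_ref, aa_alt)."""

    values: dict[tuple[str, int, str, str], float]
    source_structure: str = ""

    def lookup(self, residue: int, aa_ref: str, aa_alt: str,
               chain: str | None = None) -> float | None:
        if chain is not None:
            return self.values.get((chain, residue, aa_ref, aa_alt))
        for (c, r, wt, mt), v in self.values.items():
            if r == residue and wt == aa_ref and mt == aa_alt:
                return v
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, r, wt, mt, v) for (c, r, wt, mt), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["chain", "residue", "aa_ref", "aa_alt", "ddg"])


def _parse_mutation_label(label: str, line_no: int) -> tuple[str, str, int, str]:
    """Decode a PositionScan mutation label like ``EA455K``.

    Layout: wild-type amino acid (1-letter), chain identifier (1 char),
    residue number, mutant amino acid (1-letter).
    """
    label = label.strip()
    if len(label) < 4:
        raise FormatError(f"mutation label too short: {label!r}", line=line_no)
    wt, chain, mid, alt = label[0], label[1], label[2:-1], label[-1]
    if wt not in AA3_TO_1.values() or alt not in set(AA3_TO_1.values()) | {"*"}:
        raise FormatError(f"unrecognised amino acids in label {label!r}", line=line_no)
    if not mid.isdigit():
        raise FormatError(f"non-numeric residue number in label {label!r}", line=line_no)
    return wt, chain, int(mid), alt


def parse_foldx_positionscan(
    files: Iterable[str | Path],
    residue_offset: int = 0,
    source_structure: str = "",
) -> DdgTable:
    """Read FoldX PositionScan output into a :class:`DdgTable`.

    Two dialects are accepted, distinguished per line:

    * scanning-output rows: ``<label>\\t<ddg>`` where the label encodes
      wild-type amino acid, chain and residue (e.g. ``EA455K  2.31``);
    * generic two-column fallback: ``<label>,<ddg>`` with comma or
      whitespace separation.

    ``residue_offset`` is added to structure residue numbers to obtain
    protein coordinates. Duplicate keys take the last value with a warning.
    """
    values: dict[tuple[str, int, str, str], float] = {}
    for path in files:
        path = Path(path)
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split()
                if len(parts) != 2:
                    raise FormatError(
                        f"expected 'label ddg', got {line!r} in {path.name}",
                        line=line_no,
                    )
                label, raw = parts
                wt, chain, resnum, alt = _parse_mutation_label(label, line_no)
                try:
                    ddg = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"non-numeric ∆∆G {raw!r} in {path.name}", line=line_no
                    ) from exc
                key = (chain, resnum + residue_offset, wt, alt)
                if key in values:
                    warnings.warn(
                        f"duplicate PositionScan record {label}; keeping the last",
                        stacklevel=2,
                    )
                values[key] = ddg
    return DdgTable(values=values, source_structure=source_structure)


def write_positionscan(table: DdgTable, path: str | Path) -> None:
    """Write a DdgTable in the scanning-output dialect (label TAB ddg)."""
    with open(path, "w") as fh:
        for (chain, residue, wt, alt), v in sorted(table.values.items()):
            fh.write(f"{wt}{chain}{residue}{alt}\t{v:.6g}\n")


def classify_destabilising(
    ddg: float, threshold: float = DDG_DESTABILISING_THRESHOLD
) -> bool:
    """True iff ∆∆G strictly exceeds the destabilisation threshold."""
    if not np.isfinite(ddg):
        raise ValueError(f"non-finite ∆∆G: {ddg}")
    return bool(ddg > threshold)


# --------------------------------------------------------------------------
# Residue sets

@dataclass(frozen=True)
class ResidueSet:
    """A named set of protein residue numbers (e.g. a binding interface)."""

    name: str
    residues: frozenset[int]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(int(r) for r in self.residues))
        if any(r < 0 for r in self.residues):
            raise ValueError(f"{self.name}: negative residue numbers")


def in_residue_set(residue_number: int, residue_set: ResidueSet) -> bool:
    return int(residue_number) in residue_set.residues


# --------------------------------------------------------------------------
# Structures and distances

@dataclass(frozen=True)
class TargetSelection:
    """Atom subset representing the binding partner.

    Atoms match if their chain is in ``chains`` and, when ``residues`` is
    given, their residue number is in it; ``hetero=True`` additionally admits
    HETATM records on those chains.
    """

    chains: frozenset[str]
    residues: frozenset[int] | None = None
    hetero: bool = True

    def __init__(self, chains: Iterable[str], residues: Iterable[int] | None = None,
                 hetero: bool = True):
        object.__setattr__(self, "chains", frozenset(chains))
        object.__setattr__(
            self, "residues",
            None if residues is None else frozenset(int(r) for r in residues),
        )
        object.__setattr__(self, "hetero", hetero)


@dataclass
class StructureModel:
    """A light tabular protein structure: one row per atom.

    Columns: chain, resnum, resname, atom, element, hetero, x, y, z (Å).
    ``target`` declares which atoms form the binding partner; distances are
    computed between a residue's heavy atoms and the target's heavy atoms.
    ``residue_offset`` maps structure residue numbering to protein
    coordinates (protein residue = structure residue + offset); it is always
    explicit configuration.
    """

    atoms: pd.DataFrame
    target: TargetSelection | None = None
    residue_offset: int = 0
    name: str = ""
    _target_coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        required = {"chain", "resnum", "resname", "atom", "element", "hetero",
                    "x", "y", "z"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atoms table missing columns {sorted(missing)}")
        coords = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite atom coordinates")

    def _heavy(self) -> pd.DataFrame:
        return self.atoms[self.atoms["element"].str.upper() != "H"]

    def target_coordinates(self) -> np.ndarray:
        if self.target is None:
            raise ValueError("no target selection declared on this structure")
        if self._target_coords is None:
            a = self._heavy()
            mask = a["chain"].isin(self.target.chains)
            if self.target.residues is not None:
                mask &= a["resnum"].isin(self.target.residues)
            if not self.target.hetero:
                mask &= ~a["hetero"]
            sel = a.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)
            if len(sel) == 0:
                raise ValueError("target selection matches no atoms")
            self._target_coords = sel
        return self._target_coords

    def residue_coordinates(self, residue_number: int,
                            chain: str | None = None) -> np.ndarray:
        """Heavy-atom coordinates of a protein residue (protein numbering)."""
        a = self._heavy()
        structure_resnum = int(residue_number) - self.residue_offset
        mask = (a["resnum"] == structure_resnum) & ~a["hetero"]
        if chain is not None:
            mask &= a["chain"] == chain
        elif self.target is not None:
            mask &= ~a["chain"].isin(self.target.chains)
        sel = a.loc[mask, ["x", "y", "z"]].to_numpy(dtype=float)
        if len(sel) == 0:
            raise CoverageError(
                f"residue {residue_number} (structure {structure_resnum}) "
                f"not present in structure {self.name or '<unnamed>'}"
            )
        return sel

    def min_distance_to_target(self, residue_number: int,
                               chain: str | None = None) -> float:
        """Minimum heavy-atom distance (Å) from a residue to the target."""
        res = self.residue_coordinates(residue_number, chain=chain)
        return float(cdist(res, self.target_coordinates()).min())

    def within_distance(self, residue_number: int,
                        cutoff: float = FUNCTIONAL_SITE_CUTOFF,
                        chain: str | None = None) -> bool:
        """True iff the residue lies within ``cutoff`` Å of the target (inclusive)."""
        return self.min_distance_to_target(residue_number, chain=chain) <= cutoff

    def protein_residues(self, chain: str | None = None) -> list[int]:
        """Protein residue numbers present (non-target, non-hetero chains)."""
        a = self.atoms[~self.atoms["hetero"]]
        if chain is not None:
            a = a[a["chain"] == chain]
        elif self.target is not None:
            a = a[~a["chain"].isin(self.target.chains)]
        return sorted(int(r) + self.residue_offset for r in a["resnum"].unique())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Rigid-body transform (useful for invariance checks)."""
        atoms = self.atoms.copy()
        xyz = atoms[["x", "y", "z"]].to_numpy(dtype=float) @ np.asarray(rotation).T
        xyz = xyz + np.asarray(translation, dtype=float)
        atoms[["x", "y", "z"]] = xyz
        return StructureModel(
            atoms=atoms, target=self.target,
            residue_offset=self.residue_offset, name=self.name,
        )


def read_structure(
    path: str | Path,
    target: TargetSelection | None = None,
    residue_offset: int = 0,
    name: str | None = None,
) -> StructureModel:
    """Read a PDB file (ATOM/HETATM records) into a :class:`StructureModel`.

    Insertion codes are rejected with a clear error; alternate locations keep
    the first conformer.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name or path.stem, str(path))
    model = next(structure.get_models())
    rows = []
    for chain in model:
        for residue in chain:
            het_flag, resnum, icode = residue.id
            if icode.strip():
                raise FormatError(
                    f"insertion code {icode!r} at {chain.id}:{resnum} is not "
                    "supported; renumber the structure first"
                )
            hetero = bool(het_flag.strip())
            for atom in residue:
                if atom.get_altloc() not in (" ", "A"):
                    continue
                x, y, z = atom.coord
                rows.append(
                    (chain.id, int(resnum), residue.resname.strip(),
                     atom.get_name(), (atom.element or "").strip() or "X",
                     hetero, float(x), float(y), float(z))
                )
    atoms = pd.DataFrame(
        rows,
        columns=["chain", "resnum", "resname", "atom", "element", "hetero",
                 "x", "y", "z"],
    )
    if atoms.empty:
        raise FormatError(f"no ATOM/HETATM records in {path}")
    return StructureModel(atoms=atoms, target=target,
                          residue_offset=residue_offset, name=name or path.stem)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write the atom table as fixed-width PDB ATOM/HETATM records."""
    with open(path, "w") as fh:
        serial = 0
        for row in structure.atoms.itertuples(index=False):
            serial += 1
            record = "HETATM" if row.hetero else "ATOM  "
            atom_name = row.atom if len(row.atom) >= 4 else f" {row.atom:<3s}"
            fh.write(
                f"{record}{serial:5d} {atom_name:<4.4s} {row.resname:<3.3s} "
                f"{row.chain:1.1s}{row.resnum:4d}    "
                f"{row.x:8.3f}{row.y:8.3f}{row.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {row.element:>2.2s}\n"
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# Feature attachment

def attach_features(
    catalogue: SnvCatalogue,
    ddg: DdgTable | None = None,
    residue_sets: Sequence[ResidueSet] | Mapping[str, ResidueSet] | None = None,
    structure: StructureModel | None = None,
    *,
    chain: str | None = None,
    ddg_threshold: float = DDG_DESTABILISING_THRESHOLD,
    distance_cutoff: float = FUNCTIONAL_SITE_CUTOFF,
) -> SnvCatalogue:
    """Return a catalogue whose entries carry named feature columns.

    Adds, depending on what is supplied:

    * ``ddg`` (float, NaN where unscored) and ``destabilising``
      (Boolean, ``ddg > ddg_threshold``; NaN-∆∆G entries are False but remain
      unscored via ``ddg``);
    * one Boolean column per residue set, named after the set;
    * ``dist_to_target`` (float Å, NaN where the residue is absent from the
      structure) and ``near_target`` (Boolean, ``dist <= distance_cutoff``).

    A tally of unscored entries per feature is logged; downstream tests must
    drop unscored entries from both null and observed before testing on the
    affected feature.
    """
    entries = catalogue.entries.copy()
    residues = entries["residue"].to_numpy()

    if ddg is not None:
        chains = {c for (c, _, _, _) in ddg.values} if chain is None else {chain}
        if len(chains) > 1:
            raise ValueError(
                f"∆∆G table spans chains {sorted(chains)}; pass chain= explicitly"
            )
        the_chain = next(iter(chains)) if chains else (chain or "A")
        vals = np.full(len(entries), np.nan)
        for i, row in enumerate(entries.itertuples(index=False)):
            if row.consequence != "missense":
                continue
            v = ddg.values.get((the_chain, int(row.residue), row.aa_ref, row.aa_alt))
            if v is not None:
                vals[i] = v
        entries["ddg"] = vals
        entries["destabilising"] = np.where(np.isnan(vals), False, vals > ddg_threshold)
        entries["destabilising"] = entries["destabilising"].astype(bool)
        n_unscored = int(np.isnan(vals[entries["consequence"] == "missense"]).sum())
        if n_unscored:
            logger.info("attach_features: %d missense entries without ∆∆G", n_unscored)

    if residue_sets is not None:
        if isinstance(residue_sets, Mapping):
            residue_sets = list(residue_sets.values())
        for rs in residue_sets:
            entries[rs.name] = np.isin(residues, list(rs.residues))

    if structure is not None:
        covered = set(structure.protein_residues(chain=chain))
        dist = np.full(len(entries), np.nan)
        cache: dict[int, float] = {}
        for i, r in enumerate(residues):
            r = int(r)
            if r not in covered:
                continue
            if r not in cache:
                cache[r] = structure.min_distance_to_target(r, chain=chain)
            dist[i] = cache[r]
        entries["dist_to_target"] = dist
        entries["near_target"] = np.where(np.isnan(dist), False, dist <= distance_cutoff)
        entries["near_target"] = entries["near_target"].astype(bool)
        n_unscored = int(np.isnan(dist).sum())
        if n_unscored:
            logger.info(
                "attach_features: %d entries at residues without structure "
                "coverage", n_unscored,
            )

    return SnvCatalogue(
        region_id=catalogue.region_id,
        entries=entries,
        class_filter=catalogue.class_filter,
        excluded_lookup=catalogue.excluded_lookup,
        exclusions=catalogue.exclusions,
    )
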