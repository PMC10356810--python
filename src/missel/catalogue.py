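"""Enumeration of all possible coding SNVs and the neutral null model.

Every CDS position yields three possible single-nucleotide variants; each is
annotated with its codon consequence under the standard genetic code and, via
the trinucleotide spectrum, with an expected probability of occurrence under
neutrality. Probabilities are restricted to a consequence class (missense by
default) and renormalised to sum to 1, forming the null against which
observed mutations are tested.

The null is nucleotide-level: distinct nucleotide changes producing the same
amino-acid substitution remain distinct entries, and amino-acid-level scores
are copied onto each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import (
    BoundsError,
    DataConsistencyError,
    DegenerateNullError,
)
from .spectrum import (
    BASE_INDEX,
    BASES,
    MutationRecord,
    Transcript,
    TrinucleotideSpectrum,
    context_of,
)

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

CONSEQUENCES = ("synonymous", "missense", "nonsense", "stop_loss")

__all__ = [
    "CODON_TO_AA",
    "PossibleSnv",
    "SnvCatalogue",
    "ObservedMutationSet",
    "consequence_of",
    "enumerate_snvs",
    "build_null",
    "map_observed",
]


@dataclass(frozen=True)
class PossibleSnv:
    """One possible coding SNV. Mostly a typed view onto a catalogue row."""

    cds_position: int
    ref: str
    alt: str
    codon_index: int
    aa_ref: str
    aa_alt: str
    consequence: str

    @property
    def residue_number(self) -> int:
        return self.codon_index


def consequence_of(aa_ref: str, aa_alt: str) -> str:
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    if aa_ref == "*":
        return "stop_loss"
    return "missense"


def enumerate_snvs(
    transcript: Transcript,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """All single-base edits of the CDS within a closed residue interval.

    Returns a DataFrame in deterministic order (position ascending, alt base
    A<C<G<T) with columns cds_pos, ref, alt, residue, aa_ref, aa_alt,
    consequence, ctx5, ctx3. ``region`` is a 1-based closed residue interval;
    ``None`` means the whole protein.
    """
    n_codons = transcript.n_codons
    if region is None:
        region = (1, n_codons)
    start, end = region
    if not (1 <= start <= end <= n_codons):
        raise BoundsError(
            f"residue interval {region} outside protein of length {n_codons}"
        )

    rows = []
    seq = transcript.cds_sequence
    for residue in range(start, end + 1):
        codon_start = (residue - 1) * 3
        codon = seq[codon_start : codon_start + 3]
        aa_ref = CODON_TO_AA.get(codon)
        for offset in range(3):
            pos = codon_start + offset + 1
            ref = seq[pos - 1]
            c5, _, c3 = context_of(transcript, pos)
            for alt in BASES:
                if alt == ref:
                    continue
                if aa_ref is None:
                    # codon contains an ambiguous base; consequence undefined
                    aa_alt = None
                    cons = None
                else:
                    mutant = codon[:offset] + alt + codon[offset + 1 :]
                    aa_alt = CODON_TO_AA[mutant]
                    cons = consequence_of(aa_ref, aa_alt)
                rows.append((pos, ref, alt, residue, aa_ref, aa_alt, cons, c5, c3))

    return pd.DataFrame(
        rows,
        columns=[
            "cds_pos",
            "ref",
            "alt",
            "residue",
            "aa_ref",
            "aa_alt",
            "consequence",
            "ctx5",
            "ctx3",
        ],
    )


@dataclass
class SnvCatalogue:
    """The neutral null model over a coding region.

    ``entries`` holds the SNVs of the retained consequence class(es) with a
    ``prob`` column summing to 1; feature columns are appended by
    :func:`missel.structure.attach_features`. ``excluded_lookup`` maps
    (cds_pos, ref, alt) of enumerated-but-filtered SNVs to their consequence
    so observed records falling on them can be tallied rather than mistaken
    for data errors. ``exclusions`` records layering provenance.
    """

    region_id: str
    entries: pd.DataFrame
    class_filter: frozenset[str]
    excluded_lookup: dict[tuple[int, str, str], str] = field(default_factory=dict)
    exclusions: tuple[str, ...] = ()

    def __post_init__(self):
        total = float(self.entries["prob"].sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities sum to {total}, expected 1")

    @property
    def prob(self) -> np.ndarray:
        return self.entries["prob"].to_numpy()

    def feature_columns(self) -> list[str]:
        core = {
            "cds_pos", "ref", "alt", "residue", "aa_ref", "aa_alt",
            "consequence", "ctx5", "ctx3", "prob",
        }
        return [c for c in self.entries.columns if c not in core]

    def eval_predicate(self, expression: str) -> np.ndarray:
        """Evaluate a Boolean expression over feature columns.

        The grammar is that of :meth:`pandas.DataFrame.eval` restricted to
        comparisons and Boolean operators, e.g. ``"ddg > 2.0"`` or
        ``"interface and not destabilising"``. NaN feature values evaluate
        falsy.
        """
        result = self.entries.eval(expression)
        mask = np.asarray(result, dtype=bool)
        if mask.shape != (len(self.entries),):
            raise ValueError(f"predicate {expression!r} is not row-wise Boolean")
        return mask


def build_null(
    entries: pd.DataFrame,
    spectrum: TrinucleotideSpectrum,
    class_filter: Iterable[str] = ("missense",),
    region_id: str = "region",
) -> SnvCatalogue:
    """Attach neutral probabilities to enumerated SNVs and renormalise.

    Each entry's raw weight is the spectrum rate of its (context, alt)
    channel; entries outside ``class_filter`` are dropped (recorded in
    ``excluded_lookup``), and the remaining weights are normalised to sum 1.
    """
    class_filter = frozenset(class_filter)
    unknown = class_filter - set(CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence class(es): {sorted(unknown)}")

    entries = entries.copy()
    ok_ctx = (
        entries["ctx5"].isin(BASE_INDEX)
        & entries["ctx3"].isin(BASE_INDEX)
        & entries["consequence"].notna()
    )
    i5 = entries["ctx5"].where(ok_ctx, "A").map(BASE_INDEX).to_numpy()
    iref = entries["ref"].map(BASE_INDEX).to_numpy()
    i3 = entries["ctx3"].where(ok_ctx, "A").map(BASE_INDEX).to_numpy()
    ialt = entries["alt"].map(BASE_INDEX).to_numpy()
    raw = spectrum.rate[i5, iref, i3, ialt]
    raw[~ok_ctx.to_numpy()] = 0.0
    entries["prob"] = raw

    keep = entries["consequence"].isin(class_filter)
    excluded_lookup = {
        (int(r.cds_pos), r.ref, r.alt): (r.consequence or "unannotated")
        for r in entries.loc[~keep].itertuples(index=False)
    }
    kept = entries.loc[keep].reset_index(drop=True)
    total = float(kept["prob"].sum())
    if total <= 0:
        raise DegenerateNullError(
            f"no spectrum mass on consequence class(es) {sorted(class_filter)}"
        )
    kept["prob"] = kept["prob"] / total
    return SnvCatalogue(
        region_id=region_id,
        entries=kept,
        class_filter=class_filter,
        excluded_lookup=excluded_lookup,
    )


@dataclass
class ObservedMutationSet:
    """Observed mutations mapped onto catalogue entries.

    ``counts`` is aligned row-for-row with the catalogue's entries;
    ``dropped`` tallies records that were filtered out and why.
    """

    region_id: str
    counts: np.ndarray
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def map_observed(
    mutations: Iterable[MutationRecord],
    catalogue: SnvCatalogue,
    *,
    count_weighted: bool = True,
) -> ObservedMutationSet:
    """Match observed mutation records to catalogue entries.

    Records of consequence classes outside the catalogue's filter are dropped
    with a logged tally; records outside the region are dropped with a
    warning; a reference-base mismatch against the catalogue is an error.
    """
    entries = catalogue.entries
    index = {
        (int(pos), ref, alt): i
        for i, (pos, ref, alt) in enumerate(
            zip(entries["cds_pos"], entries["ref"], entries["alt"])
        )
    }
    ref_at: dict[int, str] = {int(p): r for p, r in zip(entries["cds_pos"], entries["ref"])}
    for (pos, ref, _alt), _cons in catalogue.excluded_lookup.items():
        ref_at.setdefault(pos, ref)

    counts = np.zeros(len(entries), dtype=np.int64)
    dropped: dict[str, int] = {}
    for m in mutations:
        key = (m.cds_position, m.ref, m.alt)
        w = m.count if count_weighted else 1
        if key in index:
            counts[index[key]] += w
            continue
        if key in catalogue.excluded_lookup:
            cons = catalogue.excluded_lookup[key]
            dropped[f"consequence:{cons}"] = dropped.get(f"consequence:{cons}", 0) + w
            continue
        known_ref = ref_at.get(m.cds_position)
        if known_ref is not None and known_ref != m.ref:
            raise DataConsistencyError(
                f"{m.gene_id}:{m.cds_position} ref {m.ref} != catalogue base {known_ref}"
            )
        warnings.warn(
            f"mutation {m.gene_id}:{m.cds_position}{m.ref}>{m.alt} outside region "
            f"{catalogue.region_id}; dropped",
            stacklevel=2,
        )
        dropped["outside_region"] = dropped.get("outside_region", 0) + w

    if dropped:
        logger.info("map_observed dropped records: %s", dropped)
    return ObservedMutationSet(
        region_id=catalogue.region_id, counts=counts, dropped=dropped
    )
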