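"""Trinucleotide mutational-spectrum estimation.

The neutral null model rests on a strand-specific 192-channel spectrum: for
every trinucleotide context (5' base, reference base, 3' base — read in the
direction of transcription) and every alternate base, a rate defined as

    rate = (observed mutations of that channel) / (occurrences of the context
                                                   in the included transcripts)

Contexts are computed on the spliced coding sequence; the first and last CDS
positions take their missing neighbour from a supplied one-base flank, so
every position has a full trinucleotide. Positions whose trinucleotide
contains a non-ACGT base are excluded from both numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, DataConsistencyError, MissingInputError

BASES = "ACGT"
BASE_INDEX: Mapping[str, int] = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BASES",
    "Transcript",
    "MutationRecord",
    "TrinucleotideSpectrum",
    "select_longest_transcript",
    "context_of",
    "estimate_spectrum",
    "random_spectrum",
]


@dataclass(frozen=True)
class Transcript:
    """A spliced coding sequence with one flanking base at each end.

    ``cds_sequence`` is given in the direction of transcription and must have
    length divisible by 3. The flanks exist only to give the terminal CDS
    positions a trinucleotide context.
    """

    gene_id: str
    transcript_id: str
    cds_sequence: str
    upstream_flank: str
    downstream_flank: str

    def __post_init__(self):
        if len(self.cds_sequence) == 0 or len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} "
                "is not a positive multiple of 3"
            )
        if len(self.upstream_flank) != 1 or len(self.downstream_flank) != 1:
            raise ValueError(f"{self.transcript_id}: flanks must be single bases")
        allowed = set("ACGTN")
        seq = self.cds_sequence + self.upstream_flank + self.downstream_flank
        if not set(seq) <= allowed:
            bad = sorted(set(seq) - allowed)
            raise ValueError(f"{self.transcript_id}: invalid bases {bad}")

    @property
    def length(self) -> int:
        """CDS length in nucleotides."""
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3


@dataclass(frozen=True)
class MutationRecord:
    """One observed somatic SNV on a transcript's CDS.

    ``count`` is the number of distinct clones carrying the mutation after
    clone-merging; it weights the mutation in spectrum estimation and in the
    observed sets unless unique-site mode is requested.
    """

    gene_id: str
    cds_position: int  # 1-based
    ref: str
    alt: str
    count: int = 1
    aa_change: str | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.cds_position}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT ref/alt: {self.ref}>{self.alt}")
        if self.cds_position < 1:
            raise ValueError(f"cds_position must be >= 1, got {self.cds_position}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class TrinucleotideSpectrum:
    """Strand-specific mutation rates over 192 (context, alt) channels.

    Arrays are indexed ``[i5, iref, i3, ialt]`` with A,C,G,T -> 0..3; entries
    with ``ialt == iref`` are structurally zero and not channels.
    """

    rate: np.ndarray  # (4, 4, 4, 4) mutations per available context site
    context_counts: np.ndarray  # (4, 4, 4) occurrences in included transcripts
    mutation_counts: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 4, 4, 4))
    )

    N_CHANNELS = 192

    def __post_init__(self):
        self.rate = np.asarray(self.rate, dtype=float)
        self.context_counts = np.asarray(self.context_counts, dtype=float)
        self.mutation_counts = np.asarray(self.mutation_counts, dtype=float)
        if self.rate.shape != (4, 4, 4, 4):
            raise ValueError("rate must have shape (4,4,4,4)")
        if self.context_counts.shape != (4, 4, 4):
            raise ValueError("context_counts must have shape (4,4,4)")
        if not np.all(np.isfinite(self.rate)) or np.any(self.rate < 0):
            raise ValueError("rates must be finite and non-negative")

    def probability(self, context: Sequence[str], alt: str) -> float:
        """Unnormalised rate of ``context -> alt``.

        Returns 0 with a warning for channels whose context was never seen;
        normalisation across a region happens in the catalogue module.
        """
        c5, ref, c3 = context
        i5, iref, i3 = BASE_INDEX[c5], BASE_INDEX[ref], BASE_INDEX[c3]
        ialt = BASE_INDEX[alt]
        if iref == ialt:
            raise ValueError(f"alt equals ref ({ref})")
        if self.context_counts[i5, iref, i3] == 0:
            warnings.warn(
                f"context {c5}{ref}{c3} never observed in included transcripts; "
                "rate treated as 0",
                stacklevel=2,
            )
            return 0.0
        return float(self.rate[i5, iref, i3, ialt])

    def total_mutations(self) -> float:
        return float(self.mutation_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """192-row table (ctx5, ref, ctx3, alt, context_count, mutation_count, rate)."""
        rows = []
        for i5, c5 in enumerate(BASES):
            for iref, ref in enumerate(BASES):
                for i3, c3 in enumerate(BASES):
                    for ialt, alt in enumerate(BASES):
                        if ialt == iref:
                            continue
                        rows.append(
                            (
                                c5,
                                ref,
                                c3,
                                alt,
                                self.context_counts[i5, iref, i3],
                                self.mutation_counts[i5, iref, i3, ialt],
                                self.rate[i5, iref, i3, ialt],
                            )
                        )
        return pd.DataFrame(
            rows,
            columns=[
                "ctx5",
                "ref",
                "ctx3",
                "alt",
                "context_count",
                "mutation_count",
                "rate",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrinucleotideSpectrum":
        rate = np.zeros((4, 4, 4, 4))
        ctx = np.zeros((4, 4, 4))
        muts = np.zeros((4, 4, 4, 4))
        for row in frame.itertuples(index=False):
            i5, iref, i3, ialt = (
                BASE_INDEX[row.ctx5],
                BASE_INDEX[row.ref],
                BASE_INDEX[row.ctx3],
                BASE_INDEX[row.alt],
            )
            rate[i5, iref, i3, ialt] = row.rate
            ctx[i5, iref, i3] = row.context_count
            muts[i5, iref, i3, ialt] = row.mutation_count
        return cls(rate=rate, context_counts=ctx, mutation_counts=muts)


def select_longest_transcript(transcripts: Iterable[Transcript]) -> Transcript:
    """Pick the transcript with the longest CDS; ties broken by the
    lexicographically smallest transcript_id."""
    ts = list(transcripts)
    if not ts:
        raise MissingInputError("no transcripts supplied")
    return min(ts, key=lambda t: (-t.length, t.transcript_id))


def context_of(transcript: Transcript, cds_position: int) -> tuple[str, str, str]:
    """Trinucleotide context of a CDS position, read in transcription direction.

    Position 1 borrows the upstream flank; the last position borrows the
    downstream flank; internal positions use spliced CDS neighbours.
    """
    if not 1 <= cds_position <= transcript.length:
        raise BoundsError(
            f"position {cds_position} outside CDS of length {transcript.length}"
        )
    padded = (
        transcript.upstream_flank + transcript.cds_sequence + transcript.downstream_flank
    )
    i = cds_position  # padded index of the reference base
    return (padded[i - 1], padded[i], padded[i + 1])


def _select_per_gene(transcripts: Iterable[Transcript]) -> dict[str, Transcript]:
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return {g: select_longest_transcript(ts) for g, ts in by_gene.items()}


def estimate_spectrum(
    mutations: Iterable[MutationRecord],
    transcripts: Iterable[Transcript],
    *,
    count_weighted: bool = True,
    restrict_to_mutated_genes: bool = True,
) -> TrinucleotideSpectrum:
    """Estimate the 192-channel spectrum from observed SNVs.

    The numerator of each channel is the (recurrence-weighted, unless
    ``count_weighted=False``) number of observed mutations with that context
    and alternate base; the denominator is the number of occurrences of the
    context in the selected (longest-per-gene) transcripts. By default only
    genes carrying at least one mutation contribute to the denominator.
    Positions with a non-ACGT trinucleotide are excluded from both.
    """
    mutations = list(mutations)
    selected = _select_per_gene(transcripts)

    if restrict_to_mutated_genes and mutations:
        genes = {m.gene_id for m in mutations}
        missing = genes - selected.keys()
        if missing:
            raise MissingInputError(
                f"no transcript for mutated gene(s): {sorted(missing)}"
            )
        included = {g: selected[g] for g in genes}
    else:
        included = selected

    context_counts = np.zeros((4, 4, 4))
    for t in included.values():
        padded = t.upstream_flank + t.cds_sequence + t.downstream_flank
        idx = np.array([BASE_INDEX.get(b, -1) for b in padded], dtype=np.int64)
        i5, iref, i3 = idx[:-2], idx[1:-1], idx[2:]
        ok = (i5 >= 0) & (iref >= 0) & (i3 >= 0)
        np.add.at(context_counts, (i5[ok], iref[ok], i3[ok]), 1)

    mutation_counts = np.zeros((4, 4, 4, 4))
    for m in mutations:
        t = included.get(m.gene_id) or selected.get(m.gene_id)
        if t is None:
            raise MissingInputError(f"no transcript for gene {m.gene_id}")
        if m.cds_position > t.length:
            raise BoundsError(
                f"{m.gene_id}:{m.cds_position} outside CDS ({t.length} nt)"
            )
        seq_ref = t.cds_sequence[m.cds_position - 1]
        if seq_ref != m.ref:
            raise DataConsistencyError(
                f"{m.gene_id}:{m.cds_position} ref {m.ref} != transcript base {seq_ref}"
            )
        c5, ref, c3 = context_of(t, m.cds_position)
        if any(b not in BASE_INDEX for b in (c5, ref, c3)):
            continue  # ambiguous context excluded from numerator too
        w = m.count if count_weighted else 1
        mutation_counts[
            BASE_INDEX[c5], BASE_INDEX[ref], BASE_INDEX[c3], BASE_INDEX[m.alt]
        ] += w

    denom = context_counts[:, :, :, None]
    rate = np.where(denom > 0, mutation_counts / np.where(denom > 0, denom, 1.0), 0.0)

    return TrinucleotideSpectrum(
        rate=rate, context_counts=context_counts, mutation_counts=mutation_counts
    )


def random_spectrum(
    seed: int | np.random.Generator,
    mean_rate: float = 1e-3,
    sigma: float = 1.0,
    context_count: int = 1000,
) -> TrinucleotideSpectrum:
    """A synthetic lognormal spectrum, useful as planted truth in simulations.

    All 192 channels get a positive rate drawn from
    LogNormal(log(mean_rate), sigma); context counts are constant.
    """
    rng = np.random.default_rng(seed)
    rate = rng.lognormal(mean=np.log(mean_rate), sigma=sigma, size=(4, 4, 4, 4))
    for i in range(4):
        rate[:, i, :, i] = 0.0
    ctx = np.full((4, 4, 4), float(context_count))
    return TrinucleotideSpectrum(
        rate=rate, context_counts=ctx, mutation_counts=rate * ctx[..., None]
    )
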