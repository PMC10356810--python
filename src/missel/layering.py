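"""Exclude-and-retest layering.

Strong selection of one mutation category can mask weaker selection of
another: if destabilising mutations are enriched threefold, the proportion
of observed mutations on, say, the ligand-binding interface is diluted and a
direct test may find nothing. The layering procedure removes an
already-explained category from *both* the null model (renormalising the
probabilities) and the observed data, then re-tests the remaining features
on the remainder; iterating over an ordered list of hypothesised layers
classifies the mutation set and leaves a residual of unexplained mutations.

Entries matching several layers are excluded at the first matching layer;
the exclusion order is explicit analyst configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalogue import ObservedMutationSet, SnvCatalogue
from .errors import DegenerateLayerError
from .stats import SelectionTestResult, binomial_feature_test, monte_carlo_test

logger = logging.getLogger(__name__)

UNDERPOWERED_N = 5  # layers reaching fewer observed mutations are flagged

__all__ = ["LayerSpec", "LayeredResult", "exclude", "layered_analysis"]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the exclude-and-retest procedure.

    ``feature`` is the column (Boolean for the binomial test, numeric score
    for the Monte Carlo test) to test at this layer; ``exclude_if`` is the
    predicate removed from null and observed before the *next* layer (default:
    the feature itself, for Boolean features).
    """

    feature: str
    test: str = "binomial"  # "binomial" | "monte_carlo"
    exclude_if: str | None = None
    statistic: str = "median"  # Monte Carlo only

    def exclusion_predicate(self) -> str | None:
        if self.exclude_if is not None:
            return self.exclude_if
        return self.feature if self.test == "binomial" else None


@dataclass
class LayeredResult:
    """Ordered per-layer results plus the residual summary."""

    results: list[SelectionTestResult]
    n_total: int
    n_residual: int
    status: str = "complete"  # or "halted:<reason>"
    overlap_tally: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_explained(self) -> float:
        if self.n_total == 0:
            return 0.0
        return 1.0 - self.n_residual / self.n_total


def exclude(
    catalogue: SnvCatalogue,
    observed: ObservedMutationSet,
    predicate: str,
    label: str | None = None,
) -> tuple[SnvCatalogue, ObservedMutationSet]:
    """Remove entries matching ``predicate`` from null and observed alike.

    The surviving null probabilities are renormalised to sum 1 and the
    exclusion label is appended to the catalogue's provenance. Emptying
    either side raises :class:`DegenerateLayerError`.
    """
    mask = catalogue.eval_predicate(predicate)
    keep = ~mask
    if not keep.any():
        raise DegenerateLayerError(f"exclusion {predicate!r} removes every entry")
    remaining_mass = float(catalogue.prob[keep].sum())
    if remaining_mass <= 0:
        raise DegenerateLayerError(
            f"exclusion {predicate!r} removes all null probability mass"
        )
    new_counts = observed.counts[keep]
    if new_counts.sum() == 0 and observed.n > 0:
        raise DegenerateLayerError(
            f"exclusion {predicate!r} removes every observed mutation"
        )
    entries = catalogue.entries.loc[keep].reset_index(drop=True).copy()
    entries["prob"] = entries["prob"] / remaining_mass
    new_cat = SnvCatalogue(
        region_id=catalogue.region_id,
        entries=entries,
        class_filter=catalogue.class_filter,
        excluded_lookup=catalogue.excluded_lookup,
        exclusions=catalogue.exclusions + (label or predicate,),
    )
    new_obs = ObservedMutationSet(
        region_id=observed.region_id, counts=new_counts, dropped=dict(observed.dropped)
    )
    return new_cat, new_obs


def layered_analysis(
    catalogue: SnvCatalogue,
    observed: ObservedMutationSet,
    layers: Sequence[LayerSpec],
    *,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> LayeredResult:
    """Run an ordered list of layers, excluding after each test.

    Per layer: test the layer's feature on the current (cumulatively
    excluded) null and observed, then apply the layer's exclusion predicate
    before the next layer. Layers whose observed size falls below
    ``UNDERPOWERED_N`` are flagged rather than silently trusted; a layer that
    empties the data halts the procedure with partial results and an
    explicit status.
    """
    rng = np.random.default_rng(seed)
    results: list[SelectionTestResult] = []
    overlap: dict[str, int] = {}
    n_total = observed.n
    cat, obs = catalogue, observed
    status = "complete"

    for i, layer in enumerate(layers):
        if layer.feature not in cat.entries.columns:
            raise KeyError(f"layer {i}: unknown feature {layer.feature!r}")
        try:
            if layer.test == "binomial":
                res = binomial_feature_test(obs, cat, layer.feature)
            elif layer.test == "monte_carlo":
                res = monte_carlo_test(
                    obs, cat, layer.feature, statistic=layer.statistic,
                    n_draws=n_draws, seed=rng,
                )
            else:
                raise ValueError(f"layer {i}: unknown test {layer.test!r}")
        except DegenerateLayerError:
            raise
        except Exception as exc:  # degenerate feature/observation on this layer
            status = f"halted:layer {i} ({layer.feature}): {exc}"
            logger.warning(status)
            break
        res.underpowered = res.n < UNDERPOWERED_N
        results.append(res)

        predicate = layer.exclusion_predicate()
        if predicate is not None:
            try:
                n_before = obs.n
                cat, obs = exclude(cat, obs, predicate, label=layer.feature)
                overlap[layer.feature] = n_before - obs.n
            except DegenerateLayerError as exc:
                status = f"halted:layer {i} exclusion ({predicate}): {exc}"
                logger.warning(status)
                obs = ObservedMutationSet(region_id=obs.region_id,
                                          counts=np.zeros(0, dtype=np.int64))
                break

    return LayeredResult(
        results=results,
        n_total=n_total,
        n_residual=obs.n,
        status=status,
        overlap_tally=overlap,
    )
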