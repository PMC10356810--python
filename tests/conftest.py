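import numpy as np
import pytest

import missel as ms


@pytest.fixture(scope="session")
def transcript():
    """A 100-codon synthetic transcript (deterministic)."""
    return ms.simulate_transcript(100, seed=11)


@pytest.fixture(scope="session")
def spectrum():
    """A positive-rate 192-channel spectrum (deterministic)."""
    return ms.random_spectrum(12)


@pytest.fixture(scope="session")
def catalogue(transcript, spectrum):
    """Missense null catalogue with planted partitions and synthetic ∆∆G."""
    cat = ms.build_null(ms.enumerate_snvs(transcript), spectrum,
                        region_id=transcript.gene_id)
    cat = ms.plant_partition_features(cat, seed=13)
    cat.entries["ddg"] = ms.simulate_ddg(cat, seed=14)
    return cat


@pytest.fixture()
def neutral_observed(catalogue):
    scenario = ms.SelectionScenario(layers=(), n_mutations=200)
    return ms.simulate_mutations(catalogue, scenario, seed=15)


def make_toy_catalogue(probs, scores, score_name="ddg"):
    """Minimal catalogue wrapper around explicit probabilities and scores."""
    import pandas as pd

    probs = np.asarray(probs, dtype=float)
    m = len(probs)
    entries = pd.DataFrame(
        {
            "cds_pos": np.arange(1, m + 1),
            "ref": ["A"] * m,
            "alt": ["C"] * m,
            "residue": np.arange(1, m + 1),
            "aa_ref": ["K"] * m,
            "aa_alt": ["Q"] * m,
            "consequence": ["missense"] * m,
            "ctx5": ["A"] * m,
            "ctx3": ["A"] * m,
            "prob": probs / probs.sum(),
            score_name: np.asarray(scores, dtype=float),
        }
    )
    return ms.SnvCatalogue(region_id="toy", entries=entries,
                           class_filter=frozenset({"missense"}))
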