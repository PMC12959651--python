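import numpy as np
import pytest

from delpath.io import DeletionVariant, ProteinRecord
from delpath.simulate import (
    SimConfig,
    example_scales,
    providers_for,
    simulate_proteome,
    simulate_variants,
)


@pytest.fixture(scope="session")
def toy_protein():
    return ProteinRecord("P1", "MKLVNAQWERTY")


@pytest.fixture(scope="session")
def small_proteome():
    """A compact simulated study: 60 proteins, 150 labelled deletions."""
    cfg = SimConfig(n_proteins=60, n_variants=150, length_range=(60, 200), seed=11)
    proteome = simulate_proteome(cfg)
    variants = simulate_variants(proteome, cfg)
    return proteome, variants, cfg


@pytest.fixture(scope="session")
def scales():
    return example_scales()


@pytest.fixture(scope="session")
def small_feature_table(small_proteome, scales):
    from delpath.features import FeatureExtractor

    proteome, variants, _ = small_proteome
    extractor = FeatureExtractor(
        proteome.proteins,
        scales=scales,
        tracks=proteome.tracks,
        providers=providers_for(proteome),
    )
    extractor.fit(variants)
    return extractor.transform(variants)
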