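import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")

from dualrna.annotations import Annotation, FeatureAnnotation
from dualrna.simulate import desk_config, generate_annotations, simulate_counts
from dualrna.counting import remove_rrna
from dualrna.normalize import normalize_dual


def micro_config(seed=0, **overrides):
    """Very small simulation for fast unit tests."""
    defaults = dict(
        n_host_genes=40,
        n_phage_genes=9,
        library_size_range=(50_000, 50_000),
    )
    defaults.update(overrides)
    return desk_config(seed=seed, **defaults)


@pytest.fixture(scope="session")
def toy_annotation():
    """Two replicons, hand-placed features, for counting and normalization."""
    feats = [
        FeatureAnnotation("geneA", "host", "host_chr", 100, 1100, "+", "ORF",
                          product="protein A"),
        FeatureAnnotation("geneB", "host", "host_chr", 1200, 2200, "-", "ORF",
                          product="protein B"),
        FeatureAnnotation("rrna16S", "host", "host_chr", 2400, 3889, "+", "rRNA",
                          product="16S ribosomal RNA"),
        FeatureAnnotation("trnaX", "host", "host_chr", 4000, 4075, "+", "tRNA"),
        FeatureAnnotation("geneP", "phage", "phage_chr", 50, 1050, "+", "ORF",
                          product="phage protein P"),
    ]
    return Annotation(feats, {"host_chr": 5000, "phage_chr": 2000})


@pytest.fixture(scope="session")
def desk_run():
    """One desk-scale simulation shared by read-only tests."""
    cfg = desk_config(seed=11)
    ann = generate_annotations(cfg)
    table, truth = simulate_counts(cfg, ann)
    clean, rrna_frac = remove_rrna(table, ann)
    norm = normalize_dual(clean, ann)
    return dict(
        config=cfg, ann=ann, table=table, truth=truth,
        clean=clean, rrna_frac=rrna_frac, norm=norm,
    )
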