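import numpy as np
import pandas as pd
import pytest

from methpairs import ClassMap, ProbeSet, SyntheticConfig, generate_dataset


def make_probeset(positions, beta, classes=None, chrom="1", sample_names=None,
                  recode=True):
    """Small ProbeSet builder for unit tests.

    positions: list of ints (one chromosome unless chrom is a list);
    beta: array-like (n_probes, n_samples); classes: per-probe label or
    iterable of labels (defaults to a single shared class "gene").
    """
    beta = np.asarray(beta, dtype=float)
    n = len(positions)
    if classes is None:
        classes = ["gene"] * n
    raw = [frozenset([c]) if isinstance(c, str) else frozenset(c)
           for c in classes]
    chroms = [chrom] * n if isinstance(chrom, str) else list(chrom)
    sample_names = sample_names or [f"s{k + 1}" for k in range(beta.shape[1])]
    probes = pd.DataFrame({
        "probe_id": [f"p{i + 1}" for i in range(n)],
        "chrom": chroms,
        "position": positions,
        "raw_classes": raw,
    })
    ps = ProbeSet(probes, beta, sample_names)
    if recode:
        labels = {c for rc in raw for c in rc}
        ps.recode(ClassMap(mapping={c: c for c in labels}))
    return ps


@pytest.fixture(scope="session")
def planted_dataset():
    """Default synthetic benchmark: ~320 clusters, 10% planted |dM|=3."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SyntheticConfig(seed=7, n_chroms=2, probes_per_chrom=120)
    return cfg, generate_dataset(cfg)
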