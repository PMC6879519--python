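import numpy as np
import pandas as pd
import pytest

from exrna_perf import CountMatrix


def build_count_matrix(
    counts: dict[str, list[int]],
    feature_ids: list[str],
    feature_class: list[str] | None = None,
    biotype: list[str] | None = None,
    chrom_class: list[str] | None = None,
    region_class: list[str] | None = None,
) -> CountMatrix:
    """Assemble a small CountMatrix with sensible annotation defaults."""
    n = len(feature_ids)
    fc = feature_class or ["endogenous"] * n
    ann = pd.DataFrame(
        {
            "feature_class": fc,
            "biotype": biotype
            or ["spike" if c.startswith("spike") else "protein_coding" for c in fc],
            "chrom_class": chrom_class
            or ["spike" if c.startswith("spike") else "nuclear" for c in fc],
            "region_class": region_class
            or ["not_applicable" if c.startswith("spike") else "exonic" for c in fc],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    df = pd.DataFrame(counts, index=ann.index, dtype=np.int64)
    return CountMatrix(df, ann)


@pytest.fixture
def toy_cm() -> CountMatrix:
    """3 endogenous genes + 2 ERCC spikes across two samples."""
    return build_count_matrix(
        {"s1": [100, 25, 0, 900, 100], "s2": [25, 100, 3, 450, 50]},
        ["g1", "g2", "g3", "ERCC_1", "ERCC_2"],
        feature_class=["endogenous"] * 3 + ["spike_ercc"] * 2,
    )
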