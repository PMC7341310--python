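import numpy as np
import pandas as pd
import pytest

from triohet.io_formats import CountMatrix, SampleSheet, SpliceEvent


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(100, size=(50, 6))
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
    )


@pytest.fixture
def trio_sheet() -> SampleSheet:
    rows = []
    for role, short, species in [
        ("hybrid", "hyb", "mule"),
        ("paternal_parent", "pat", "horse"),
        ("maternal_parent", "mat", "donkey"),
    ]:
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"muscle_{short}_{rep}",
                    "species_role": role,
                    "species_name": species,
                    "tissue": "muscle",
                    "replicate": rep,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def make_se_event(event_id="ev1", gene_id="gA", inc_counts=None, skp_counts=None, lI=198, lS=99):
    samples = sorted((inc_counts or {"a1": 50}).keys())
    inc_counts = inc_counts or {s: 50 for s in samples}
    skp_counts = skp_counts or {s: 50 for s in samples}
    return SpliceEvent(
        event_id=event_id,
        gene_id=gene_id,
        event_type="SE",
        chrom="chr1",
        strand="+",
        inclusion_chain=[(100, 200), (500, 600), (1000, 1100)],
        exclusion_chain=[(100, 200), (1000, 1100)],
        eff_len_inclusion=lI,
        eff_len_exclusion=lS,
        inclusion_counts=inc_counts,
        skipping_counts=skp_counts,
    )
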