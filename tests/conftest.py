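import numpy as np
import pandas as pd
import pytest

from brainenrich import GeneRegionMatrix, ProbeExpressionBundle


@pytest.fixture
def toy_bundle():
    """4 probes (3 genes) x 3 samples across 2 regions."""
    expr = pd.DataFrame(
        {
            "s1": [2.0, 4.0, 1.0, 0.5],
            "s2": [3.0, 5.0, 2.0, 1.5],
            "s3": [4.0, 6.0, 3.0, 2.5],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return ProbeExpressionBundle(
        donor_id="d1",
        expression=expr,
        sample_region={"s1": "cortex", "s2": "cortex", "s3": "raphe"},
        probe_gene={"p1": "GENEA", "p2": "GENEA", "p3": "GENEB", "p4": "GENEC"},
    ).validate()


@pytest.fixture
def toy_reference():
    """Donor-averaged 6-gene x 3-region reference with known values."""
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(6)]
    values = pd.DataFrame(
        rng.normal(size=(6, 3)), index=genes, columns=["r1", "r2", "r3"]
    )
    return GeneRegionMatrix(values=values, stage="donor_averaged")


@pytest.fixture
def bundle_files(toy_bundle, tmp_path):
    """The toy bundle written to the three-file atlas layout."""
    from brainenrich import write_bundle

    return write_bundle(toy_bundle, tmp_path / "donor1")
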