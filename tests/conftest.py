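import pandas as pd
import pytest

from sctrace import synthdata as sd

# Library sizes back-solved from the printed count/RPM pairs of the
# two-isoform worked example: 35 reads <-> 59.72 RPM (ICM) and
# 142 reads <-> 131.43 RPM (ESC).
ICM_LIBRARY = 586_068
ESC_LIBRARY = 1_080_423


@pytest.fixture(scope="session")
def default_population():
    """Default staged population (9 ICM / 3 epiblast / 2+3+2 outgrowth / 12 ESC)."""
    config, truth = sd.default_config(seed=1)
    return sd.generate_counts(config, truth)


@pytest.fixture(scope="session")
def two_isoform_fixture():
    """Toy two-variant gene with reads planted at the worked-example counts."""
    models = sd.random_gene_models(n_genes=1, n_exons=3, seed=0)
    abundances = pd.DataFrame(
        {"ICM": [88, 35], "ESC": [13, 142]},
        index=[m.variant_id for m in models],
    )
    reads, reference, truth = sd.generate_junction_reads(
        models, abundances, mismatch_rate=0.0, seed=2
    )
    return models, abundances, reads, reference, truth
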