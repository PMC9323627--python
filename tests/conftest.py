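import numpy as np
import pandas as pd
import pytest

from owasjoint.data_io import ReferencePanel, write_plink
from owasjoint.fixtures import make_fixtures


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """Synthetic toy input bundle (GWAS, 3 weight files, TSS, PLINK panel)."""
    return make_fixtures(tmp_path_factory.mktemp("toy"), seed=11)


def make_panel(tmp_path, variants: pd.DataFrame, dosages: np.ndarray) -> ReferencePanel:
    """Round-trip a dosage matrix through the PLINK triple on disk."""
    prefix = tmp_path / "panel"
    write_plink(prefix, variants, dosages)
    return ReferencePanel.from_plink(prefix)


@pytest.fixture
def small_panel(tmp_path):
    """Deterministic 6-sample x 4-SNP panel with one monomorphic SNP."""
    variants = pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3", "rs4"],
            "chrom": ["1"] * 4,
            "pos": [100, 200, 300, 400],
            "a1": ["A", "C", "G", "T"],
            "a2": ["G", "T", "A", "C"],
        }
    )
    dosages = np.array(
        [
            [0, 1, 2, 2],
            [1, 0, 1, 2],
            [2, 2, 0, 2],
            [0, 1, 1, 2],
            [1, 2, 2, 2],
            [2, 0, 0, 2],
        ],
        dtype=float,
    )  # rs4 is monomorphic
    return make_panel(tmp_path, variants, dosages)
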