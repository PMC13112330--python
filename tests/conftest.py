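import numpy as np
import pandas as pd
import pytest

from benthochange.annotations import ANNOTATION_COLUMNS


def make_annotations(rows: list[dict]) -> pd.DataFrame:
    """Build an annotation frame from sparse row dicts with sane defaults."""
    defaults = {
        "site_id": "S1", "timepoint": "T1", "phylum": "Porifera",
        "otu": "Farrea occa", "x_m": 0.0, "y_m": 0.0, "depth_m": 800.0,
        "growth": 0, "tissue_loss": 0, "biofouling": 0, "orientation": 0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults, individual_id=f"ind-{i:03d}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out, columns=list(ANNOTATION_COLUMNS))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def t1_cohort():
    """Six scored survivors: growth scores [0,0,1,1,2,3], one tissue loss."""
    return make_annotations([
        {"growth": 0},
        {"growth": 0},
        {"growth": 1},
        {"growth": 1},
        {"growth": 2, "tissue_loss": 1},
        {"growth": 3},
    ])
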