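import pandas as pd
import pytest

import screenscore as ss


@pytest.fixture
def toy_screen_csv(tmp_path):
    """6-row toy screen: one compound treatment plus one control well each."""
    path = tmp_path / "screen.csv"
    pd.DataFrame(
        {
            "sample_id": ["S1"] * 6,
            "treatment_id": ["ixazomib"] * 4 + ["", ""],
            "treatment_type": ["single"] * 4 + ["", ""],
            "concentration_nM": [1, 10, 100, 1000, "", ""],
            "replicate": [1, 1, 1, 1, 1, 1],
            "signal": [9000, 7000, 4000, 2500, 10000, 2000],
            "well_role": ["compound"] * 4 + ["neg_ctrl", "pos_ctrl"],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def toy_library_tsv(tmp_path):
    path = tmp_path / "library.tsv"
    pd.DataFrame(
        {
            "treatment_id": ["ixazomib", "venetoclax", "ven+ixa"],
            "type": ["single", "single", "combination"],
            "components": ["ixazomib", "venetoclax", "venetoclax;ixazomib"],
            "targets": ["PSMB5", "BCL2;BCL2L1", "BCL2;BCL2L1;PSMB5"],
            "series": ["1;10;100;1000;10000"] * 3,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def reference_fit():
    """The reference curve: full kill, IC50 100 nM, unit slope, tested 1-10,000 nM."""
    return ss.LogisticFit(
        top=100.0, bottom=0.0, log10_ic50=2.0, hill=1.0,
        rss=0.0, converged=True, x_min=0.0, x_max=4.0,
    )
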