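import numpy as np
import pytest

from dosepred.data_io import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


SERIES_MATRIX_OK = """!Series_title\t"copper response"
!Series_geo_accession\t"GSETEST"
!Sample_geo_accession\t"GSM1"\t"GSM2"\t"GSM3"
!Sample_characteristics_ch1\t"dose: 1.5"\t"dose: 3.0"\t"dose: 6.0"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"
"probe_a"\t1.0\t2.0\t3.0
"probe_b"\t4.0\t5.0\t6.0
"probe_c"\t7.0\t8.0\t9.0
"probe_d"\t10.0\t11.0\t12.0
!series_matrix_table_end
"""


@pytest.fixture
def series_matrix_file(tmp_path):
    def make(text=SERIES_MATRIX_OK, name="series.txt"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return make


@pytest.fixture
def small_dataset(rng):
    n, p = 24, 6
    X = rng.standard_normal((n, p))
    y = 2.0 * X[:, 0] - X[:, 1] + 0.3 * rng.standard_normal(n)
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(p)],
        X=X,
        y=y,
    )
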