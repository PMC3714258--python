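import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tfqpcr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TOY_CT_TSV = """\
gene_id\tgenotype\ttime_point\treplicate\trun_id\tct
AT1G01010\tCol-0\t0\t1\trunA\t25.0
AT1G01010\tCol-0\t0\t2\trunA\t25.2
AT1G01010\tCol-0\t0\t3\trunA\t24.8
AT2G02020\tCol-0\t0\t1\trunA\t31.0
AT2G02020\tCol-0\t0\t2\trunA\t30.6
AT2G02020\tCol-0\t0\t3\trunA\t30.8
AT1G55060\t\t0\t1\trunA\t21.9
AT1G55060\t\t0\t2\trunA\t22.1
AT1G55060\t\t0\t3\trunA\t22.3
AT1G55060\t\t0\t4\trunA\t22.5
"""


@pytest.fixture
def toy_ct_path(tmp_path):
    path = tmp_path / "toy_ct.tsv"
    path.write_text(TOY_CT_TSV)
    return path


@pytest.fixture
def toy_ct_table(toy_ct_path):
    return tfqpcr.read_ct_table(toy_ct_path)


@pytest.fixture(scope="session")
def small_noiseless():
    """Deterministic noiseless dataset with every planted class present."""
    cfg = tfqpcr.GeneratorConfig(n_genes=110, noise_sd=0.0, seed=3)
    table, truth = tfqpcr.generate_dataset(cfg)
    calls = tfqpcr.run_comparison_modes(table)
    return cfg, table, truth, calls
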