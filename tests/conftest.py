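import pytest

import thioscreen as ts


@pytest.fixture(scope="session")
def table2():
    return ts.load_table2()


@pytest.fixture(scope="session")
def small_cfg():
    return ts.SimConfig(
        seed=11, n_snps=80, n_eai_snps=8, n_clinical_snps=2,
        noise_sigma=0.2, dropout_rate=0.0, nocall_rate=0.0,
    )


@pytest.fixture(scope="session")
def line_genotypes(small_cfg):
    return ts.simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def allele_signals(small_cfg, line_genotypes):
    return ts.simulate_allele_signals(line_genotypes, small_cfg)


@pytest.fixture(scope="session")
def patient_genotypes(small_cfg):
    return ts.simulate_genotypes(small_cfg, small_cfg.n_patients, "patient")


@pytest.fixture(scope="session")
def patients(small_cfg, patient_genotypes):
    return ts.simulate_patients(small_cfg, patient_genotypes)
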