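import pytest

from hcpquant import GeneratorConfig, analyze, generate_dataset


def run_full_analysis(ds):
    return analyze(
        ds.evidence,
        records=ds.all_records(),
        product_records=ds.product_records,
        design=ds.design,
        annotations=ds.annotations,
        risk_list=ds.risk_list,
        class_map=ds.class_map,
    )


@pytest.fixture(scope="session")
def full_analysis():
    """The standard end-to-end analysis call, as a reusable helper."""
    return run_full_analysis


@pytest.fixture(scope="session")
def noiseless_ds():
    cfg = GeneratorConfig(
        seed=11,
        n_products=3,
        response_factor_sigma=0.0,
        injection_sigma=0.0,
        dropout_midpoint_intensity=None,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_ds):
    return run_full_analysis(noiseless_ds)


@pytest.fixture(scope="session")
def noisy_ds():
    return generate_dataset(GeneratorConfig(seed=5, n_products=3))


@pytest.fixture(scope="session")
def noisy_result(noisy_ds):
    return run_full_analysis(noisy_ds)
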