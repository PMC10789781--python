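import pytest
from hypothesis import HealthCheck, settings

import radlayers as rl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> rl.SimulationConfig:
    """Desk-scale simulation shared by most integration tests."""
    return rl.SimulationConfig(
        seed=11,
        n_probes=4000,
        n_chroms=2,
        chrom_length=8_000_000,
        genes_per_chrom=40,
        peaks_per_mark=300,
        n_genes_expr=1000,
    )


@pytest.fixture(scope="session")
def bundle(small_config) -> rl.SimulatedBundle:
    return rl.simulate_all(small_config)


@pytest.fixture(scope="session")
def layer_model(bundle) -> rl.LayerModel:
    scores, _ = rl.assign_hic_scores(bundle.manifest, bundle.hic_track)
    return rl.build_layers(scores, bundle.manifest)


@pytest.fixture(scope="session")
def fe_dmps(bundle):
    """Called DMP table for the iron condition vs pooled controls."""
    exp_m = bundle.experiment.to_m()
    control = rl.define_control(exp_m)
    dmps = rl.call_dmps(
        exp_m,
        exp_m.sample_ids("Fe", 1.0, "48h"),
        exp_m.control_sample_ids(),
        control,
    )
    return rl.classify_subgroups(dmps, control), control
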