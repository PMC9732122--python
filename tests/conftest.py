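import pytest

from diazodiel.pipeline import RunConfig, run_pipeline


def make_config(tmp_dir, noise_cv: float = 0.0, seed: int = 1) -> RunConfig:
    cfg = RunConfig.default()
    cfg.seed = seed
    cfg.output_dir = tmp_dir
    for sp in cfg.species.values():
        sp.noise_cv = noise_cv
    return cfg


@pytest.fixture(scope="session")
def noise_free_report(tmp_path_factory):
    """One full noise-free synthetic pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("noise_free_run")
    cfg = make_config(out)
    return cfg, run_pipeline(cfg)
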