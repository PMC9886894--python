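import pytest

from cogdep import GeneratorConfig, generate_corpus, generate_seed_and_pool


@pytest.fixture(scope="session")
def small_corpus():
    """40 users x ~20 posts, fully separable, fixed seed."""
    cfg = GeneratorConfig(n_users=40, posts_per_user_mean=20, seed=101)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def seed_pool():
    cfg = GeneratorConfig(seed=202)
    return generate_seed_and_pool(
        cfg, n_seed_distorted=200, n_seed_normal=300, pool_size=600
    )
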