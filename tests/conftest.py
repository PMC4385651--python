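import numpy as np
import pytest

from rffr.synthetic_data import SyntheticSpec, separated_means


def make_spec(
    n_clusters: int = 3,
    n_rows: int = 300,
    seed: int = 0,
    n_ligands: int = 4,
    runs_per_pair: int = 3,
    feb_noise_sd: float = 0.3,
    best_offset: float = -2.0,
    sep_sds: float = 12.0,
    **kwargs,
) -> SyntheticSpec:
    """Small planted-structure spec for fast tests: equal weights, separated
    Gaussian clusters, one distinguished best-binding cluster."""
    sds = np.tile([7.0, 12.0, 0.7, 0.03], (n_clusters, 1))
    rng = np.random.default_rng(555)
    offsets = rng.uniform(-0.8, 0.0, size=n_clusters)
    offsets[0] = best_offset
    defaults = dict(
        n_clusters=n_clusters,
        duration_ns=n_rows / 1000.0,
        interval_ps=1.0,
        cluster_means=separated_means(n_clusters, sds, min_sep_sds=sep_sds),
        cluster_sds=sds,
        mixing_weights=np.full(n_clusters, 1.0 / n_clusters),
        ligand_ids=tuple(f"L{i}" for i in range(n_ligands)),
        feb_base=rng.uniform(-9.0, -6.0, size=n_ligands),
        feb_cluster_offset=offsets,
        feb_noise_sd=feb_noise_sd,
        runs_per_pair=runs_per_pair,
        seed=seed,
    )
    defaults.update(kwargs)
    return SyntheticSpec(**defaults)


@pytest.fixture
def small_spec() -> SyntheticSpec:
    return make_spec()
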