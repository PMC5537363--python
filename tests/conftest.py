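import numpy as np
import pytest

import sporecyte as sc

# Morphology-scale spore parameters used throughout the tests: a ~10 μm
# long-axis ellipsoidal spore has a cross-section of ~50 μm², which keeps
# several hundred spores per field physically packable.
SPORE_AREA = 50.0


def scene_spec(**kw) -> sc.SceneSpec:
    base = dict(
        field_um=(1200.0, 900.0),
        pixel_size_um=0.75,
        n_spores=100,
        single_area_mean_um2=SPORE_AREA,
        single_area_cv=0.15,
        cluster_fraction=0.0,
        pad_per_spore_area_um2=0.0,
        seed=0,
    )
    base.update(kw)
    return sc.SceneSpec(**base)


def area_gate(a1: float = SPORE_AREA) -> sc.GateSpec:
    """Area-only spore gate: keeps clusters of any shape for the correction."""
    return sc.GateSpec(min_area_um2=0.3 * a1, max_circularity=np.inf)


@pytest.fixture(scope="session")
def clustered_scene() -> sc.Scene:
    """One full-size field: 300 spores, 20% clustered, default noise."""
    return sc.generate_scene(
        scene_spec(
            field_um=(2400.0, 1800.0), n_spores=300, cluster_fraction=0.2, seed=42
        )
    )


@pytest.fixture(scope="session")
def pad_scene() -> sc.Scene:
    """Noise-free field of 30 spores each carrying a 100 μm² adhesive pad."""
    return sc.generate_scene(
        scene_spec(
            n_spores=30,
            single_area_cv=0.1,
            pad_per_spore_area_um2=100.0,
            background_noise_sd=0.0,
            seed=3,
        )
    )
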