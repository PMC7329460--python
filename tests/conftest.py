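import numpy as np
import pandas as pd
import pytest

import semifield as sf


@pytest.fixture(scope="session")
def tiny_markers():
    return sf.MarkerMatrix(
        ["a", "b", "c"],
        [[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [0.0, 0.0, 2.0]],
        ["m1", "m2", "m3"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small grain simulation with all GM2 terms active."""
    cfg = sf.SimulationConfig(
        seed=42, n_lines=15, n_markers=300, beds=2, rows_per_bed=25,
        variances={"g": 1.5, "l": 0.5, "g_n": 0.3, "l_n": 0.2,
                   "r": 0.4, "s1": 0.1, "s2": 0.25, "e": 1.0},
    )
    return sf.simulate_trait(cfg)


@pytest.fixture(scope="session")
def small_g(small_sim):
    return sf.vanraden_g(small_sim.markers)


@pytest.fixture(scope="session")
def gm1_bundle(small_sim, small_g):
    return sf.assemble_model("GM1", small_sim.records, small_sim.layout,
                             small_g, trait="value")


@pytest.fixture(scope="session")
def gm1_bundle_ridged(small_sim):
    """GM1 bundle with a ridged G so K^-1 (MME routes) exists."""
    g = sf.vanraden_g(small_sim.markers, ridge=1e-3)
    return sf.assemble_model("GM1", small_sim.records, small_sim.layout,
                             g, trait="value")


@pytest.fixture(scope="session")
def gm2_bundle(small_sim, small_g):
    return sf.assemble_model("GM2", small_sim.records, small_sim.layout,
                             small_g, trait="value")


@pytest.fixture(scope="session")
def root_sim():
    cfg = sf.SimulationConfig(
        seed=5, n_lines=12, n_markers=300, beds=2, rows_per_bed=24,
        trait_kind="root", n_intervals=4,
        variances={"g": 1.0, "l": 0.6, "r": 0.5, "s": 0.4, "e": 1.2},
    )
    return sf.simulate_trait(cfg)


def make_root_images(seed=0, n_tubes=12, per_tube=30, lines=None, beds=(1,)):
    """Synthetic per-image root records spanning 0.5-2.4 m depth."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_tubes):
        bed = beds[i % len(beds)]
        line = (lines or [f"L{j}" for j in range(1, 7)])[i % 6]
        for k in range(per_tube):
            depth = 0.5 + 1.9 * rng.random()
            rows.append({
                "bed": bed, "tube": i + 1, "camera": i % 4 + 1,
                "depth_m": round(depth, 3),
                "length_cm": float(np.abs(rng.normal(3.0, 1.0))),
                "line": line, "valid": True,
            })
    return pd.DataFrame(rows)
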