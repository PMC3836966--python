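import numpy as np
import pytest

import physmap.synthdata as sd
from physmap.fingerprints import build_overlap_graph
from physmap.assembly import _annotate_band_counts
from physmap.pipeline import default_assembly_params
from physmap.synthdata import (
    ArmParams,
    DigestParams,
    NoiseParams,
    fingerprint_clone,
    fingerprint_library,
    scaled_arm_params,
    simulate_arm,
    simulate_library,
)


@pytest.fixture(scope="session")
def small_world():
    """A 5 Mb arm with a 500-clone library, fingerprints and overlap graph."""
    arm = simulate_arm(scaled_arm_params(5_000_000), seed=11)
    library = simulate_library(arm, n_clones=500, seed=11)
    fps, chimeric = fingerprint_library(library, seed=11)
    params = default_assembly_params(DigestParams())
    graph = build_overlap_graph(fps, params, cutoff=params.cutoff_ladder[0])
    _annotate_band_counts(graph, fps)
    return {
        "arm": arm,
        "library": library,
        "fps": fps,
        "chimeric": chimeric,
        "params": params,
        "graph": graph,
    }


@pytest.fixture(scope="session")
def clean_stacks():
    """Noise-free library of three widely separated stacks of 7 identical
    170 kb clones — the degenerate easy case where every assembly mode must
    agree."""
    digest = DigestParams()
    noise = NoiseParams(band_sigma=0.0, well_contamination_rate=0.0)
    arm = simulate_arm(ArmParams(arm_length=2_000_000, genes_per_bin=(4, 8, 2)), seed=9)
    sites = sd.DigestSiteIndex(arm.seed, digest)
    clones, k = [], 0
    for s in (100_000, 500_000, 900_000):
        for _ in range(7):
            clones.append(sd.CloneModel(f"cl{k:03d}", 1, "A", k + 1, s, s + 170_000, False))
            k += 1
    fps = [fingerprint_clone(c, sites, digest, noise, seed=9) for c in clones]
    params = default_assembly_params(digest)
    return {"fps": fps, "params": params, "n_stacks": 3, "stack_size": 7}
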