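"""Shared fixtures: small synthetic worlds reused across test modules.

Everything is generated in memory from fixed seeds; no test reads data from
outside the repository.
"""

from __future__ import annotations

import pytest

from pretrna.catalog import build_catalog
from pretrna.simulate import (ReadSimConfig, SpeciesProfile, simulate_genome,
                              simulate_reads)
from pretrna.tails import build_baits, cpm_normalize, fish_reads


@pytest.fixture(scope="session")
def arch_world():
    """A 500-gene species with geometric trailers and strong pairing avoidance."""
    profile = SpeciesProfile(
        name="synthA", n_genes=500,
        trailer_distribution={"family": "geometric", "p": 0.4},
        pairing_avoidance=0.9,
    )
    sim = simulate_genome(profile, seed=11)
    genes = build_catalog(sim.genome, sim.annotations)
    return profile, sim, genes


@pytest.fixture(scope="session")
def read_world():
    """A small multi-copy catalog plus 2 input + 2 IP fished replicates."""
    profile = SpeciesProfile(
        name="synthR", n_genes=30,
        trailer_distribution={"family": "geometric", "p": 0.4},
        copy_number_distribution={"family": "histogram",
                                  "probs": {1: 0.4, 2: 0.3, 3: 0.2, 5: 0.1}},
    )
    sim = simulate_genome(profile, seed=2)
    genes = build_catalog(sim.genome, sim.annotations)
    baits = build_baits(genes, bait_length=36)
    config = ReadSimConfig(depth=100_000, seed=7)
    runs = {}
    for cond, base_seed in (("input", 100), ("IP", 200)):
        runs[cond] = [
            simulate_reads(genes, config, condition=cond,
                           replicate=f"{cond}{i + 1}", seed=base_seed + i)
            for i in range(2)
        ]
    raw = {cond: [fish_reads(r.sequences, baits, r.replicate) for r in reps]
           for cond, reps in runs.items()}
    cpm = {cond: [cpm_normalize(t) for t in tables]
           for cond, tables in raw.items()}
    return {"profile": profile, "sim": sim, "genes": genes, "baits": baits,
            "config": config, "runs": runs, "raw": raw, "cpm": cpm}
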