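import numpy as np
import pytest

from berrylink.simulate import (
    ArraySpec,
    CommunityConfig,
    HgtPlan,
    HostSpec,
    PhageSpec,
    ProtospacerPlan,
    ReadPlan,
    simulate_community,
)


def small_config(seed: int = 13, error_rate: float = 0.0) -> CommunityConfig:
    """A miniature community (2 hosts x 1 array x 5 spacers, 2 phages) kept
    small enough for unit tests while exercising every planted feature."""
    return CommunityConfig(
        rng_seed=seed,
        hosts=[
            HostSpec("hostA", 12_000, [ArraySpec(n_spacers=5)]),
            HostSpec("hostB", 12_000, [ArraySpec(n_spacers=5)]),
        ],
        phages=[
            PhageSpec("phageA", 8_000, [1.0, 0.5]),
            PhageSpec("phageB", 8_000, [0.5, 1.0]),
        ],
        protospacer_plan=ProtospacerPlan(0.6, 2),
        read_plan=ReadPlan(150, [3_000, 3_000], error_rate, 40),
    )


@pytest.fixture(scope="session")
def small_community():
    """Error-free miniature community shared by read-level unit tests."""
    genomes, truth, reads = simulate_community(small_config())
    return genomes, truth, reads


@pytest.fixture(scope="session")
def small_hosts(small_community):
    genomes, _, _ = small_community
    return [g for g in genomes if g.id.startswith("host")]


@pytest.fixture(scope="session")
def small_phages(small_community):
    genomes, _, _ = small_community
    return [g for g in genomes if g.id.startswith("phage")]


@pytest.fixture(scope="session")
def merged_reads(small_community):
    _, _, reads = small_community
    return [r for s in sorted(reads) for r in reads[s]]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
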