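import numpy as np
import pytest

from ctpscreen import (
    ExpressionSimConfig,
    GeneSet,
    LibrarySimConfig,
    RankedProfile,
    SignaturePair,
    simulate_ctp_library,
    simulate_expression,
)


@pytest.fixture
def identity_profile():
    """Universe g0..g9, gene gi at rank i+1."""
    return RankedProfile(
        gene_ids=tuple(f"g{i}" for i in range(10)),
        ranks=np.arange(1, 11),
        compound_id="identity",
    )


@pytest.fixture
def small_signature():
    return SignaturePair(
        up=GeneSet("up", ("g000001", "g000002", "g000003")),
        down=GeneSet("down", ("g000004", "g000005", "g000006")),
    )


@pytest.fixture
def planted_expression():
    cfg = ExpressionSimConfig(
        n_genes=1000, n_deg_up=50, n_deg_down=50,
        effect_fc=4.0, noise_sd=0.25, n_per_group=3, seed=7,
    )
    return cfg, *simulate_expression(cfg)


@pytest.fixture
def planted_library(small_signature):
    cfg = LibrarySimConfig(
        n_genes=1000, n_compounds=100, n_reversers=5, strength=0.8, seed=11,
    )
    library, truth = simulate_ctp_library(cfg, small_signature)
    return cfg, small_signature, library, truth


def brute_force_es(member_ranks, n):
    """Independent full-scan KS oracle: walk every rank position 1..n,
    tracking the running member count, and take the two directional suprema
    of the deviation between the set's rank-CDF and the uniform CDF."""
    members = set(int(r) for r in member_ranks)
    t = len(members)
    count = 0
    a = -np.inf
    b = -np.inf
    for r in range(1, n + 1):
        if r in members:
            b = max(b, r / n - count / t)
            count += 1
            a = max(a, count / t - r / n)
    if a > b:
        return a, b, a
    if b > a:
        return a, b, -b
    return a, b, 0.0
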