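"""Shared fixtures: simulations reused across module and acceptance tests.

The expensive forward simulations are session-scoped so the diffusion
agreement checks, the demography ordering checks and the end-to-end
discrimination checks all reuse a single run each.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import alleleclock as ac
from alleleclock import synth
from alleleclock.simulate import (
    bottleneck_preset,
    constant_preset,
    expansion_preset,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_random_panel(
    rng: np.random.Generator,
    n_haplotypes: int | None = None,
    n_variants: int | None = None,
) -> ac.HaplotypePanel:
    """Random segregating phased panel for oracle comparisons."""
    H = n_haplotypes or int(rng.integers(4, 21))
    V = n_variants or int(rng.integers(2, 51))
    cols = []
    for _ in range(V):
        p = rng.uniform(0.05, 0.95)
        col = (rng.random(H) < p).astype(np.int8)
        if col.sum() == 0:
            col[rng.integers(0, H)] = 1
        if col.sum() == H:
            col[rng.integers(0, H)] = 0
        cols.append(col)
    matrix = np.stack(cols, axis=1)
    positions = np.sort(rng.choice(np.arange(1, 10 * V + 1), size=V, replace=False))
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, V)
    ref = bases[ref_i]
    alt = bases[(ref_i + rng.integers(1, 4, V)) % 4]
    return ac.HaplotypePanel.from_matrix(
        matrix=matrix, chrom="1", positions=positions, ref=ref, alt=alt
    )


def nc_brute_force(
    panel: ac.HaplotypePanel,
    index: int,
    mode: str = "minor",
    include_singletons: bool = False,
):
    """Independent reference NC: test every candidate in sorted order.

    Walks outward from the index position candidate by candidate with
    explicit set arithmetic, stopping at the first strict-subset or
    four-gamete candidate; returns (d_up, reason_up, d_down, reason_down).
    """
    H = panel.n_haplotypes
    C = panel.carrier_matrix(mode=mode)
    v = panel.variants
    mac = v["mac"].to_numpy()
    pos = v["pos"].to_numpy()
    chrom = v["chrom"].to_numpy()
    carriers = [set(np.flatnonzero(C[:, j]).tolist()) for j in range(panel.n_variants)]
    ci = carriers[index]

    def qualifies(j: int) -> str | None:
        if j == index or chrom[j] != chrom[index]:
            return None
        if mac[j] < (1 if include_singletons else 2):
            return None
        cj = carriers[j]
        if len(cj) == 0 or len(cj) == H:
            return None
        if cj < ci:
            return "linked_rarer"
        n11 = len(ci & cj)
        n10 = len(ci - cj)
        n01 = len(cj - ci)
        n00 = H - n11 - n10 - n01
        if n11 > 0 and n10 > 0 and n01 > 0 and n00 > 0:
            return "recombination"
        return None

    def scan(direction: int):
        side = [j for j in range(panel.n_variants) if (pos[j] - pos[index]) * direction > 0]
        side.sort(key=lambda j: abs(pos[j] - pos[index]))
        for j in side:
            r = qualifies(j)
            if r is not None:
                return int(abs(pos[j] - pos[index])), r
        return None, "censored"

    d_up, r_up = scan(-1)
    d_down, r_down = scan(+1)
    return d_up, r_up, d_down, r_down


@pytest.fixture(scope="session")
def theory_sim() -> ac.simulate.SimulationResult:
    """Constant-N run sized so that >= 2e5 mutations are introduced.

    Free recombination keeps sites independent, matching the single-locus
    diffusion the run is compared against; half the mutations are neutral
    and half carry gamma = -10.
    """
    cfg = ac.SimulationConfig(
        N=1000,
        theta=1e-4,
        rho=0.0,
        region_length=340_000,
        fraction_selected=0.5,
        gamma=-10.0,
        seed=42,
        free_recombination=True,
    )
    return ac.simulate_trajectories(cfg)


@pytest.fixture(scope="session")
def demography_sims() -> dict[str, ac.simulate.SimulationResult]:
    """Constant / expansion / bottleneck runs with a neutral-deleterious mix."""
    kw = dict(
        theta=1e-4,
        rho=0.0,
        region_length=300_000,
        fraction_selected=0.5,
        gamma=-10.0,
        free_recombination=True,
    )
    makers = {
        "constant": (constant_preset, 101),
        "expansion": (expansion_preset, 102),
        "bottleneck": (bottleneck_preset, 103),
    }
    return {
        name: ac.simulate_trajectories(maker(N=500, seed=seed, **kw))
        for name, (maker, seed) in makers.items()
    }


@pytest.fixture(scope="session")
def synthetic_run():
    """Full synthetic pipeline input: panel + truth with pure class labels.

    Neutral variants are labelled synonymous and selected variants probably
    damaging, so category comparisons align exactly with the generative
    selection classes.
    """
    cfg = synth.SyntheticConfig(
        seed=5,
        category_probabilities={
            "neutral": {"synonymous": 1.0},
            "selected": {"probably_damaging": 1.0},
        },
    )
    panel, truth = synth.generate_panel(cfg)
    synth.assign_categories(panel, truth, cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def synthetic_nc_table(synthetic_run):
    _, panel, _ = synthetic_run
    return ac.nc_scan(panel, mac_range=(2, 6))
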