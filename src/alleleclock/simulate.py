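"""Forward-in-time, individual-based Wright-Fisher simulation with selection.

The simulator tracks a population of ``2N`` phased haplotypes along a
contiguous region with recurrent mutation (infinite sites on integer
positions), crossover recombination and genic selection, and records the
origin generation of every mutation ever introduced.  True allelic age
conditional on current frequency is therefore directly observable, which is
what the diffusion theory in :mod:`alleleclock.diffusion` predicts and what
the Neighborhood-based Clock statistic is calibrated against.

Model
-----
* Discrete generations, random mating (selfing allowed), multiplicative
  fitness across sites and additive within a site: a haplotype pair carrying
  dosage ``g`` at a site with coefficient ``s`` multiplies fitness by
  ``(1 + s)**g``.  ``s = gamma / (2 N0)`` where ``N0`` is the initial size.
* Mutation: each gamete receives ``Poisson(mu * L)`` new mutations, with the
  per-site rate ``mu = theta / (4 N0)``; every mutation hits a fresh position.
  A fraction ``fraction_selected`` of new mutations receives ``gamma``; the
  rest are neutral.
* Recombination: ``Poisson(r * L)`` crossovers per meiosis at uniform
  positions, with ``r = rho / (4 N0)`` per site.  ``free_recombination=True``
  replaces crossovers by independent inheritance of every site, which removes
  linkage entirely (useful when comparing against single-locus theory).
* Demography: a per-generation diploid-size schedule built from epochs
  (absolute size, instantaneous fraction, or exponential growth rate).

Runs are reproducible: the same config and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DemographyEpoch",
    "SimulationConfig",
    "AlleleTrajectory",
    "SimulationResult",
    "constant_preset",
    "expansion_preset",
    "bottleneck_preset",
    "build_size_schedule",
    "simulate_trajectories",
    "age_by_frequency",
    "per_mutation_mean_ages",
    "sample_panel",
]


@dataclass(frozen=True)
class DemographyEpoch:
    """A change in diploid population size taking effect at a generation.

    ``start_generation`` counts generations after burn-in.  Exactly one of
    ``size`` (absolute diploid size), ``fraction`` (instantaneous multiplier,
    e.g. 0.5 for a 50% bottleneck) or ``growth_rate`` (per-generation
    exponential rate, applied from this epoch until the next) must be given.
    """

    start_generation: int
    size: int | None = None
    fraction: float | None = None
    growth_rate: float | None = None

    def __post_init__(self) -> None:
        n_set = sum(v is not None for v in (self.size, self.fraction, self.growth_rate))
        if n_set != 1:
            raise ValueError("exactly one of size/fraction/growth_rate must be set")
        if self.start_generation < 0:
            raise ValueError("start_generation must be >= 0")
        if self.size is not None and self.size < 2:
            raise ValueError("population size must be >= 2")


@dataclass
class SimulationConfig:
    N: int = 1000
    burn_in: int | None = None  # default 10 N
    run_length: int | None = None  # default ceil(2.05 N), after burn-in
    theta: float = 1e-4  # 4 N mu per site
    rho: float = 1e-4  # 4 N r per site
    region_length: int = 100_000
    fraction_selected: float = 0.7
    gamma: float = -10.0
    demography: list[DemographyEpoch] = field(default_factory=list)
    seed: int | None = None
    free_recombination: bool = False
    record_trajectories: bool = True
    trajectory_thinning: int = 1  # record every k-th generation (memory guard)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.theta < 0 or self.rho < 0:
            raise ValueError("theta and rho must be >= 0")
        if not 0.0 <= self.fraction_selected <= 1.0:
            raise ValueError("fraction_selected must be in [0, 1]")
        if self.burn_in is None:
            self.burn_in = 10 * self.N
        if self.run_length is None:
            self.run_length = math.ceil(2.05 * self.N)
        if self.trajectory_thinning < 1:
            raise ValueError("trajectory_thinning must be >= 1")

    @property
    def total_generations(self) -> int:
        return self.burn_in + self.run_length


@dataclass
class AlleleTrajectory:
    """Per-generation frequency path of one mutation."""

    site: int
    origin_generation: int
    frequencies: np.ndarray  # frequency at each recorded generation, from origin
    gamma: float
    final_frequency: float
    fate: str  # "lost" | "fixed" | "segregating"

    @property
    def age_at_sampling(self) -> int | None:
        return None if self.fate != "segregating" else len(self.frequencies)


def constant_preset(N: int = 1000, **kw) -> SimulationConfig:
    return SimulationConfig(N=N, demography=[], **kw)


def expansion_preset(N: int = 1000, fold: float = 5.0, **kw) -> SimulationConfig:
    """Exponential expansion starting 2N generations after burn-in.

    The population grows by ``fold`` over the remaining 0.05 N generations of
    the run.  This parameterizes rapid recent growth by a (fold, duration)
    pair rather than any simulator-specific rate constant.
    """
    cfg = SimulationConfig(N=N, **kw)
    start = 2 * N
    duration = max(cfg.run_length - start, 1)
    rate = math.log(fold) / duration
    cfg.demography = [DemographyEpoch(start_generation=start, growth_rate=rate)]
    return cfg


def bottleneck_preset(
    N: int = 1000, reduction: float = 0.5, fold: float = 5.0, **kw
) -> SimulationConfig:
    """Instantaneous reduction at 2N generations after burn-in, then growth."""
    cfg = SimulationConfig(N=N, **kw)
    start = 2 * N
    duration = max(cfg.run_length - start, 1)
    rate = math.log(fold / reduction) / duration
    cfg.demography = [
        DemographyEpoch(start_generation=start, fraction=reduction),
        DemographyEpoch(start_generation=start, growth_rate=rate),
    ]
    return cfg


def build_size_schedule(config: SimulationConfig) -> np.ndarray:
    """Diploid size at every generation ``0..total_generations`` (inclusive)."""
    T = config.total_generations
    sizes = np.empty(T + 1, dtype=np.int64)
    sizes[: config.burn_in + 1] = config.N
    epochs = sorted(config.demography, key=lambda e: e.start_generation)
    current = float(config.N)
    rate = 0.0
    idx = 0
    for t in range(config.burn_in + 1, T + 1):
        rel = t - config.burn_in
        while idx < len(epochs) and epochs[idx].start_generation <= rel:
            ep = epochs[idx]
            if ep.size is not None:
                current = float(ep.size)
            elif ep.fraction is not None:
                current = current * ep.fraction
            else:
                rate = ep.growth_rate
            idx += 1
        current = current * math.exp(rate) if rate != 0.0 else current
        n = int(round(current))
        if n < 2:
            raise ValueError(f"population size fell below 2 at generation {t}")
        sizes[t] = n
    return sizes


@dataclass
class SimulationResult:
    """Raw output of one run.

    ``mutation_table`` has one row per mutation ever introduced (columns:
    site, origin_generation, gamma, fate, final_count).  ``occupancy`` is a
    flat record of (mutation id, generation, derived count, 2N at that
    generation) for every recorded generation, from which trajectories and
    age-by-frequency tables are built without materialising per-mutation
    objects.  ``population`` is the final phased 0/1 matrix (2N_final x S) of
    the sites still segregating at sampling time.
    """

    config: SimulationConfig
    size_schedule: np.ndarray
    mutation_table: pd.DataFrame
    occupancy: dict[str, np.ndarray] | None
    population: np.ndarray
    positions: np.ndarray
    segregating_ids: np.ndarray
    sampling_generation: int

    @property
    def trajectories(self) -> list[AlleleTrajectory]:
        """Materialise AlleleTrajectory objects from the occupancy record."""
        if self.occupancy is None:
            raise ValueError("run was executed with record_trajectories=False")
        ids = self.occupancy["id"]
        order = np.lexsort((self.occupancy["generation"], ids))
        ids_s = ids[order]
        freq = self.occupancy["count"][order] / self.occupancy["popsize"][order]
        starts = np.flatnonzero(np.r_[True, ids_s[1:] != ids_s[:-1]])
        bounds = np.r_[starts, ids_s.size]
        mt = self.mutation_table
        out = []
        for i, s in enumerate(starts):
            e = bounds[i + 1]
            mid = int(ids_s[s])
            row = mt.iloc[mid]
            f = freq[s:e]
            out.append(
                AlleleTrajectory(
                    site=int(row["site"]),
                    origin_generation=int(row["origin_generation"]),
                    frequencies=f,
                    gamma=float(row["gamma"]),
                    final_frequency=float(f[-1]),
                    fate=str(row["fate"]),
                )
            )
        return out


def _draw_positions(rng, n, region_length, occupied: set) -> np.ndarray:
    """Distinct integer positions, avoiding currently occupied ones."""
    out = []
    while len(out) < n:
        cand = rng.integers(1, region_length + 1, size=n - len(out))
        for p in cand:
            p = int(p)
            if p not in occupied:
                occupied.add(p)
                out.append(p)
    return np.array(out, dtype=np.int64)


def simulate_trajectories(config: SimulationConfig) -> SimulationResult:
    """Run the individual-based simulation.

    Every mutation introduced during burn-in and run is registered with its
    origin generation and selection coefficient; per-generation counts are
    recorded when ``config.record_trajectories`` is set (thinned by
    ``trajectory_thinning``).  The final population matrix is always kept so
    a phased panel can be sampled.
    """
    rng = np.random.default_rng(config.seed)
    sizes = build_size_schedule(config)
    T = config.total_generations
    N0 = config.N
    L = config.region_length
    mu_genome = config.theta / (4.0 * N0) * L
    cx_rate = 0.0 if config.free_recombination else config.rho / (4.0 * N0) * L

    G = np.zeros((2 * sizes[0], 0), dtype=np.int8)
    pos = np.empty(0, dtype=np.int64)
    sel = np.empty(0, dtype=np.float64)  # per-site s
    ids = np.empty(0, dtype=np.int64)
    occupied: set[int] = set()

    all_pos: list[np.ndarray] = []
    all_origin: list[np.ndarray] = []
    all_gamma: list[np.ndarray] = []
    fate_lost: list[np.ndarray] = []
    fate_fixed: list[np.ndarray] = []
    final_counts: dict[int, int] = {}
    n_mut_total = 0

    occ_id: list[np.ndarray] = []
    occ_gen: list[np.ndarray] = []
    occ_cnt: list[np.ndarray] = []
    occ_pop: list[np.ndarray] = []

    s_of_gamma = config.gamma / (2.0 * N0)

    for t in range(1, T + 1):
        n_cur = sizes[t - 1]
        n_new = sizes[t]
        H_new = 2 * n_new

        # --- parent sampling proportional to multiplicative fitness
        sel_cols = np.flatnonzero(sel != 0.0)
        if sel_cols.size:
            dosage = G[0::2, :][:, sel_cols].astype(np.float64) + G[1::2, :][:, sel_cols]
            logw = dosage @ np.log1p(sel[sel_cols])
            logw -= logw.max()
            w = np.exp(logw)
            p = w / w.sum()
            parents = rng.choice(n_cur, size=(n_new, 2), p=p)
        else:
            parents = rng.integers(0, n_cur, size=(n_new, 2))

        par_all = parents.reshape(-1)  # gamete g comes from individual par_all[g]
        start = rng.integers(0, 2, size=H_new)
        S = G.shape[1]
        child = G[2 * par_all + start]  # copy

        if S and config.free_recombination:
            mask = rng.integers(0, 2, size=(H_new, S), dtype=np.int8).astype(bool)
            other = G[2 * par_all + 1 - start]
            child = np.where(mask, other, child)
        elif S and cx_rate > 0.0:
            k = rng.poisson(cx_rate, size=H_new)
            rec = np.flatnonzero(k)
            if rec.size > H_new // 16:
                # dense regime: bucket all crossovers into sorted-site
                # intervals and take the cumulative parity per gamete
                K = int(k.sum())
                cxp = rng.uniform(0.0, L, size=K)
                gidx = np.repeat(np.arange(H_new), k)
                order = np.argsort(pos, kind="stable")
                iv = np.searchsorted(pos[order], cxp, side="left")
                bucket = np.zeros((H_new, S + 1), dtype=np.int16)
                np.add.at(bucket, (gidx, iv), 1)
                parity = np.cumsum(bucket[:, :S], axis=1) & 1
                mask = np.empty_like(parity, dtype=bool)
                mask[:, order] = parity.astype(bool)
                other = G[2 * par_all + 1 - start]
                child = np.where(mask, other, child)
            else:
                for g in rec:
                    cxp = np.sort(rng.uniform(0.0, L, size=k[g]))
                    flip = (np.searchsorted(cxp, pos) % 2).astype(bool)
                    if flip.any():
                        other_row = G[2 * par_all[g] + 1 - start[g]]
                        child[g, flip] = other_row[flip]

        # --- new mutations
        n_mut = rng.poisson(2.0 * n_new * mu_genome)
        if mu_genome > 0 and n_mut:
            new_pos = _draw_positions(rng, n_mut, L, occupied)
            gametes = rng.integers(0, H_new, size=n_mut)
            newcols = np.zeros((H_new, n_mut), dtype=np.int8)
            newcols[gametes, np.arange(n_mut)] = 1
            is_sel = rng.random(n_mut) < config.fraction_selected
            new_s = np.where(is_sel, s_of_gamma, 0.0)
            new_ids = np.arange(n_mut_total, n_mut_total + n_mut, dtype=np.int64)
            n_mut_total += n_mut
            all_pos.append(new_pos)
            all_origin.append(np.full(n_mut, t, dtype=np.int64))
            all_gamma.append(np.where(is_sel, config.gamma, 0.0))
            child = np.concatenate([child, newcols], axis=1)
            pos = np.concatenate([pos, new_pos])
            sel = np.concatenate([sel, new_s])
            ids = np.concatenate([ids, new_ids])

        # --- bookkeeping: counts, recording, pruning
        cnt = child.sum(axis=0, dtype=np.int64)
        if config.record_trajectories and (t % config.trajectory_thinning == 0 or t == T):
            occ_id.append(ids.copy())
            occ_gen.append(np.full(ids.size, t, dtype=np.int64))
            occ_cnt.append(cnt.copy())
            occ_pop.append(np.full(ids.size, H_new, dtype=np.int64))

        # prune lazily: an all-0 column stays 0 and an all-1 column stays 1
        # (no back mutation), so compaction can be deferred until dead
        # columns are a noticeable fraction of the matrix
        lost = cnt == 0
        fixed = cnt == H_new
        gone = lost | fixed
        n_gone = int(gone.sum())
        if n_gone and (t == T or n_gone > 16 + 0.05 * gone.size):
            fate_lost.append(ids[lost])
            fate_fixed.append(ids[fixed])
            for p_ in pos[gone]:
                occupied.discard(int(p_))
            keep = ~gone
            child = np.ascontiguousarray(child[:, keep])
            pos = pos[keep]
            sel = sel[keep]
            ids = ids[keep]
            cnt = cnt[keep]
        G = child

    # final fate pass for columns that escaped the lazy pruning
    H_final = 2 * sizes[T]
    still = (cnt > 0) & (cnt < H_final)
    if (~still).any():
        fate_lost.append(ids[cnt == 0])
        fate_fixed.append(ids[cnt == H_final])
        G = np.ascontiguousarray(G[:, still])
        pos, sel, ids, cnt = pos[still], sel[still], ids[still], cnt[still]
    final_counts = dict(zip(ids.tolist(), cnt.tolist())) if ids.size else {}

    mt = pd.DataFrame(
        {
            "site": np.concatenate(all_pos) if all_pos else np.empty(0, np.int64),
            "origin_generation": (
                np.concatenate(all_origin) if all_origin else np.empty(0, np.int64)
            ),
            "gamma": np.concatenate(all_gamma) if all_gamma else np.empty(0),
        }
    )
    fate = np.full(len(mt), "segregating", dtype=object)
    if fate_lost:
        fate[np.concatenate(fate_lost)] = "lost"
    if fate_fixed:
        fate[np.concatenate(fate_fixed)] = "fixed"
    mt["fate"] = fate
    fc = np.zeros(len(mt), dtype=np.int64)
    if final_counts:
        k = np.fromiter(final_counts.keys(), dtype=np.int64)
        v = np.fromiter(final_counts.values(), dtype=np.int64)
        fc[k] = v
    mt["final_count"] = fc

    occupancy = None
    if config.record_trajectories:
        occupancy = {
            "id": np.concatenate(occ_id) if occ_id else np.empty(0, np.int64),
            "generation": np.concatenate(occ_gen) if occ_gen else np.empty(0, np.int64),
            "count": np.concatenate(occ_cnt) if occ_cnt else np.empty(0, np.int64),
            "popsize": np.concatenate(occ_pop) if occ_pop else np.empty(0, np.int64),
        }

    order = np.argsort(pos, kind="stable")
    return SimulationResult(
        config=config,
        size_schedule=sizes,
        mutation_table=mt,
        occupancy=occupancy,
        population=G[:, order],
        positions=pos[order],
        segregating_ids=ids[order],
        sampling_generation=T,
    )


# ---------------------------------------------------------------------------
# age statistics


def _occupancy_frame(
    result: SimulationResult,
    window: tuple[int, int] | None = None,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flat (id, gamma, age, frequency) observations from the occupancy record.

    One row per segregating mutation per recorded generation inside the
    observation window.  When ``sample_size`` is given, the observed frequency
    is a binomial sample of that many haplotypes (sample frequency rather than
    population frequency); monomorphic-in-sample draws are dropped.
    """
    if result.occupancy is None:
        raise ValueError("run was executed with record_trajectories=False")
    occ = result.occupancy
    if window is None:
        window = (result.config.burn_in, result.sampling_generation)
    lo, hi = window
    m = (occ["generation"] >= lo) & (occ["generation"] <= hi)
    m &= (occ["count"] > 0) & (occ["count"] < occ["popsize"])
    ids = occ["id"][m]
    gen = occ["generation"][m]
    cnt = occ["count"][m]
    popsz = occ["popsize"][m]
    origin = result.mutation_table["origin_generation"].to_numpy()[ids]
    gamma = result.mutation_table["gamma"].to_numpy()[ids]
    age = gen - origin
    if sample_size is None:
        freq = cnt / popsz
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        sc = rng.binomial(sample_size, cnt / popsz)
        keep = (sc > 0) & (sc < sample_size)
        ids, age, gamma = ids[keep], age[keep], gamma[keep]
        freq = sc[keep] / sample_size
    return pd.DataFrame({"id": ids, "gamma": gamma, "age": age, "frequency": freq})


def age_by_frequency(
    result: SimulationResult | list[AlleleTrajectory],
    bins: np.ndarray | None = None,
    mode: str = "occupation",
    window: tuple[int, int] | None = None,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean allelic age per frequency bin and selection class.

    ``mode="occupation"`` averages over every (mutation, generation) pair in
    the observation window -- the stationary-ensemble estimate that matches
    the diffusion prediction of age conditional on frequency.  Standard errors
    treat mutations (not generation observations, which are autocorrelated
    along a trajectory) as the independent unit, via the cluster-ratio
    formula.  ``mode="final"`` uses only the sampling-time snapshot.

    Bins default to 1% width.  Empty bins are emitted with n = 0 and NaN mean,
    flagged in the ``defined`` column rather than dropped; single-observation
    bins have NaN (undefined) SE.
    """
    if bins is None:
        bins = np.arange(0.0, 1.0 + 1e-9, 0.01)
    bins = np.asarray(bins, dtype=float)

    if isinstance(result, list):
        if not result:
            raise ValueError("empty trajectory collection")
        rows = []
        for i, tr in enumerate(result):
            if mode == "final":
                if tr.fate != "segregating":
                    continue
                # first recorded state is the creation generation (age 0)
                rows.append((i, tr.gamma, len(tr.frequencies) - 1, tr.final_frequency))
            else:
                # first recorded state is the creation generation (age 0)
                ages = np.arange(len(tr.frequencies))
                seg = (tr.frequencies > 0) & (tr.frequencies < 1)
                for a, f in zip(ages[seg], tr.frequencies[seg]):
                    rows.append((i, tr.gamma, a, f))
        obs = pd.DataFrame(rows, columns=["id", "gamma", "age", "frequency"])
    else:
        if mode == "final":
            mt = result.mutation_table
            seg = mt["fate"] == "segregating"
            obs = pd.DataFrame(
                {
                    "id": np.flatnonzero(seg.to_numpy()),
                    "gamma": mt.loc[seg, "gamma"].to_numpy(),
                    "age": result.sampling_generation
                    - mt.loc[seg, "origin_generation"].to_numpy(),
                    "frequency": mt.loc[seg, "final_count"].to_numpy()
                    / (2 * result.size_schedule[-1]),
                }
            )
        else:
            obs = _occupancy_frame(result, window, sample_size, rng)

    obs = obs.copy()
    obs["bin"] = np.digitize(obs["frequency"], bins) - 1
    out_rows = []
    classes = sorted(obs["gamma"].unique()) if len(obs) else []
    for g in classes:
        sub = obs[obs["gamma"] == g]
        for b in range(len(bins) - 1):
            cell = sub[sub["bin"] == b]
            n_obs = len(cell)
            if n_obs == 0:
                out_rows.append((bins[b], bins[b + 1], g, 0, 0, np.nan, np.nan, False))
                continue
            per = cell.groupby("id")["age"].agg(["sum", "count"])
            tot_t = per["count"].sum()
            mean = per["sum"].sum() / tot_t
            m_cl = len(per)
            if m_cl > 1:
                resid = per["sum"] - mean * per["count"]
                se = math.sqrt((resid**2).sum() * m_cl / (m_cl - 1)) / tot_t
            else:
                se = np.nan
            out_rows.append(
                (bins[b], bins[b + 1], g, m_cl, n_obs, mean, se, True)
            )
    return pd.DataFrame(
        out_rows,
        columns=[
            "bin_low",
            "bin_high",
            "gamma",
            "n",
            "n_observations",
            "mean_age",
            "se",
            "defined",
        ],
    )


def per_mutation_mean_ages(
    result: SimulationResult,
    freq_range: tuple[float, float],
    gamma: float,
    window: tuple[int, int] | None = None,
    sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-mutation mean age while inside a frequency band.

    Returns one value per mutation of the given selection class that was ever
    observed inside ``freq_range`` -- independent observation units suitable
    for rank tests between selection classes.
    """
    obs = _occupancy_frame(result, window, sample_size, rng)
    lo, hi = freq_range
    sub = obs[(obs["gamma"] == gamma) & (obs["frequency"] >= lo) & (obs["frequency"] < hi)]
    return sub.groupby("id")["age"].mean().to_numpy()


def sample_panel(
    result: SimulationResult,
    n_haplotypes: int,
    seed: int | np.random.Generator | None = None,
    chrom: str = "1",
):
    """Sample a phased haplotype panel (without replacement) with truth ages.

    Returns ``(panel, truth)`` where truth is a DataFrame aligned with the
    panel's variants carrying origin generation, true age at sampling, gamma
    and population frequency.  The simulated ancestral allele is always the
    REF allele (mutations create the ALT allele).
    """
    from .panel import HaplotypePanel  # local import to avoid a cycle

    H = result.population.shape[0]
    if n_haplotypes > H:
        raise ValueError(f"requested {n_haplotypes} haplotypes from {H} available")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = np.sort(rng.choice(H, size=n_haplotypes, replace=False))
    sub = result.population[rows]
    cnt = sub.sum(axis=0)
    seg = (cnt > 0) & (cnt < n_haplotypes)
    sub = sub[:, seg]
    positions = result.positions[seg]
    ids = result.segregating_ids[seg]

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=positions.size)
    alt_i = (ref_i + rng.integers(1, 4, size=positions.size)) % 4

    mt = result.mutation_table
    origin = mt["origin_generation"].to_numpy()[ids]
    gamma = mt["gamma"].to_numpy()[ids]
    truth = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "origin_generation": origin,
            "age": result.sampling_generation - origin,
            "gamma": gamma,
            "population_frequency": mt["final_count"].to_numpy()[ids]
            / (2 * result.size_schedule[-1]),
            "sample_count": cnt[seg],
        }
    )
    panel = HaplotypePanel.from_matrix(
        matrix=sub,
        chrom=chrom,
        positions=positions,
        ref=bases[ref_i],
        alt=bases[alt_i],
    )
    return panel, truth
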