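"""The Neighborhood-based Clock (NC) statistic.

For an index variant on a phased panel, scan outward in each direction along
the chromosome and stop at the first candidate variant that signals an event
younger than the index allele:

* a detectable recombination between index and candidate — the four-gamete
  test observes all four two-locus haplotypes (00, 01, 10, 11); or
* a *fully linked rarer* variant — the candidate's carriers are a strict,
  non-empty subset of the index variant's carriers, evidence of a mutation
  that arose later on the index haplotype background.

NC is the base-10 logarithm of the sum of the upstream and downstream
physical distances (bp) to the stopping variants.  Younger alleles have had
less time to accumulate nearby sub-mutations and recombination events, so
they yield larger NC values.  A direction that reaches the end of the contig
without a qualifying candidate is censored and NC is undefined for that
variant (censored variants are excluded from downstream statistics and
counted in logs).

By default the focal allele whose carriers define these sets is the *minor*
allele of each variant, and candidates are all segregating non-singleton
variants regardless of functional class; singletons can be admitted with a
flag.  The four-gamete test itself is allele-labeling invariant, so it is
evaluated on the focal-carrier encoding without loss of generality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "NCResult",
    "carrier_set",
    "four_gamete",
    "fully_linked_rarer",
    "nc_statistic",
    "nc_scan",
]


@dataclass(frozen=True)
class NCResult:
    variant: int  # column index in the panel
    chrom: str
    pos: int
    mac: int
    d_up: int | None
    d_down: int | None
    reason_up: str  # "recombination" | "linked_rarer" | "censored"
    reason_down: str
    nc: float  # NaN when either direction is censored

    @property
    def censored(self) -> bool:
        return self.reason_up == "censored" or self.reason_down == "censored"


def carrier_set(panel: HaplotypePanel, variant: int, mode: str = "minor") -> frozenset:
    """Indices of haplotypes carrying the focal allele of a variant."""
    col = panel.carrier_matrix(mode=mode)[:, variant]
    if col.all() or not col.any():
        raise ValueError(f"variant {variant} is not segregating")
    return frozenset(np.flatnonzero(col).tolist())


def four_gamete(panel: HaplotypePanel, i: int, j: int) -> bool:
    """True iff all four two-locus haplotypes are present between sites i, j."""
    if i == j:
        raise ValueError("four-gamete test needs two distinct sites")
    a = panel.matrix[:, i].astype(bool)
    b = panel.matrix[:, j].astype(bool)
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = panel.n_haplotypes - n11 - n10 - n01
    return n11 > 0 and n10 > 0 and n01 > 0 and n00 > 0


def fully_linked_rarer(
    panel: HaplotypePanel, index: int, cand: int, mode: str = "minor"
) -> bool:
    """True iff the candidate's carriers form a strict subset of the index's."""
    ci = carrier_set(panel, index, mode=mode)
    cc = carrier_set(panel, cand, mode=mode)
    return cc < ci


def _scan_side(
    qualifying: np.ndarray, positions: np.ndarray, idx_pos: int, upstream: bool
) -> tuple[int | None, str, int | None]:
    """First qualifying candidate on one side; returns (distance, reason code idx, col)."""
    if upstream:
        side = np.flatnonzero(qualifying & (positions < idx_pos))
        if side.size == 0:
            return None, "censored", None
        stop = side[np.argmax(positions[side])]
    else:
        side = np.flatnonzero(qualifying & (positions > idx_pos))
        if side.size == 0:
            return None, "censored", None
        stop = side[np.argmin(positions[side])]
    return int(abs(positions[stop] - idx_pos)), "", int(stop)


def nc_statistic(
    panel: HaplotypePanel,
    index: int,
    mode: str = "minor",
    include_singletons: bool = False,
    candidate_filter: np.ndarray | None = None,
) -> NCResult:
    """NC statistic for one index variant.

    ``candidate_filter`` is an optional boolean mask over the panel's
    variants restricting candidacy (applied on top of the same-contig,
    segregating, non-singleton defaults).
    """
    if not 0 <= index < panel.n_variants:
        raise ValueError(f"index variant {index} not in panel")
    v = panel.variants
    chrom = v["chrom"].to_numpy()
    positions = v["pos"].to_numpy()
    mac = v["mac"].to_numpy()
    if mac[index] < 2:
        raise ValueError("index variant must be non-singleton (mac >= 2)")

    C = panel.carrier_matrix(mode=mode)
    c_idx = C[:, index]
    mac_focal = C.sum(axis=0, dtype=np.int64)
    n11 = c_idx.astype(np.int64) @ C
    n_idx = int(c_idx.sum())
    H = panel.n_haplotypes
    n10 = n_idx - n11
    n01 = mac_focal - n11
    n00 = H - n_idx - mac_focal + n11

    recomb = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    subset = (n11 == mac_focal) & (mac_focal > 0) & (mac_focal < n_idx)

    eligible = (chrom == chrom[index]) & (mac >= (1 if include_singletons else 2))
    eligible &= (mac_focal > 0) & (mac_focal < H)
    eligible[index] = False
    if candidate_filter is not None:
        eligible &= np.asarray(candidate_filter, dtype=bool)

    qualifying = eligible & (recomb | subset)
    d_up, r_up, s_up = _scan_side(qualifying, positions, positions[index], True)
    d_down, r_down, s_down = _scan_side(qualifying, positions, positions[index], False)
    if s_up is not None:
        r_up = "linked_rarer" if subset[s_up] else "recombination"
    if s_down is not None:
        r_down = "linked_rarer" if subset[s_down] else "recombination"
    nc = (
        math.log10(d_up + d_down)
        if d_up is not None and d_down is not None
        else float("nan")
    )
    return NCResult(
        variant=index,
        chrom=str(chrom[index]),
        pos=int(positions[index]),
        mac=int(mac[index]),
        d_up=d_up,
        d_down=d_down,
        reason_up=r_up,
        reason_down=r_down,
        nc=nc,
    )


def nc_scan(
    panel: HaplotypePanel,
    mac_range: tuple[int, int] = (2, 6),
    mode: str = "minor",
    include_singletons: bool = False,
) -> pd.DataFrame:
    """NC statistics for every variant with MAC in ``mac_range`` (inclusive).

    Returns one row per index variant with distances, stop reasons, NC, and
    the variant's polarity/category/damage score for downstream statistics.
    Censored rows carry NaN in the ``nc`` column.
    """
    v = panel.variants
    lo, hi = mac_range
    mac_all = v["mac"].to_numpy()
    chrom_all = v["chrom"].to_numpy()
    pos_all = v["pos"].to_numpy()
    H = panel.n_haplotypes
    C = panel.carrier_matrix(mode=mode)
    Cf = C.astype(np.float32)
    mac_focal = C.sum(axis=0, dtype=np.int64)

    rows = []
    for chrom in pd.unique(v["chrom"]):
        on_chrom = np.flatnonzero(chrom_all == chrom)  # position-sorted
        pos = pos_all[on_chrom]
        mf = mac_focal[on_chrom]
        macs = mac_all[on_chrom]
        Cc = Cf[:, on_chrom]
        idx_local = np.flatnonzero((macs >= lo) & (macs <= hi))
        if idx_local.size == 0:
            continue
        # two-locus gamete counts for every (index, candidate) pair
        N11 = Cc[:, idx_local].T @ Cc  # (I x Vc)
        n_idx = mf[idx_local].astype(np.float32)
        n10 = n_idx[:, None] - N11
        n01 = mf[None, :] - N11
        n00 = H - n_idx[:, None] - mf[None, :] + N11
        recomb = (N11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
        subset = (N11 == mf[None, :]) & (mf[None, :] > 0) & (mf[None, :] < n_idx[:, None])
        eligible = (macs >= (1 if include_singletons else 2)) & (mf > 0) & (mf < H)
        qualifying = (recomb | subset) & eligible[None, :]
        qualifying[np.arange(idx_local.size), idx_local] = False

        for k, j in enumerate(idx_local):
            q = qualifying[k]
            ups = np.flatnonzero(q[:j])
            dns = np.flatnonzero(q[j + 1 :])
            if ups.size:
                s_up = ups[-1]
                d_up = int(pos[j] - pos[s_up])
                r_up = "linked_rarer" if subset[k, s_up] else "recombination"
            else:
                d_up, r_up = None, "censored"
            if dns.size:
                s_dn = int(dns[0] + j + 1)
                d_down = int(pos[s_dn] - pos[j])
                r_down = "linked_rarer" if subset[k, s_dn] else "recombination"
            else:
                d_down, r_down = None, "censored"
            nc_val = (
                math.log10(d_up + d_down)
                if d_up is not None and d_down is not None
                else float("nan")
            )
            row = v.iloc[on_chrom[j]]
            rows.append(
                {
                    "chrom": str(chrom),
                    "pos": int(pos[j]),
                    "mac": int(macs[j]),
                    "polarity": row["polarity"],
                    "category": row["category"],
                    "damage_score": row["damage_score"],
                    "d_up": d_up,
                    "reason_up": r_up,
                    "d_down": d_down,
                    "reason_down": r_down,
                    "nc": nc_val,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "mac",
            "polarity",
            "category",
            "damage_score",
            "d_up",
            "reason_up",
            "d_down",
            "reason_down",
            "nc",
        ],
    )
    n_cens = int(out["nc"].isna().sum()) if len(out) else 0
    logger.info("nc_scan: %d index variants, %d censored", len(out), n_cens)
    return out
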