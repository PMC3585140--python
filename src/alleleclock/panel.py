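"""Phased haplotype panels: VCF I/O, ancestral polarization, annotations.

A :class:`HaplotypePanel` is a phased 0/1 haplotype-by-variant matrix plus a
variant table.  Only phased, biallelic SNVs with complete genotypes are
admitted; everything else is excluded with counted reasons so that input and
retained totals always reconcile.

Coordinate and allele conventions:

* positions are 1-based (VCF convention) and distances downstream are plain
  differences of these coordinates;
* the *minor* allele of a variant is the less frequent allele in the panel,
  with an exact 50/50 tie assigned to the ALT allele;
* ``polarity`` describes the minor allele relative to an ancestral-allele
  map: ``ancestral`` when the minor allele equals the ancestral allele,
  ``derived`` when it is the non-ancestral allele, and ``unpolarized`` when
  the ancestral state is unknown or matches neither allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "HaplotypePanel",
    "read_phased_vcf",
    "write_phased_vcf",
    "polarize",
    "attach_annotations",
    "read_table",
]

CATEGORIES = (
    "synonymous",
    "benign",
    "possibly_damaging",
    "probably_damaging",
    "other",
    "none",
)

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "mac",
    "minor_is_alt",
    "polarity",
    "derived_count",
    "category",
    "damage_score",
]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    mac: int
    minor_is_alt: bool
    polarity: str = "unpolarized"
    derived_count: int | None = None
    category: str = "none"
    damage_score: float | None = None

    @property
    def focal_allele(self) -> str:
        """The minor allele, the default focal allele of downstream scans."""
        return self.alt if self.minor_is_alt else self.ref


@dataclass
class HaplotypePanel:
    """Phased 0/1 matrix (haplotypes x variants) with a variant table."""

    haplotype_ids: list[str]
    matrix: np.ndarray
    variants: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x variants)")
        if self.matrix.shape != (len(self.haplotype_ids), len(self.variants)):
            raise ValueError("matrix shape inconsistent with ids/variant table")
        pos = self.variants[["chrom", "pos"]]
        for _, grp in pos.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError("positions must be strictly increasing per contig")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def alt_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0, dtype=np.int64)

    def carrier_matrix(self, mode: str = "minor") -> np.ndarray:
        """Boolean matrix of focal-allele carriers.

        ``mode="minor"`` marks carriers of each variant's minor allele;
        ``mode="derived"`` marks carriers of the derived allele where the
        polarity is known, falling back to the minor allele elsewhere.
        """
        alt = self.matrix.astype(bool)
        if mode == "minor":
            flip = ~self.variants["minor_is_alt"].to_numpy(dtype=bool)
        elif mode == "derived":
            minor_is_alt = self.variants["minor_is_alt"].to_numpy(dtype=bool)
            pol = self.variants["polarity"].to_numpy()
            # derived allele is the minor one when polarity == derived, the
            # major one when polarity == ancestral
            focal_is_alt = np.where(pol == "ancestral", ~minor_is_alt, minor_is_alt)
            flip = ~focal_is_alt
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out = alt.copy()
        out[:, flip] = ~out[:, flip]
        return out

    def record(self, i: int) -> VariantRecord:
        row = self.variants.iloc[i]
        ds = row["damage_score"]
        return VariantRecord(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            mac=int(row["mac"]),
            minor_is_alt=bool(row["minor_is_alt"]),
            polarity=str(row["polarity"]),
            derived_count=None if pd.isna(row["derived_count"]) else int(row["derived_count"]),
            category=str(row["category"]),
            damage_score=None if pd.isna(ds) else float(ds),
        )

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        chrom: str | np.ndarray,
        positions: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        haplotype_ids: list[str] | None = None,
    ) -> "HaplotypePanel":
        matrix = np.ascontiguousarray(matrix, dtype=np.int8)
        H, V = matrix.shape
        if haplotype_ids is None:
            haplotype_ids = [f"S{i // 2}|{i % 2}" for i in range(H)]
        counts = matrix.sum(axis=0, dtype=np.int64)
        mac = np.minimum(counts, H - counts)
        minor_is_alt = counts <= H - counts  # tie-break: alt is "minor"
        variants = pd.DataFrame(
            {
                "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), (V,)).copy(),
                "pos": np.asarray(positions, dtype=np.int64),
                "ref": np.asarray(ref, dtype=object),
                "alt": np.asarray(alt, dtype=object),
                "mac": mac,
                "minor_is_alt": minor_is_alt,
                "polarity": "unpolarized",
                "derived_count": pd.array([pd.NA] * V, dtype="Int64"),
                "category": "none",
                "damage_score": np.full(V, np.nan),
            }
        )
        return cls(haplotype_ids=list(haplotype_ids), matrix=matrix, variants=variants)

    def subset_variants(self, mask: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            haplotype_ids=list(self.haplotype_ids),
            matrix=self.matrix[:, mask],
            variants=self.variants.loc[mask].reset_index(drop=True),
            meta=dict(self.meta),
        )

    @classmethod
    def concatenate(cls, panels: list["HaplotypePanel"]) -> "HaplotypePanel":
        """Column-wise concatenation of panels over the same haplotypes."""
        H = panels[0].n_haplotypes
        if any(p.n_haplotypes != H for p in panels):
            raise ValueError("panels must have the same number of haplotypes")
        return cls(
            haplotype_ids=list(panels[0].haplotype_ids),
            matrix=np.concatenate([p.matrix for p in panels], axis=1),
            variants=pd.concat([p.variants for p in panels], ignore_index=True),
        )


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a panel.

    Unphased genotypes, missing genotypes, multiallelic records and non-SNVs
    are excluded; the exclusion counters are stored in ``panel.meta`` and
    logged.  The matrix has ``2 * n_samples`` rows (sample haplotypes in file
    order, first|second).
    """
    path = str(path)
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    hap_ids = [f"{s}|{h}" for s in samples for h in (0, 1)]

    cols = []
    chroms, poss, refs, alts = [], [], [], []
    excl = {"multiallelic": 0, "non_snv": 0, "unphased": 0, "missing_gt": 0}
    n_input = 0
    for rec in vf:
        n_input += 1
        if rec.alts is None or len(rec.alts) != 1:
            excl["multiallelic"] += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            excl["non_snv"] += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        reason = None
        for i, s in enumerate(samples):
            sd = rec.samples[s]
            gt = sd["GT"]
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                ok, reason = False, "missing_gt"
                break
            if not sd.phased:
                ok, reason = False, "unphased"
                break
            col[2 * i] = gt[0]
            col[2 * i + 1] = gt[1]
        if not ok:
            excl[reason] += 1
            continue
        cols.append(col)
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(ref)
        alts.append(alt)
    vf.close()

    matrix = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((2 * len(samples), 0), dtype=np.int8)
    )
    panel = HaplotypePanel.from_matrix(
        matrix=matrix,
        chrom=np.array(chroms, dtype=object),
        positions=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotype_ids=hap_ids,
    )
    panel.meta["exclusions"] = excl
    panel.meta["n_input_variants"] = n_input
    logger.info(
        "read %s: %d input variants, %d retained, exclusions %s",
        path,
        n_input,
        panel.n_variants,
        excl,
    )
    return panel


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a phased VCF (plain text, 4.2)."""
    H = panel.n_haplotypes
    if H % 2 != 0:
        raise ValueError("panel must contain an even number of haplotypes")
    samples = []
    for i in range(0, H, 2):
        hid = panel.haplotype_ids[i]
        samples.append(hid.split("|")[0] if "|" in hid else f"S{i // 2}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=alleleclock\n")
        for c in pd.unique(panel.variants["chrom"]):
            maxpos = int(panel.variants.loc[panel.variants["chrom"] == c, "pos"].max())
            fh.write(f"##contig=<ID={c},length={maxpos + 1}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        mat = panel.matrix
        for j in range(panel.n_variants):
            row = panel.variants.iloc[j]
            gts = "\t".join(
                f"{mat[2 * i, j]}|{mat[2 * i + 1, j]}" for i in range(len(samples))
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with a header line."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def polarize(panel: HaplotypePanel, ancestral_map: pd.DataFrame | str | Path) -> HaplotypePanel:
    """Set polarity and derived counts from an ancestral-allele map.

    The map is a table with columns chrom, pos, ancestral_allele.  Sites
    absent from the map, with an unknown base (e.g. N), or whose ancestral
    allele matches neither REF nor ALT stay unpolarized.  Modifies the panel
    in place and returns it.
    """
    if not isinstance(ancestral_map, pd.DataFrame):
        ancestral_map = read_table(ancestral_map)
    amap = ancestral_map.set_index(["chrom", "pos"])["ancestral_allele"]
    v = panel.variants
    H = panel.n_haplotypes
    alt_counts = panel.alt_counts()

    pol = np.full(len(v), "unpolarized", dtype=object)
    der = np.full(len(v), -1, dtype=np.int64)
    keys = list(zip(v["chrom"].astype(str), v["pos"]))
    for i, key in enumerate(keys):
        try:
            anc = str(amap.loc[key]).upper()
        except KeyError:
            continue
        ref, alt = str(v.iloc[i]["ref"]), str(v.iloc[i]["alt"])
        if anc == ref:
            der[i] = alt_counts[i]
        elif anc == alt:
            der[i] = H - alt_counts[i]
        else:
            continue
        minor_allele = alt if bool(v.iloc[i]["minor_is_alt"]) else ref
        pol[i] = "ancestral" if minor_allele == anc else "derived"
    v["polarity"] = pol
    v["derived_count"] = pd.array(
        [d if d >= 0 else pd.NA for d in der], dtype="Int64"
    )
    n_pol = int((pol != "unpolarized").sum())
    logger.info("polarized %d/%d variants", n_pol, len(v))
    return panel


def attach_annotations(
    panel: HaplotypePanel, table: pd.DataFrame | str | Path
) -> HaplotypePanel:
    """Attach functional categories and damage scores, keyed by (chrom, pos, alt).

    Duplicate keys in the table are an error.  Rows with a damage score
    outside [0, 1] are rejected with a warning.  Variants absent from the
    table keep category 'none'.  Modifies the panel in place and returns it.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_table(table)
    table = table.copy()
    key_cols = ["chrom", "pos", "alt"]
    dup = table.duplicated(subset=key_cols, keep=False)
    if dup.any():
        dups = table.loc[dup, key_cols].drop_duplicates().to_records(index=False)
        raise ValueError(f"duplicate annotation keys: {list(dups)[:10]}")
    if "damage_score" in table.columns:
        bad = table["damage_score"].notna() & (
            (table["damage_score"] < 0) | (table["damage_score"] > 1)
        )
        if bad.any():
            logger.warning(
                "rejecting %d annotation rows with damage_score outside [0, 1]",
                int(bad.sum()),
            )
            table = table.loc[~bad]
    table["chrom"] = table["chrom"].astype(str)

    v = panel.variants
    merged = v[key_cols].assign(chrom=v["chrom"].astype(str)).merge(
        table, on=key_cols, how="left", validate="m:1"
    )
    cat = merged["category"].fillna("none").to_numpy(dtype=object)
    unknown = ~np.isin(cat, CATEGORIES)
    if unknown.any():
        cat[unknown] = "other"
    v["category"] = cat
    if "damage_score" in merged.columns:
        v["damage_score"] = merged["damage_score"].to_numpy(dtype=float)
    n_matched = int((cat != "none").sum())
    logger.info("annotations matched %d/%d variants", n_matched, len(v))
    return panel
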