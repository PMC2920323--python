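"""Per-accession heterozygosity and pairwise genetic distances.

Accessions are single plants genotyped at co-dominant marker loci (two
allele calls per locus, e.g. SSRs). Heterozygosity is the fraction of
scored loci with two different alleles. The genetic distance between two
accessions is the negative log of the mean proportion of shared alleles
over the loci scored in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeTable:
    """Genotypes of n accessions at L co-dominant loci.

    ``alleles`` is an object array of shape (n, L, 2); missing calls are
    ``None``. Allele labels are opaque tokens compared by equality.
    """

    ids: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    alleles: np.ndarray
    loci: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=object)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_accessions, n_loci, 2)")
        if self.loci is None:
            self.loci = np.array([f"loc{k + 1}" for k in range(self.n_loci)], dtype=object)
        if len(self.ids) != self.n_accessions or len(self.lons) != self.n_accessions:
            raise ValueError("ids/coordinates do not match genotype rows")

    @property
    def n_accessions(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def scored_mask(self) -> np.ndarray:
        """(n, L) boolean: locus scored (both allele calls present)."""
        a = self.alleles
        present = np.vectorize(lambda v: v is not None and v == v, otypes=[bool])
        return present(a[:, :, 0]) & present(a[:, :, 1])


def heterozygosity(table: GenotypeTable) -> np.ndarray:
    """Fraction of scored loci at which the two allele calls differ, per accession."""
    scored = table.scored_mask()
    n_scored = scored.sum(axis=1)
    if np.any(n_scored == 0):
        bad = table.ids[n_scored == 0]
        raise ValueError(f"accessions with no scored loci: {list(bad)}")
    het = np.not_equal(table.alleles[:, :, 0], table.alleles[:, :, 1]) & scored
    return het.sum(axis=1) / n_scored


def _shared_proportion_locus(a: tuple, b: tuple) -> float:
    """Shared allele copies between two genotypes at one locus, / 2 (in {0, .5, 1})."""
    a1, a2 = a
    b1, b2 = b
    shared = 0
    remaining = [b1, b2]
    for allele in (a1, a2):
        if allele in remaining:
            remaining.remove(allele)
            shared += 1
    return shared / 2.0


def shared_allele_distance(table: GenotypeTable, i: int, j: int) -> float:
    """-ln of the mean proportion of shared alleles over co-scored loci.

    Zero shared proportion is floored at 1/(4 L) (L = co-scored loci) to keep
    the distance finite; with ~99 loci the floor is practically unreachable.
    """
    scored = table.scored_mask()
    both = scored[i] & scored[j]
    if not both.any():
        raise ValueError(f"no co-scored loci for accessions {i} and {j}")
    loci = np.flatnonzero(both)
    ps = np.mean(
        [
            _shared_proportion_locus(tuple(table.alleles[i, k]), tuple(table.alleles[j, k]))
            for k in loci
        ]
    )
    if ps == 0.0:
        ps = 1.0 / (4.0 * loci.size)
    return float(-np.log(ps))


def distance_matrix(table: GenotypeTable) -> np.ndarray:
    """Symmetric matrix of shared-allele genetic distances, zero diagonal.

    Pairs with no co-scored loci become NaN with a warning.  Allele labels
    are integer-encoded per locus so all pairs are computed vectorized; the
    multiset intersection of two diploid genotypes reduces to
    max(direct matches, crossed matches).
    """
    n, L = table.n_accessions, table.n_loci
    if n < 2:
        raise ValueError("need at least 2 accessions")
    scored = table.scored_mask()
    # integer codes per locus; -1..-2n for missing so they never match
    a1 = np.empty((n, L), dtype=np.int64)
    a2 = np.empty((n, L), dtype=np.int64)
    for k in range(L):
        labels = {}
        for r in range(n):
            for s, arr in ((0, a1), (1, a2)):
                v = table.alleles[r, k, s]
                if not scored[r, k]:
                    arr[r, k] = -(1 + 2 * r + s)
                else:
                    arr[r, k] = labels.setdefault(v, len(labels))
    out = np.zeros((n, n))
    for i in range(n):
        direct = (a1[i] == a1[i:]).astype(np.int8) + (a2[i] == a2[i:]).astype(np.int8)
        crossed = (a1[i] == a2[i:]).astype(np.int8) + (a2[i] == a1[i:]).astype(np.int8)
        shared = np.maximum(direct, crossed) / 2.0
        both = scored[i] & scored[i:]
        n_both = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ps = np.where(n_both > 0, (shared * both).sum(axis=1) / np.maximum(n_both, 1), np.nan)
        ps = np.where((ps == 0) & (n_both > 0), 1.0 / (4.0 * np.maximum(n_both, 1)), ps)
        with np.errstate(invalid="ignore"):
            out[i, i:] = -np.log(ps)
        out[i:, i] = out[i, i:]
        out[i, i] = 0.0
    if np.isnan(out).any():
        warnings.warn("some accession pairs share no co-scored loci; distances set to NaN")
    return out


# -- I/O ----------------------------------------------------------------

def genotype_table_from_wide(df: pd.DataFrame) -> GenotypeTable:
    """Build a GenotypeTable from a wide frame: id, lon, lat, then two columns
    per locus (``<locus>_a``, ``<locus>_b``); empty/NaN cells are missing."""
    meta = {"id", "lon", "lat"}
    locus_cols = [c for c in df.columns if c not in meta]
    loci = []
    for c in locus_cols:
        if c.endswith("_a"):
            base = c[:-2]
            if f"{base}_b" not in df.columns:
                raise ValueError(f"locus column {c!r} has no matching {base}_b")
            loci.append(base)
    if not loci:
        raise ValueError("no locus columns found (expect <locus>_a/<locus>_b pairs)")

    def clean(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return str(v)

    n, L = len(df), len(loci)
    alleles = np.empty((n, L, 2), dtype=object)
    for k, locus in enumerate(loci):
        alleles[:, k, 0] = [clean(v) for v in df[f"{locus}_a"]]
        alleles[:, k, 1] = [clean(v) for v in df[f"{locus}_b"]]
    return GenotypeTable(
        ids=df["id"].to_numpy(),
        lons=df["lon"].to_numpy(float),
        lats=df["lat"].to_numpy(float),
        alleles=alleles,
        loci=np.asarray(loci, dtype=object),
    )


def genotype_table_to_wide(table: GenotypeTable) -> pd.DataFrame:
    cols = {"id": table.ids, "lon": table.lons, "lat": table.lats}
    for k, locus in enumerate(table.loci):
        cols[f"{locus}_a"] = ["" if v is None else v for v in table.alleles[:, k, 0]]
        cols[f"{locus}_b"] = ["" if v is None else v for v in table.alleles[:, k, 1]]
    return pd.DataFrame(cols)


def genotype_table_from_long(df: pd.DataFrame) -> GenotypeTable:
    """Build a GenotypeTable from a long frame: id, lon, lat, locus, allele1, allele2."""
    required = {"id", "locus", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"long genotype table needs columns {sorted(required)}")
    wide = df.pivot_table(
        index="id", columns="locus", values=["allele1", "allele2"], aggfunc="first"
    )
    ids = wide.index.to_numpy()
    loci = wide["allele1"].columns.to_numpy()
    meta = df.drop_duplicates("id").set_index("id").loc[ids]
    n, L = len(ids), len(loci)
    alleles = np.empty((n, L, 2), dtype=object)
    a1 = wide["allele1"].to_numpy(dtype=object)
    a2 = wide["allele2"].to_numpy(dtype=object)

    def clean(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return str(v)

    for k in range(L):
        alleles[:, k, 0] = [clean(v) for v in a1[:, k]]
        alleles[:, k, 1] = [clean(v) for v in a2[:, k]]
    return GenotypeTable(
        ids=ids,
        lons=meta["lon"].to_numpy(float),
        lats=meta["lat"].to_numpy(float),
        alleles=alleles,
        loci=np.asarray(loci, dtype=object),
    )
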