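"""Data model and TSV input/output for GWAS summary statistics and LD information.

The interchange format is a headered, tab-delimited table with one row per
variant and canonical column names ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N``.
A ``column_map`` lets callers read files with other header conventions
(e.g. GWAS-Catalog-style ``variant_id``/``effect_allele`` headers) without
rewriting them.

Linkage disequilibrium is supplied as data — either a dense r² matrix or a
sparse ``(id_a, id_b, r2)`` triplet list — rather than computed from genotypes;
the pipeline only ever needs an r² lookup for its candidate variants.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistic interchange format
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

VALID_ALLELES = frozenset("ACGT")

#: complementary-strand partner of each nucleotide
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryInputError(ValueError):
    """Raised for malformed summary-statistic or LD input."""


@dataclasses.dataclass(frozen=True)
class VariantAssociation:
    """One variant's association summary statistics for one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` — log-odds
    units for binary traits, SD units for continuous traits.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        object.__setattr__(self, "chrom", str(self.chrom))
        problem = _row_problem(
            self.effect_allele,
            self.other_allele,
            self.pos,
            self.eaf,
            self.beta,
            self.se,
            self.pval,
            self.n,
        )
        if problem is not None:
            raise SummaryInputError(f"invalid variant {self.snp_id!r}: {problem}")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)`` ∈ (0, 0.5]."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G allele pairs (strand-ambiguous by label)."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


def _row_problem(ea, oa, pos, eaf, beta, se, pval, n) -> str | None:
    """Return a reason string if the field values violate an invariant."""
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        return "allele not a single nucleotide in {A,C,G,T}"
    if ea == oa:
        return "effect and other allele identical"
    for name, value in (("pos", pos), ("eaf", eaf), ("beta", beta), ("se", se),
                        ("pval", pval), ("n", n)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return f"missing or unparseable {name}"
    if pos < 1:
        return "position must be >= 1"
    if not 0.0 < eaf < 1.0:
        return "eaf outside (0, 1)"
    if se <= 0.0:
        return "se must be > 0"
    if not 0.0 < pval <= 1.0:
        return "pval outside (0, 1]"
    if n < 2:
        return "n must be >= 2"
    return None


@dataclasses.dataclass
class SummaryDataset:
    """A trait's GWAS summary statistics, one validated row per variant.

    The primary store is a :class:`pandas.DataFrame` with the canonical
    columns; ``variants`` offers dict-like access as
    :class:`VariantAssociation` objects.
    """

    trait_name: str
    trait_type: str  # "continuous" or "binary"
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SummaryInputError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise SummaryInputError(f"summary table missing columns: {missing}")
        if self.table["SNP"].duplicated().any():
            dupes = self.table.loc[self.table["SNP"].duplicated(), "SNP"].tolist()
            raise SummaryInputError(f"duplicate snp_id in dataset: {dupes[:5]}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_variants(
        cls, trait_name: str, trait_type: str, variants: Iterable[VariantAssociation]
    ) -> "SummaryDataset":
        rows = [
            (v.snp_id, v.chrom, v.pos, v.effect_allele, v.other_allele,
             v.eaf, v.beta, v.se, v.pval, v.n)
            for v in variants
        ]
        table = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        if not rows:
            table = _empty_table()
        return cls(trait_name, trait_type, table)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in set(self.table["SNP"])

    def get(self, snp_id: str) -> VariantAssociation:
        rows = self.table[self.table["SNP"] == snp_id]
        if rows.empty:
            raise KeyError(snp_id)
        return _variant_from_row(rows.iloc[0])

    @property
    def variants(self) -> dict[str, VariantAssociation]:
        return {row.SNP: _variant_from_row(row) for row in self.table.itertuples()}

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        keep = self.table[self.table["SNP"].isin(set(snp_ids))]
        return SummaryDataset(self.trait_name, self.trait_type, keep.copy())


def _variant_from_row(row) -> VariantAssociation:
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    return VariantAssociation(
        snp_id=get("SNP"), chrom=str(get("CHR")), pos=int(get("POS")),
        effect_allele=get("EA"), other_allele=get("OA"), eaf=float(get("EAF")),
        beta=float(get("BETA")), se=float(get("SE")), pval=float(get("P")),
        n=int(get("N")),
    )


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": pd.Series(dtype=str), "CHR": pd.Series(dtype=str),
            "POS": pd.Series(dtype=np.int64), "EA": pd.Series(dtype=str),
            "OA": pd.Series(dtype=str), "EAF": pd.Series(dtype=float),
            "BETA": pd.Series(dtype=float), "SE": pd.Series(dtype=float),
            "P": pd.Series(dtype=float), "N": pd.Series(dtype=np.int64),
        }
    )


def read_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SummaryDataset:
    """Read a tab-delimited summary-statistic file into a validated dataset.

    Parameters
    ----------
    path:
        TSV file with a header row.
    column_map:
        Optional mapping from canonical names (``SNP``, ``BETA``, ...) to the
        file's header names, for non-canonical inputs.
    trait_name:
        Defaults to the file stem.
    trait_type:
        ``"continuous"`` (effects in SD units) or ``"binary"`` (log-odds).

    Rows violating a field invariant (se ≤ 0, EAF outside (0,1), non-SNP
    alleles, unparseable numbers, ...) are dropped and the reason logged.
    Duplicate ``SNP`` ids keep the row with the smallest p-value.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    colmap = {k: k for k in CANONICAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [canon for canon, src in colmap.items() if src not in raw.columns]
    if missing:
        raise SummaryInputError(
            f"{path}: required column(s) not resolvable: {missing} "
            f"(file has {list(raw.columns)})"
        )
    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})

    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    def _to_float(s):
        try:
            return float(s)  # exact shortest-repr round trip, unlike the fast parser
        except (TypeError, ValueError):
            return float("nan")

    for col in ("POS", "EAF", "BETA", "SE", "P", "N"):
        df[col] = df[col].map(_to_float)
    df["SNP"] = df["SNP"].astype(str).str.strip()
    df["CHR"] = df["CHR"].astype(str).str.strip()

    n_in = len(df)
    reasons = df.apply(
        lambda r: _row_problem(r.EA, r.OA, r.POS, r.EAF, r.BETA, r.SE, r.P, r.N), axis=1
    ) if n_in else pd.Series(dtype=object)
    bad = reasons.notna() if n_in else pd.Series(dtype=bool)
    for snp, reason in zip(df.loc[bad, "SNP"], reasons[bad]):
        logger.warning("%s: dropping row %s (%s)", path.name, snp, reason)
    df = df[~bad] if n_in else df

    # duplicate ids: keep the most significant association
    if df["SNP"].duplicated().any():
        before = len(df)
        df = df.sort_values(["P", "SNP"], kind="mergesort").drop_duplicates("SNP", keep="first")
        df = df.sort_index()
        logger.warning("%s: dropped %d duplicate snp_id rows (kept smaller p)", path.name, before - len(df))

    df = df.astype({"POS": np.int64, "N": np.int64}) if len(df) else _empty_table()
    logger.info("%s: read %d rows, retained %d", path.name, n_in, len(df))
    return SummaryDataset(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        table=df.reset_index(drop=True),
    )


def write_summary(dataset: SummaryDataset, path: str | Path) -> Path:
    """Write a dataset to canonical TSV. Floats use shortest round-trip repr,
    so ``read_summary(write_summary(d))`` reproduces every field exactly
    (including p-values down to the subnormal range)."""
    path = Path(path)
    dataset.table.to_csv(path, sep="\t", index=False, columns=CANONICAL_COLUMNS)
    return path


@dataclasses.dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) lookup for a set of variants."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise SummaryInputError(f"LD matrix shape {self.r2.shape} != ({k},{k})")
        if np.any((self.r2 < 0) | (self.r2 > 1)):
            raise SummaryInputError("LD r2 entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise SummaryInputError("LD matrix diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T):
            raise SummaryInputError("LD matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    def r2_between(self, a: str, b: str) -> float:
        """r² between two variants; pairs not covered default to 0."""
        if a == b:
            return 1.0
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


def read_ld(path: str | Path, snp_ids: Sequence[str]) -> LDMatrix:
    """Read LD for ``snp_ids`` from a dense matrix TSV or a sparse triplet TSV.

    Dense: header row of snp ids (optionally preceded by an id column), one
    row per variant. Sparse: three columns ``id_a  id_b  r2``; pairs absent
    from the file default to r² = 0. Triplets naming unknown variants are
    logged and ignored.
    """
    path = Path(path)
    snp_ids = list(snp_ids)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    known = set(snp_ids)
    dense_like = sum(h in known for h in header) >= max(1, len(header) - 1) and len(header) > 1
    if len(header) == 3 and not dense_like:
        return _read_ld_triplets(path, snp_ids)
    return _read_ld_dense(path, snp_ids)


def _read_ld_dense(path: Path, snp_ids: list[str]) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(df.index):
        # no id column: header carries the ids, rows are positional
        df = pd.read_csv(path, sep="\t")
        df.index = df.columns
    missing = [s for s in snp_ids if s not in df.columns]
    if missing:
        raise SummaryInputError(f"{path}: dense LD matrix lacks snp ids {missing[:5]}")
    mat = df.loc[snp_ids, snp_ids].to_numpy(dtype=float)
    return LDMatrix(snp_ids, mat)


def _read_ld_triplets(path: Path, snp_ids: list[str]) -> LDMatrix:
    index = {s: i for i, s in enumerate(snp_ids)}
    mat = np.eye(len(snp_ids))
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = ["id_a", "id_b", "r2"]
    for row in df.itertuples(index=False):
        r2 = float(row.r2)
        if not 0.0 <= r2 <= 1.0:
            raise SummaryInputError(f"{path}: r2 {r2} outside [0, 1] for ({row.id_a}, {row.id_b})")
        ia = index.get(str(row.id_a))
        ib = index.get(str(row.id_b))
        if ia is None or ib is None:
            logger.warning("%s: triplet names unknown snp id (%s, %s); ignored", path.name, row.id_a, row.id_b)
            continue
        mat[ia, ib] = r2
        mat[ib, ia] = r2
    return LDMatrix(snp_ids, mat)


def write_ld(ld: LDMatrix, path: str | Path, fmt: str = "dense") -> Path:
    """Write an LD matrix as dense TSV (default) or sparse triplets."""
    path = Path(path)
    if fmt == "dense":
        df = pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids)
        df.to_csv(path, sep="\t")
    elif fmt == "sparse":
        rows = []
        for i, a in enumerate(ld.snp_ids):
            for j in range(i + 1, len(ld.snp_ids)):
                if ld.r2[i, j] != 0.0:
                    rows.append((a, ld.snp_ids[j], ld.r2[i, j]))
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown LD format {fmt!r}")
    return path
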