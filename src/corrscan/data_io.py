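"""Reading and validating genotypes, SNP maps and phenotype tables; scan-table output.

Genotypes are allele counts in {0, 1, 2} (count of the second allele), read either
from PLINK ``--recode A`` RAW text or from a plain TSV. The SNP map carries genome
order: chromosome labels are opaque strings (``X`` is an ordinary chromosome) and
each chromosome must form one contiguous, position-sorted block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PLINK_RAW_META_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class MalformedGenotypeError(ValueError):
    """A genotype value outside {0, 1, 2, missing}."""


class DuplicateIdError(ValueError):
    """Duplicate individual or SNP identifiers."""


class SortOrderError(ValueError):
    """SNP map not sorted within a chromosome, or a chromosome split into blocks."""


class InsufficientDataError(ValueError):
    """Fewer than two usable phenotype records."""


class AlignmentError(ValueError):
    """Two objects that must share a SNP map do not."""


@dataclass(frozen=True)
class SnpMap:
    """Genome-ordered SNP map: chromosome label, 1-based position, SNP id."""

    chromosome: np.ndarray
    position: np.ndarray
    snp_id: np.ndarray

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        ids = np.asarray(self.snp_id, dtype=object)
        if not (len(chrom) == len(pos) == len(ids)):
            raise ValueError("chromosome, position and snp_id must have equal length")
        if len(np.unique(ids)) != len(ids):
            raise DuplicateIdError("duplicate SNP ids in map")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "snp_id", ids)
        # each chromosome must be one contiguous run with non-decreasing positions
        seen: set = set()
        for label, start, stop in self._iter_blocks():
            if label in seen:
                raise SortOrderError(f"chromosome {label!r} appears in non-contiguous blocks")
            seen.add(label)
            block = pos[start:stop]
            if np.any(np.diff(block) < 0):
                bad = start + int(np.argmax(np.diff(block) < 0)) + 1
                raise SortOrderError(
                    f"positions not sorted within chromosome {label!r} "
                    f"(SNP {ids[bad]!r} at row {bad})"
                )

    def _iter_blocks(self):
        if len(self.chromosome) == 0:
            return
        changes = np.nonzero(self.chromosome[1:] != self.chromosome[:-1])[0] + 1
        bounds = np.concatenate(([0], changes, [len(self.chromosome)]))
        for i in range(len(bounds) - 1):
            yield self.chromosome[bounds[i]], int(bounds[i]), int(bounds[i + 1])

    @property
    def blocks(self) -> list[tuple[str, int, int]]:
        """Per-chromosome ``(label, start, stop)`` half-open global index ranges."""
        return list(self._iter_blocks())

    def __len__(self) -> int:
        return len(self.snp_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnpMap):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chromosome == other.chromosome))
            and bool(np.all(self.position == other.position))
            and bool(np.all(self.snp_id == other.snp_id))
        )

    def first_mismatch(self, other: "SnpMap") -> int | None:
        """Index of the first discordant SNP between two maps, or None."""
        n = min(len(self), len(other))
        for i in range(n):
            if (
                self.snp_id[i] != other.snp_id[i]
                or self.chromosome[i] != other.chromosome[i]
                or self.position[i] != other.position[i]
            ):
                return i
        return None if len(self) == len(other) else n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": self.chromosome, "position": self.position, "id": self.snp_id}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpMap":
        return cls(
            chromosome=df["chromosome"].astype(str).to_numpy(dtype=object),
            position=df["position"].to_numpy(dtype=np.int64),
            snp_id=df["id"].astype(str).to_numpy(dtype=object),
        )


def _placeholder_map(n_snps: int, snp_ids: Sequence[str]) -> SnpMap:
    log.debug("no SNP map supplied; synthesizing single-chromosome placeholder map")
    return SnpMap(
        chromosome=np.array(["0"] * n_snps, dtype=object),
        position=np.arange(1, n_snps + 1, dtype=np.int64),
        snp_id=np.asarray(snp_ids, dtype=object),
    )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele counts with an aligned SNP map.

    ``values`` is float64 with NaN marking missing genotypes; every non-missing
    entry is 0, 1 or 2. Column order always equals map order (asserted here).
    """

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    values: np.ndarray
    map: SnpMap
    counted_alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.individual_ids):
            raise ValueError("row count does not match number of individual ids")
        if m != len(self.snp_ids):
            raise ValueError("column count does not match number of SNP ids")
        if len(np.unique(self.individual_ids)) != n:
            raise DuplicateIdError("duplicate individual ids")
        if len(np.unique(self.snp_ids)) != m:
            raise DuplicateIdError("duplicate SNP ids")
        bad = ~(np.isnan(self.values) | np.isin(self.values, (0.0, 1.0, 2.0)))
        if np.any(bad):
            r, c = np.argwhere(bad)[0]
            raise MalformedGenotypeError(
                f"genotype value {self.values[r, c]!r} at individual "
                f"{self.individual_ids[r]!r} (row {r}), SNP {self.snp_ids[c]!r} "
                f"(column {c}) is not in {{0, 1, 2, missing}}"
            )
        if len(self.map) != m or np.any(self.map.snp_id != self.snp_ids):
            raise AlignmentError("SNP column order does not match the SNP map")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, column_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP columns (genome order kept)."""
        idx = np.asarray(column_index)
        sub_map = SnpMap(
            chromosome=self.map.chromosome[idx],
            position=self.map.position[idx],
            snp_id=self.map.snp_id[idx],
        )
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            snp_ids=self.snp_ids[idx],
            values=self.values[:, idx],
            map=sub_map,
            counted_alleles=None if self.counted_alleles is None else self.counted_alleles[idx],
        )


def read_genotypes(
    path: str | Path, dialect: str = "tsv", snp_map: SnpMap | None = None
) -> GenotypeMatrix:
    """Read a genotype matrix from PLINK RAW (``dialect='plink_raw'``) or TSV.

    The TSV dialect has a header row (first column = individual id, remaining
    columns = SNP ids) and ``NA`` for missing. PLINK RAW has the six metadata
    columns FID IID PAT MAT SEX PHENOTYPE followed by one ``<snp>_<allele>``
    column per SNP; the counted-allele suffix is stripped and recorded.
    """
    path = Path(path)
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        missing_meta = [c for c in PLINK_RAW_META_COLUMNS if c not in df.columns[:6]]
        if missing_meta:
            raise ValueError(f"PLINK RAW header lacks metadata columns {missing_meta}")
        snp_cols = list(df.columns[6:])
        snp_ids, alleles = [], []
        for col in snp_cols:
            base, _, allele = col.rpartition("_")
            if base:
                snp_ids.append(base)
                alleles.append(allele)
            else:
                snp_ids.append(col)
                alleles.append("")
        individual_ids = df["IID"].astype(str).to_numpy(dtype=object)
        values = df[snp_cols].to_numpy(dtype=np.float64)
        counted = np.asarray(alleles, dtype=object)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        snp_ids = list(df.columns[1:])
        individual_ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
        values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
        counted = None
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if snp_map is None:
        snp_map = _placeholder_map(len(snp_ids), snp_ids)
    geno = GenotypeMatrix(
        individual_ids=individual_ids,
        snp_ids=np.asarray(snp_ids, dtype=object),
        values=values,
        map=snp_map,
        counted_alleles=counted,
    )
    log.info("read %d individuals x %d SNPs from %s", geno.n_individuals, geno.n_snps, path)
    return geno


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect (header row; NA for missing); exact round-trip."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(str(s) for s in geno.snp_ids) + "\n")
        for i, iid in enumerate(geno.individual_ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.values[i]
            ]
            fh.write(str(iid) + "\t" + "\t".join(row) + "\n")


def read_snp_map(path: str | Path) -> SnpMap:
    """Read a SNP map from a headered TSV (chromosome, position, id) or a
    header-less PLINK BIM-like file (chrom, id, cm[ignored], pos, ...)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header_tokens = [t.strip().lower() for t in first.rstrip("\n").split("\t")]
    if "chromosome" in header_tokens and "position" in header_tokens and "id" in header_tokens:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "id": str})
        return SnpMap.from_frame(df)
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str, 1: str})
    if bim.shape[1] < 4:
        raise ValueError("BIM-like map needs at least 4 columns (chrom, id, cm, pos)")
    return SnpMap(
        chromosome=bim[0].to_numpy(dtype=object),
        position=bim[3].to_numpy(dtype=np.int64),
        snp_id=bim[1].to_numpy(dtype=object),
    )


def write_snp_map(snp_map: SnpMap, path: str | Path) -> None:
    snp_map.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PhenotypeTable:
    """One record per individual: trait value plus an encoded fixed-effect design.

    The design matrix includes an intercept; categorical factors are coded as
    full-rank indicator contrasts with the first observed level as reference.
    """

    ids: np.ndarray
    y: np.ndarray
    design: np.ndarray
    design_names: list[str]
    trait: str
    source_frame: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.design = np.asarray(self.design, dtype=np.float64)
        if len(np.unique(self.ids)) != len(self.ids):
            raise DuplicateIdError("duplicate individual ids in phenotype table")
        if len(np.unique(self.y[~np.isnan(self.y)])) < 2:
            raise InsufficientDataError(
                f"trait {self.trait!r} has fewer than 2 distinct non-missing values"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        trait: str,
        fixed: Sequence[str] = (),
        id_column: str | None = None,
    ) -> "PhenotypeTable":
        if trait not in df.columns:
            raise KeyError(f"trait column {trait!r} not found")
        for col in fixed:
            if col not in df.columns:
                raise KeyError(f"fixed-effect column {col!r} not found")
        id_column = id_column or df.columns[0]
        keep = df[trait].notna()
        n_dropped = int((~keep).sum())
        if n_dropped:
            log.info("dropped %d rows with missing %s", n_dropped, trait)
        df = df.loc[keep]
        if len(df) < 2:
            raise InsufficientDataError("fewer than 2 individuals with a trait value")
        cols = [np.ones(len(df))]
        names = ["intercept"]
        for col in fixed:
            series = df[col]
            if pd.api.types.is_numeric_dtype(series):
                cols.append(series.to_numpy(dtype=np.float64))
                names.append(col)
            else:
                levels = list(pd.unique(series))  # first observed level = reference
                for lvl in levels[1:]:
                    cols.append((series == lvl).to_numpy(dtype=np.float64))
                    names.append(f"{col}[{lvl}]")
        return cls(
            ids=df[id_column].astype(str).to_numpy(dtype=object),
            y=df[trait].to_numpy(dtype=np.float64),
            design=np.column_stack(cols),
            design_names=names,
            trait=trait,
            source_frame=df.reset_index(drop=True),
        )

    def with_covariates(self, names: Sequence[str], matrix: np.ndarray) -> "PhenotypeTable":
        """Append numeric covariate columns (rows aligned to ``self.ids``)."""
        matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
        if matrix.shape[0] != self.n:
            raise ValueError("covariate rows do not match phenotype records")
        return PhenotypeTable(
            ids=self.ids,
            y=self.y,
            design=np.column_stack([self.design, matrix]),
            design_names=self.design_names + list(names),
            trait=self.trait,
            source_frame=self.source_frame,
        )


def read_phenotypes(
    path: str | Path, trait: str, fixed: Sequence[str] = (), id_column: str | None = None
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable.from_frame(df, trait=trait, fixed=fixed, id_column=id_column)


SCAN_TABLE_COLUMNS = [
    "window_index",
    "chromosome",
    "start_bp",
    "end_bp",
    "midpoint_bp",
    "start_snp",
    "end_snp",
    "r",
    "r_p",
    "z_diff",
    "p_raw",
    "p_bonferroni",
    "class",
    "rank_percent",
]


def write_scan_table(result, path: str | Path) -> None:
    """Write one TSV row per window; correlations at 6-decimal precision,
    p-values in scientific notation, empty rank for unranked windows."""
    df = result.to_frame()
    if len(df) == 0:
        raise ValueError("scan result is empty; nothing to write")

    def fmt_f(v):
        return "" if pd.isna(v) else f"{v:.6f}"

    def fmt_p(v):
        return "" if pd.isna(v) else f"{v:.6g}"

    out = pd.DataFrame(
        {
            "window_index": df["window_index"],
            "chromosome": df["chromosome"],
            "start_bp": df["start_bp"],
            "end_bp": df["end_bp"],
            "midpoint_bp": df["midpoint_bp"],
            "start_snp": df["start_snp"],
            "end_snp": df["end_snp"],
            "r": df["r"].map(fmt_f),
            "r_p": df["r_p"].map(fmt_f),
            "z_diff": df["z_diff"].map(fmt_f),
            "p_raw": df["p_raw"].map(fmt_p),
            "p_bonferroni": df["p_bonferroni"].map(fmt_p),
            "class": df["class"],
            "rank_percent": df["rank_percent"].map(fmt_f),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_scan_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "class": str})
    for col in ("r", "r_p", "z_diff", "p_raw", "p_bonferroni", "rank_percent"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_effects(path: str | Path, snp_map: SnpMap):
    """Read a 2-column (snp_id, effect) TSV and align it to a SNP map."""
    from .gblup import SnpEffects  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("effect file needs columns snp_id, effect")
    lookup = dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)))
    missing = [s for s in snp_map.snp_id if s not in lookup]
    if missing:
        raise AlignmentError(f"effect file lacks {len(missing)} map SNPs (first: {missing[0]!r})")
    u = np.array([lookup[s] for s in snp_map.snp_id], dtype=np.float64)
    return SnpEffects(u_hat=u, map=snp_map)


def write_effects(effects, path: str | Path) -> None:
    pd.DataFrame({"snp_id": effects.map.snp_id, "effect": effects.u_hat}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
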