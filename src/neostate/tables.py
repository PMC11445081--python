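"""Input tables: relative-abundance matrices, sample metadata, genome annotations.

All on-disk formats are UTF-8, tab-delimited text with a header row. The
in-memory substrate of the community-typing pipeline is :class:`AbundanceTable`,
a validated samples x species matrix of relative abundances (fractions summing
to 1 per sample). Mixture modelling needs counts, so :func:`to_counts` scales
fractions to a uniform pseudo-depth; using one depth for every sample keeps
overdispersion comparable across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "CountTable",
    "read_abundance_table",
    "to_counts",
    "DEFAULT_TIMEPOINT_MAP",
    "read_sample_metadata",
    "derive_timepoint_labels",
    "reconcile_samples",
    "read_genome_annotations",
    "parse_gene_field",
]

#: half-open [lo, hi) day-of-life windows mapped to nominal timepoint labels
DEFAULT_TIMEPOINT_MAP = {
    "day4": (3, 6),
    "day7": (6, 14),
    "day21": (14, 35),
    "infancy": (180, 395),
}

_ROW_SUM_TOL = 1e-6
_ROW_SUM_REJECT = 0.05


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dups}")


@dataclass
class AbundanceTable:
    """Samples x species relative-abundance matrix.

    ``data`` is a DataFrame indexed by sample id with species ids as columns.
    Every value is >= 0 and every row sums to 1 within 1e-6.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "species")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("negative abundance values")
        rowsum = values.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > _ROW_SUM_TOL):
            bad = self.data.index[np.abs(rowsum - 1.0) > _ROW_SUM_TOL].tolist()
            raise ValueError(f"rows do not sum to 1: {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        """Validate ``df``; renormalize rows off by <= 0.05 (with a warning)."""
        values = df.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("negative abundance values")
        rowsum = values.sum(axis=1)
        dev = np.abs(rowsum - 1.0)
        if np.any(dev > _ROW_SUM_REJECT):
            bad = df.index[dev > _ROW_SUM_REJECT].tolist()
            raise ValueError(
                f"rows are not relative abundances (sum deviates by >{_ROW_SUM_REJECT}): "
                f"{bad[:5]}"
            )
        if np.any(dev > _ROW_SUM_TOL):
            n_bad = int(np.sum(dev > _ROW_SUM_TOL))
            warnings.warn(
                f"renormalized {n_bad} row(s) whose sums deviated from 1 by <= "
                f"{_ROW_SUM_REJECT}",
                stacklevel=2,
            )
            df = df.div(rowsum, axis=0)
        return cls(df)

    def to_tsv(self, path, orientation: str = "samples_as_rows") -> None:
        df = self.data if orientation == "samples_as_rows" else self.data.T
        df.to_csv(path, sep="\t")

    def filter_species(self, min_prevalence: float = 0.0, min_abundance: float = 0.0,
                       renormalize: bool = True) -> "AbundanceTable":
        """Optional prevalence/abundance species filter (default keeps everything)."""
        keep = ((self.data > min_abundance).mean(axis=0) >= min_prevalence)
        df = self.data.loc[:, keep]
        if renormalize:
            df = df.div(df.sum(axis=1), axis=0)
        return AbundanceTable(df)


@dataclass
class CountTable:
    """Samples x species non-negative integer pseudo-counts at uniform depth."""

    data: pd.DataFrame
    depth: int

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "species")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("count table must be integer-valued")
        if np.any(values < 0):
            raise ValueError("negative counts")
        slack = self.data.shape[1]
        rowsum = values.sum(axis=1)
        if np.any(np.abs(rowsum - self.depth) > slack):
            raise ValueError("row sums deviate from depth by more than the species count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_fractions(self) -> AbundanceTable:
        frac = self.data.div(self.data.sum(axis=1), axis=0)
        return AbundanceTable(frac)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


def read_abundance_table(path, orientation: str = "samples_as_rows") -> AbundanceTable:
    """Read a TSV relative-abundance matrix.

    ``orientation`` declares whether rows of the file are samples or species;
    the returned table is always samples x species. Rows whose sums deviate
    from 1 by more than 1e-6 but at most 0.05 are renormalized with a warning;
    larger deviations are rejected (the file is probably a count table).
    """
    if orientation not in ("samples_as_rows", "species_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "species_as_rows":
        df = df.T
    _check_unique(df.index, "sample")
    _check_unique(df.columns, "species")
    return AbundanceTable.from_dataframe(df)


def to_counts(table: AbundanceTable, depth: int = 10_000) -> CountTable:
    """Scale fractions to integer pseudo-counts at uniform depth ``depth``.

    Each entry is round(fraction * depth); row totals land within +/- S of the
    depth, S = number of species. Depths below 100 are rejected as too coarse
    for mixture fitting.
    """
    depth = int(depth)
    if depth < 100:
        raise ValueError("pseudo-depth must be >= 100")
    counts = np.rint(table.values * depth).astype(np.int64)
    df = pd.DataFrame(counts, index=table.data.index, columns=table.data.columns)
    return CountTable(df, depth=depth)


REQUIRED_METADATA_COLUMNS = ("sample_id", "participant_id", "day_of_life", "birth_mode")
BIRTH_MODES = ("VD", "CS")


def derive_timepoint_labels(day_of_life: pd.Series, timepoint_map=None) -> pd.Series:
    """Map day-of-life integers onto nominal timepoint labels (half-open ranges).

    Days falling outside every window get the explicit marker ``"other"``.
    """
    timepoint_map = timepoint_map or DEFAULT_TIMEPOINT_MAP
    labels = pd.Series("other", index=day_of_life.index, dtype=object)
    for name, (lo, hi) in timepoint_map.items():
        labels[(day_of_life >= lo) & (day_of_life < hi)] = name
    return labels


def read_sample_metadata(path, timepoint_map=None) -> pd.DataFrame:
    """Read per-sample metadata; derive ``timepoint_label`` from day of life.

    Missing covariate values are retained as the explicit string ``"missing"``
    (they are dropped listwise only inside model fitting, never here).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing required columns: {missing_cols}")
    _check_unique(df["sample_id"], "sample")
    if (df["day_of_life"] < 0).any():
        raise ValueError("day_of_life must be >= 0")
    bad_modes = set(df["birth_mode"].dropna().unique()) - set(BIRTH_MODES)
    if bad_modes:
        raise ValueError(f"unknown birth_mode values: {sorted(bad_modes)}")
    df["timepoint_label"] = derive_timepoint_labels(df["day_of_life"], timepoint_map)
    covariate_cols = [c for c in df.columns
                      if c not in REQUIRED_METADATA_COLUMNS + ("timepoint_label",)]
    for c in covariate_cols:
        df[c] = df[c].astype(object).where(df[c].notna(), "missing")
    return df.set_index("sample_id", drop=False)


def reconcile_samples(table: AbundanceTable, metadata: pd.DataFrame) -> dict:
    """Report sample ids present in only one of the abundance table / metadata."""
    abund = set(table.sample_ids)
    meta = set(metadata["sample_id"])
    listing = {
        "abundance_only": sorted(abund - meta),
        "metadata_only": sorted(meta - abund),
        "shared": len(abund & meta),
    }
    if listing["abundance_only"]:
        logger.warning(
            "%d abundance sample(s) missing from metadata", len(listing["abundance_only"])
        )
    return listing


GENOME_QC_COLUMNS = ("completeness", "contamination", "n50", "mean_contig_len", "n_contigs")


def parse_gene_field(value) -> tuple:
    """Split a ';'-separated gene-identifier field into a deduplicated tuple.

    AMR entries may carry a class label as ``symbol|class``; the whole token is
    kept intact here and interpreted downstream.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return ()
    seen: list[str] = []
    for token in str(value).split(";"):
        token = token.strip()
        if token and token not in seen:
            seen.append(token)
    return tuple(seen)


def read_genome_annotations(path) -> pd.DataFrame:
    """Read a per-genome annotation table (QC stats, gene families, AMR/virulence).

    List-valued columns (``gene_families``, ``amr_genes``, ``virulence_genes``)
    are ';'-separated in the TSV and parsed into tuples without duplicates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    if "genome_id" not in df.columns:
        raise ValueError("annotation table requires a genome_id column")
    _check_unique(df["genome_id"], "genome")
    for col in ("gene_families", "amr_genes", "virulence_genes"):
        if col in df.columns:
            df[col] = df[col].map(parse_gene_field)
        else:
            df[col] = [() for _ in range(len(df))]
    for col in ("completeness", "contamination"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"{col} must lie in [0, 100]")
    return df.set_index("genome_id", drop=False)
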