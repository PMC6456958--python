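"""Count-table data model and deterministic preprocessing.

The analysis starts from a sample x OTU table of read counts together with a
sample metadata table assigning each sample to a host plant species and a leaf
compartment (``epiphyte`` -- leaf surface, or ``endophyte`` -- leaf interior).
This module holds the containers and the preprocessing steps that turn raw
counts into the matrices consumed downstream:

* :func:`filter_low_count_otus` -- drop OTUs whose pooled read total is below a
  threshold (default 10 reads), the usual guard against PCR/sequencing noise.
* :func:`rarefy` -- normalize every sample to a common sequencing depth by
  subsampling reads without replacement.
* :func:`binarize` / :func:`to_species_matrix` -- presence/absence per sample,
  then the plant-species x OTU "species-level" matrix whose cells count the
  samples of each plant species in which each OTU was observed.
* community summaries: per-sample OTU richness, Hellinger transformation,
  Bray-Curtis dissimilarities, sample-based rarefaction curves, and the
  compartment-specific/shared OTU partition.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._util import frame_hash

COMPARTMENTS = ("epiphyte", "endophyte")
METADATA_COLUMNS = ("plant_species", "compartment")


def _validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    if metadata.index.has_duplicates:
        dups = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if metadata[list(METADATA_COLUMNS)].isna().any().any():
        raise ValueError("metadata contains missing plant_species/compartment values")
    return metadata


@dataclass
class CountMatrix:
    """Sample x OTU non-negative integer read counts with aligned metadata.

    ``data`` rows are samples, columns are OTUs.  ``metadata`` is indexed by
    sample id and carries at least ``plant_species`` and ``compartment``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate OTU ids in count table")
        values = self.data.to_numpy()
        if values.size:
            try:
                values = values.astype(float)
            except (TypeError, ValueError):
                for r in range(values.shape[0]):
                    for c in range(values.shape[1]):
                        try:
                            float(values[r, c])
                        except (TypeError, ValueError):
                            raise ValueError(
                                "count table cell is not numeric at "
                                f"(sample={self.data.index[r]!r}, "
                                f"otu={self.data.columns[c]!r}): "
                                f"{values[r, c]!r}"
                            ) from None
                raise
            bad = ~np.isfinite(values) | (values < 0) | (np.mod(values, 1) != 0)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    "count table cell is not a non-negative integer at "
                    f"(sample={self.data.index[r]!r}, otu={self.data.columns[c]!r}): "
                    f"{self.data.iat[r, c]!r}"
                )
        _validate_metadata(self.metadata)
        absent = [s for s in self.data.index if s not in self.metadata.index]
        if absent:
            raise ValueError(f"metadata missing for sample(s): {absent}")
        # align metadata row order to the table
        self.metadata = self.metadata.loc[self.data.index]
        self.data = self.data.astype(np.int64)

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def otus(self) -> list:
        return list(self.data.columns)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_otus(self, otus) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(otus)], self.metadata)


@dataclass
class BinaryMatrix:
    """Presence/absence view of a count table (same axes, values in {0,1})."""

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("binary matrix contains values outside {0, 1}")
        _validate_metadata(self.metadata)
        self.metadata = self.metadata.loc[self.data.index]
        self.data = self.data.astype(np.int64)

    @property
    def source_hash(self) -> str:
        return frame_hash(self.data)


@dataclass
class SpeciesMatrix:
    """Plant species x OTU sample-occurrence counts.

    Cell (s, o) is the number of samples of plant species ``s`` in which OTU
    ``o`` was present; ``row_capacity`` records the number of samples per
    species, the per-row upper bound on any cell.  ``source_hash`` ties the
    matrix to the sample-level binary matrix it was built from so permutation
    ensembles can be provenance-checked against it.
    """

    data: pd.DataFrame
    row_capacity: pd.Series
    source_hash: str = field(default="")

    def __post_init__(self) -> None:
        cap = self.row_capacity.loc[self.data.index]
        vals = self.data.to_numpy()
        if vals.size:
            if (vals < 0).any():
                raise ValueError("species matrix has negative cells")
            if (vals > cap.to_numpy()[:, None]).any():
                raise ValueError("species matrix cell exceeds its row capacity")
        self.data = self.data.astype(np.int64)

    @property
    def species(self) -> list:
        return list(self.data.index)

    @property
    def otus(self) -> list:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# input / output
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read the 3-column sample metadata TSV (sample_id, plant_species, compartment)."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ("sample_id",) + METADATA_COLUMNS
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing column(s): {missing}")
    return _validate_metadata(meta.set_index("sample_id"))


def read_counts(table_path, metadata_path, format: str = "tsv",
                orientation: str = "auto") -> CountMatrix:
    """Load a count table plus metadata into a :class:`CountMatrix`.

    ``format`` is ``tsv`` (dense, first column holds ids, '#' comments
    ignored) or ``biom-json`` (BIOM 1.0 dense or sparse JSON).  For TSV the
    orientation (samples-as-rows vs OTUs-as-rows) is auto-detected from the
    overlap with metadata sample ids; pass ``orientation='samples'`` or
    ``'otus'`` to override which axis the file's ROWS represent.
    """
    meta = read_metadata(metadata_path)
    if format == "tsv":
        table = pd.read_csv(table_path, sep="\t", comment="#", index_col=0)
    elif format == "biom-json":
        table = _read_biom_json(table_path)
    else:
        raise ValueError(f"unknown count table format: {format!r}")

    known = set(meta.index)
    if orientation == "auto":
        rows_hit = sum(1 for s in table.index if s in known)
        cols_hit = sum(1 for s in table.columns if s in known)
        orientation = "samples" if rows_hit >= cols_hit else "otus"
    if orientation == "otus":
        table = table.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return CountMatrix(table, meta)


def _read_biom_json(path) -> pd.DataFrame:
    """Parse a BIOM 1.0 JSON table into a samples x OTUs DataFrame.

    BIOM stores observations (OTUs) as rows and samples as columns; both the
    dense and the sparse matrix_type are supported.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return pd.DataFrame(mat.T, index=samples, columns=otus)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_low_count_otus(mat: CountMatrix, min_total_reads: int = 10,
                          scope: str = "pooled") -> CountMatrix:
    """Remove OTUs whose read total is below ``min_total_reads``.

    ``scope='pooled'`` (default) sums reads over all samples of the table;
    ``scope='per_compartment'`` keeps an OTU if it reaches the threshold
    within at least one compartment.
    """
    if scope == "pooled":
        totals = mat.data.sum(axis=0)
        keep = totals >= min_total_reads
    elif scope == "per_compartment":
        by = mat.data.groupby(mat.metadata["compartment"].to_numpy()).sum()
        keep = (by >= min_total_reads).any(axis=0)
    else:
        raise ValueError(f"unknown filter scope: {scope!r}")
    return CountMatrix(mat.data.loc[:, keep[keep].index], mat.metadata)


def rarefy(mat: CountMatrix, depth: int, seed: int) -> CountMatrix:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per sample (equivalent to drawing
    ``depth`` reads uniformly without replacement from the sample's reads).
    Samples with fewer than ``depth`` total reads are a hard error.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = mat.sample_totals()
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"sample(s) below rarefaction depth {depth}: "
            + ", ".join(f"{s} ({t})" for s, t in short.items())
        )
    rng = np.random.default_rng(seed)
    counts = mat.data.to_numpy()
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return CountMatrix(pd.DataFrame(out, index=mat.data.index,
                                    columns=mat.data.columns), mat.metadata)


def binarize(mat: CountMatrix | BinaryMatrix) -> BinaryMatrix:
    """Presence/absence: cell = 1 iff the count is > 0 (idempotent)."""
    return BinaryMatrix((mat.data > 0).astype(np.int64), mat.metadata)


def to_species_matrix(bin_mat: BinaryMatrix, metadata: pd.DataFrame | None = None
                      ) -> SpeciesMatrix:
    """Collapse a sample-level binary matrix to the plant-species level.

    Cell (species, OTU) counts the samples of that species in which the OTU is
    present.  Species row order follows first appearance in the metadata.
    """
    meta = bin_mat.metadata if metadata is None else metadata.loc[bin_mat.data.index]
    labels = meta["plant_species"]
    species = list(dict.fromkeys(labels))
    onehot = np.stack([(labels == s).to_numpy() for s in species]).astype(np.int64)
    occ = onehot @ bin_mat.data.to_numpy()
    capacity = pd.Series(onehot.sum(axis=1), index=species)
    return SpeciesMatrix(
        pd.DataFrame(occ, index=species, columns=bin_mat.data.columns),
        row_capacity=capacity,
        source_hash=bin_mat.source_hash,
    )


def partition_otus(mat_a: CountMatrix, mat_b: CountMatrix):
    """Split OTUs into (only in A, only in B, shared), by nonzero read totals."""
    present_a = set(mat_a.data.columns[(mat_a.data.sum(axis=0) > 0)])
    present_b = set(mat_b.data.columns[(mat_b.data.sum(axis=0) > 0)])
    return (present_a - present_b, present_b - present_a, present_a & present_b)


# ---------------------------------------------------------------------------
# community summaries
# ---------------------------------------------------------------------------

def richness(mat: CountMatrix) -> pd.Series:
    """Per-sample OTU richness: number of OTUs with count > 0."""
    return (mat.data > 0).sum(axis=1)


def hellinger(mat: CountMatrix) -> pd.DataFrame:
    """Hellinger transform: sqrt(count / sample total); zero samples stay zero."""
    x = mat.data.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(totals > 0, x / np.where(totals > 0, totals, 1), 0.0))
    return pd.DataFrame(out, index=mat.data.index, columns=mat.data.columns)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between rows.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); a pair of all-zero rows is
    defined as distance 0 (identical rows).
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative input")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def rarefaction_curve(mat: CountMatrix, group: str, n_perm: int, seed: int):
    """Sample-based rarefaction curve for one plant species.

    For k = 1..n samples of the group, the mean (over ``n_perm`` random sample
    orderings) cumulative number of distinct OTUs among the first k samples.
    Returns a list of (k, mean_otus) pairs, monotone non-decreasing in k.
    """
    members = mat.metadata.index[mat.metadata["plant_species"] == group]
    if len(members) == 0:
        raise ValueError(f"no samples for plant species {group!r}")
    pres = (mat.data.loc[members].to_numpy() > 0)
    n = pres.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.cumsum(pres[order], axis=0) > 0
        acc += seen.sum(axis=1)
    means = acc / n_perm
    return [(k + 1, float(means[k])) for k in range(n)]
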