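"""OTU table and sample-metadata containers, file I/O, and normalizations.

The count table is the pipeline's single in-memory currency: a dense
non-negative integer matrix with one row per OTU and one column per sample.
Two distinct normalizations are provided and must not be confused:

``within_sample_relabund``
    column-normalized relative abundances (each sample sums to 1); feeds the
    mean-relative-abundance filter used for generalist determination.
``otu_profile``
    row-normalized occupancy profile of one OTU across samples (sums to 1);
    this is the ``P_ij`` that enters Levins' niche-breadth index, which is
    why B ranges from 1 up to the number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TSV_HEADER = "#OTU ID"


class ParseError(ValueError):
    """Malformed on-disk table (bad header, cell, or duplicate id)."""


@dataclass
class OtuTable:
    """Dense OTU-by-sample count matrix with identifiers.

    Parameters
    ----------
    otu_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of shape (n_otus, n_samples)
        Non-negative integer read counts.
    """

    otu_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self.counts = counts

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [idx[o] for o in otu_ids]
        return OtuTable(list(otu_ids), list(self.sample_ids), self.counts[rows])

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return OtuTable(list(self.otu_ids), list(sample_ids), self.counts[:, cols])

    def __eq__(self, other):
        return (
            isinstance(other, OtuTable)
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleMetadata:
    """Per-sample region labels plus optional numeric covariates/coordinates."""

    region: dict
    covariates: pd.DataFrame | None = None
    coordinates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.region = {str(k): str(v) for k, v in self.region.items()}
        if self.covariates is not None:
            cov = self.covariates.astype(float)
            if not np.all(np.isfinite(cov.to_numpy())):
                raise ValueError("covariates contain non-finite values")
            self.covariates = cov

    def regions(self) -> list:
        seen = {}
        for r in self.region.values():
            seen.setdefault(r, None)
        return list(seen)

    def samples_in_region(self, region: str) -> list:
        return [s for s, r in self.region.items() if r == region]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _infer_format(path, fmt=None) -> str:
    if fmt is not None:
        return fmt
    s = str(path)
    if s.endswith(".biom") or s.endswith(".json"):
        return "biom_json"
    return "tsv"


def read_otu_table(path, format: str | None = None) -> OtuTable:
    """Read an OTU table from TSV or BIOM v1.0 JSON.

    TSV dialect: first column holds OTU ids (header cell ``#OTU ID``),
    remaining header cells are sample ids, cells are integer counts.
    """
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "biom_json":
        import biom

        t = biom.load_table(str(path))
        counts = np.asarray(t.matrix_data.todense())
        mat = counts
        if not np.all(np.equal(np.mod(mat, 1), 0)):
            raise ParseError(f"{path}: BIOM table contains non-integer counts")
        return OtuTable(
            [str(o) for o in t.ids("observation")],
            [str(s) for s in t.ids("sample")],
            mat.astype(np.int64),
        )
    raise ValueError(f"unknown format {fmt!r}")


def _read_tsv(path) -> OtuTable:
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cells = header.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path}: header row has no sample columns")
        sample_ids = cells[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}: duplicate sample id in header")
        otu_ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cells):
                raise ParseError(
                    f"{path}: line {ln}: expected {len(cells)} columns, got {len(parts)}"
                )
            otu_ids.append(parts[0])
            row = []
            for j, cell in enumerate(parts[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-integer cell {cell!r} at OTU {parts[0]!r}, "
                        f"sample {sample_ids[j]!r}"
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"{path}: negative cell {cell!r} at OTU {parts[0]!r}, "
                        f"sample {sample_ids[j]!r}"
                    )
                row.append(v)
            rows.append(row)
        if len(set(otu_ids)) != len(otu_ids):
            raise ParseError(f"{path}: duplicate OTU id")
        return OtuTable(otu_ids, sample_ids, np.asarray(rows, dtype=np.int64))


def write_otu_table(table: OtuTable, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(TSV_HEADER + "\t" + "\t".join(table.sample_ids) + "\n")
            for i, otu in enumerate(table.otu_ids):
                fh.write(otu + "\t" + "\t".join(map(str, table.counts[i])) + "\n")
    elif fmt == "biom_json":
        import biom

        t = biom.Table(
            table.counts.astype(float),
            observation_ids=table.otu_ids,
            sample_ids=table.sample_ids,
        )
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(t.to_json("microniche"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata TSV: columns ``sample_id``, ``region``, covariates.

    Columns named ``latitude``/``longitude`` are routed to coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id" or "region" not in df.columns:
        raise ParseError(f"{path}: metadata needs 'sample_id' and 'region' columns")
    df = df.set_index("sample_id")
    region = df["region"].astype(str).to_dict()
    coord_cols = [c for c in ("latitude", "longitude") if c in df.columns]
    coords = {}
    if len(coord_cols) == 2:
        coords = {
            s: (float(df.at[s, "latitude"]), float(df.at[s, "longitude"]))
            for s in df.index
        }
    cov_cols = [c for c in df.columns if c not in ("region", *coord_cols)]
    cov = df[cov_cols].astype(float) if cov_cols else None
    return SampleMetadata(region=region, covariates=cov, coordinates=coords)


def write_metadata(meta: SampleMetadata, path) -> None:
    samples = list(meta.region)
    df = pd.DataFrame({"region": [meta.region[s] for s in samples]}, index=samples)
    if meta.coordinates:
        df["latitude"] = [meta.coordinates[s][0] for s in samples]
        df["longitude"] = [meta.coordinates[s][1] for s in samples]
    if meta.covariates is not None:
        df = df.join(meta.covariates)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# normalizations and filters
# ---------------------------------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int, return_dropped: bool = False):
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (and logged);
    padding shallow samples would fabricate reads. Uses the multivariate
    hypergeometric distribution, i.e. exact draw-without-replacement.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, ", ".join(dropped))
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    cols = []
    for j in np.flatnonzero(keep):
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    out = OtuTable(
        list(table.otu_ids),
        [s for s, k in zip(table.sample_ids, keep) if k],
        np.column_stack(cols),
    )
    if return_dropped:
        return out, dropped
    return out


def within_sample_relabund(table: OtuTable) -> np.ndarray:
    """Column-normalized relative abundances (every sample sums to 1)."""
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total count")
    return table.counts / totals[np.newaxis, :]


def otu_profiles(table: OtuTable) -> np.ndarray:
    """Row-normalized profiles P_ij = n_ij / sum_i n_ij for every OTU.

    Rows with zero total are returned as NaN (callers decide how to treat
    absent OTUs).
    """
    totals = table.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals[:, None] > 0, table.counts / totals[:, None], np.nan)


def otu_profile(table: OtuTable, otu_id: str) -> np.ndarray:
    """Occupancy profile of one OTU across samples (the B-index's P_ij)."""
    try:
        i = table.otu_ids.index(str(otu_id))
    except ValueError:
        raise KeyError(f"unknown OTU {otu_id!r}") from None
    total = table.counts[i].sum()
    if total == 0:
        raise ValueError(f"OTU {otu_id!r} has zero total count")
    return table.counts[i] / total


def prevalence_filter(
    table: OtuTable, min_occurrence: int = 4, min_total_reads: int = 10
) -> OtuTable:
    """Drop rare OTUs before network inference.

    Keeps OTUs occurring in >= ``min_occurrence`` samples with total reads
    >= ``min_total_reads`` (both inclusive); the sample axis is unchanged.
    """
    if min_occurrence < 0 or min_total_reads < 0:
        raise ValueError("thresholds must be >= 0")
    occ = (table.counts > 0).sum(axis=1)
    tot = table.counts.sum(axis=1)
    keep = (occ >= min_occurrence) & (tot >= min_total_reads)
    return OtuTable(
        [o for o, k in zip(table.otu_ids, keep) if k],
        list(table.sample_ids),
        table.counts[keep],
    )
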