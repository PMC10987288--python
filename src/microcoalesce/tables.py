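"""Count-table data model, TSV I/O, and abundance-based ASV filtering.

The central container is :class:`AbundanceTable`, an ASV-by-sample matrix of
non-negative integer counts, accompanied by :class:`SampleMetadata` rows that
assign each sample to a class (``gut``, ``water``, ``sediment``), a species
code for fish, a site, and optionally a nitrogen stable-isotope value.

Rare amplicon sequence variants (ASVs) are removed with a global relative
abundance rule: a taxon survives when its total count across all samples is at
least ``threshold_fraction`` of the grand total (default 0.005%, i.e. 5 reads
per 100,000).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("gut", "water", "sediment")

#: Default rare-ASV filter: 0.005% of all sequences.
DEFAULT_FILTER_FRACTION = 5e-5

#: Fish species codes used throughout (7 lake species).
SPECIES_CODES = ("AN", "CA", "CB", "CD", "HL", "PS", "TS")

METADATA_COLUMNS = ("sample_id", "sample_class", "species_code", "family", "site", "delta15N")


class TableError(ValueError):
    """Raised for malformed or inconsistent table inputs."""


@dataclass
class AbundanceTable:
    """ASV-by-sample count matrix with row/column identifiers.

    Parameters
    ----------
    taxon_ids : sequence of str
        Unique ASV identifiers (rows).
    sample_ids : sequence of str
        Unique sample identifiers (columns).
    counts : (n_taxa, n_samples) array-like of int
        Non-negative read counts.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = list(self.taxon_ids)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise TableError("duplicate taxon IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableError("duplicate sample IDs")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise TableError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector for one sample."""
        return self.counts[:, self.sample_ids.index(sample_id)].copy()

    def subset_samples(self, keep: Sequence[str], drop_empty_taxa: bool = True) -> "AbundanceTable":
        """Restrict to ``keep`` samples (order preserved); all-zero taxa dropped."""
        missing = [s for s in keep if s not in self.sample_ids]
        if missing:
            raise TableError(f"unknown sample IDs: {missing}")
        cols = [self.sample_ids.index(s) for s in keep]
        counts = self.counts[:, cols]
        taxa = self.taxon_ids
        if drop_empty_taxa:
            nz = counts.sum(axis=1) > 0
            counts = counts[nz]
            taxa = [t for t, k in zip(self.taxon_ids, nz) if k]
        return AbundanceTable(taxa, list(keep), counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column taxon IDs, header row sample IDs."""
        frame = self.to_frame()
        frame.index.name = "taxon_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AbundanceTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)), frame.to_numpy())


@dataclass
class SampleMetadata:
    """Metadata for a single sample.

    ``species_code`` and ``family`` are required for gut samples and absent
    (``None``) for environmental samples; ``delta15N`` is the per-mil nitrogen
    stable-isotope value where measured.
    """

    sample_id: str
    sample_class: str
    site: str
    species_code: str | None = None
    family: str | None = None
    delta15N: float | None = None

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise TableError(
                f"sample_class must be one of {SAMPLE_CLASSES}, got {self.sample_class!r}"
            )
        if self.sample_class == "gut" and not self.species_code:
            raise TableError(f"gut sample {self.sample_id!r} lacks a species_code")


def metadata_to_frame(meta: Iterable[SampleMetadata]) -> pd.DataFrame:
    rows = [dataclasses.asdict(m) for m in meta]
    frame = pd.DataFrame(rows)
    return frame[list(METADATA_COLUMNS)]


def write_metadata_tsv(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    metadata_to_frame(meta).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                sample_class=str(row.sample_class),
                site=str(row.site),
                species_code=None if pd.isna(row.species_code) else str(row.species_code),
                family=None if pd.isna(row.family) else str(row.family),
                delta15N=None if pd.isna(row.delta15N) else float(row.delta15N),
            )
        )
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise TableError("duplicate sample IDs in metadata")
    return out


def metadata_by_id(meta: Iterable[SampleMetadata]) -> dict[str, SampleMetadata]:
    out = {m.sample_id: m for m in meta}
    return out


def filter_rare_asvs(
    table: AbundanceTable, threshold_fraction: float = DEFAULT_FILTER_FRACTION
) -> AbundanceTable:
    """Remove globally rare ASVs.

    A taxon is retained when its total count across all samples, as a fraction
    of the table's grand total, is ``>= threshold_fraction``. With the default
    0.005% rule a taxon needs at least 5 reads per 100,000 total. All-zero
    taxa are always dropped. Samples are untouched.
    """
    if not 0 <= threshold_fraction < 1:
        raise TableError("threshold_fraction must be in [0, 1)")
    grand = table.grand_total
    if grand == 0:
        raise TableError("cannot filter an empty (all-zero) table")
    totals = table.counts.sum(axis=1)
    keep = (totals > 0) & (totals / grand >= threshold_fraction)
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    return AbundanceTable(taxa, table.sample_ids, table.counts[keep])


def relative_abundance(table: AbundanceTable) -> np.ndarray:
    """Taxon-by-sample proportions; each sample column sums to 1."""
    totals = table.counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise TableError(f"samples with zero total reads: {bad}")
    return table.counts / totals


def aggregate_by_class(
    table: AbundanceTable, meta: Iterable[SampleMetadata]
) -> dict[str, set[str]]:
    """Per-sample-class presence sets: taxa with count > 0 in >=1 sample of the class."""
    lookup = metadata_by_id(meta)
    missing = [s for s in table.sample_ids if s not in lookup]
    if missing:
        raise TableError(f"samples missing from metadata: {missing}")
    out: dict[str, set[str]] = {c: set() for c in SAMPLE_CLASSES}
    for j, sid in enumerate(table.sample_ids):
        cls = lookup[sid].sample_class
        present = np.nonzero(table.counts[:, j] > 0)[0]
        out[cls].update(table.taxon_ids[i] for i in present)
    return out


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement (seeded)."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise TableError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)
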