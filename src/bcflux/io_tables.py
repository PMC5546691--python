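"""OTU count tables, sample metadata, and the read/OTU-level filters.

The central container is :class:`OTUTable`: a non-negative integer count
matrix (OTU rows x sample columns) plus a per-sample :class:`SampleKey`
(compartment label, nominal time index, optional replicate) used by the
spatio-temporal BC% machinery.

Tables and metadata are plain TSV.  FASTQ read QC follows the standard
amplicon-pipeline rule set: minimum length, minimum mean Phred quality,
and no ambiguous base calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleKey",
    "OTUTable",
    "ReadQCRule",
    "QCStats",
    "read_otu_table",
    "write_otu_table",
    "filter_rare_otus",
    "to_relative_abundance",
    "rarefy_table",
    "qc_filter_reads",
]


@dataclass(frozen=True, order=True)
class SampleKey:
    """Spatio-temporal address of a sample.

    Parameters
    ----------
    compartment
        Label of the ecosystem compartment the sample came from
        (e.g. consumer ``"A"``, substrate ``"S"``, water ``"W"``).
    time_index
        Nominal sampling time (e.g. day number).  Time points need not be
        consecutive; "previous" always means the previous *sampled* time.
    replicate
        Optional replicate label; ``None`` for pooled samples.
    """

    compartment: str
    time_index: int
    replicate: str | None = None


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


class OTUTable:
    """Validated OTU x sample count matrix with per-sample metadata.

    Counts are stored as an int64 :class:`pandas.DataFrame` with OTU ids on
    the index and sample ids on the columns.  Construction validates:

    * no duplicate OTU or sample ids,
    * all counts non-negative integers,
    * metadata sample set == table sample set,
    * no two samples share the same (compartment, time, replicate) key.
    """

    def __init__(self, counts: pd.DataFrame, metadata: Mapping[str, SampleKey]):
        _check_unique(counts.index, "OTU")
        _check_unique(counts.columns, "sample")

        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("counts must be numeric")
            bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
            if bad.any():
                r, c = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"count at OTU {counts.index[r]!r}, sample "
                    f"{counts.columns[c]!r} is {values[r, c]!r}: counts must be "
                    "non-negative integers"
                )

        table_samples = set(counts.columns)
        meta_samples = set(metadata)
        if table_samples != meta_samples:
            missing_meta = sorted(table_samples - meta_samples)
            missing_table = sorted(meta_samples - table_samples)
            raise ValidationError(
                f"sample/metadata mismatch: missing metadata for {missing_meta}, "
                f"metadata without table column for {missing_table}"
            )
        keys = list(metadata.values())
        if len(set(keys)) != len(keys):
            dupes = sorted(
                {k for k in keys if keys.count(k) > 1},
                key=lambda k: (k.compartment, k.time_index),
            )
            raise ValidationError(f"duplicate sample keys: {dupes}")

        self.counts = counts.astype(np.int64)
        self.metadata: dict[str, SampleKey] = dict(metadata)

    # -- basic accessors -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_key(self, sample_id: str) -> SampleKey:
        return self.metadata[sample_id]

    def sample_by_key(self, key: SampleKey) -> str:
        for sid, k in self.metadata.items():
            if k == key:
                return sid
        raise KeyError(key)

    @property
    def compartments(self) -> list[str]:
        return sorted({k.compartment for k in self.metadata.values()})

    def samples_by_compartment(self) -> dict[str, list[str]]:
        """Sample ids per compartment, each list in time order."""
        out: dict[str, list[str]] = {}
        for sid, key in self.metadata.items():
            out.setdefault(key.compartment, []).append(sid)
        for c in out:
            out[c].sort(key=lambda s: self.metadata[s].time_index)
        return out

    # -- transforms ------------------------------------------------------
    def filter_rare_otus(self, min_total_reads: int = 3) -> "OTUTable":
        return filter_rare_otus(self, min_total_reads)

    def relative_abundance(self) -> pd.DataFrame:
        return to_relative_abundance(self)

    def rarefy(self, depth: int | None = None, seed: int | None = None) -> "OTUTable":
        return rarefy_table(self, depth=depth, seed=seed)

    # -- IO ---------------------------------------------------------------
    def write(self, table_path: str | Path, metadata_path: str | Path) -> None:
        write_otu_table(self, table_path, metadata_path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OTUTable({self.shape[0]} OTUs x {self.shape[1]} samples, "
            f"compartments={self.compartments})"
        )


def read_otu_table(
    table_path: str | Path,
    metadata_path: str | Path,
    transpose: bool = False,
) -> OTUTable:
    """Read a TSV count matrix plus a TSV metadata table.

    The count table has OTU ids in the first column and sample ids in the
    header row (set ``transpose=True`` for sample-rows x OTU-columns files).
    The metadata table needs columns ``sample_id``, ``compartment``,
    ``time_index`` and optionally ``replicate``.
    """
    table_path = Path(table_path)
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "sample (header)")

    counts = pd.read_csv(table_path, sep="\t", index_col=0)
    counts.columns = header  # undo pandas' duplicate-mangling, already checked
    if transpose:
        counts = counts.T

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"replicate": str})
    required = {"sample_id", "compartment", "time_index"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    metadata: dict[str, SampleKey] = {}
    for row in meta.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in metadata:
            raise ValidationError(f"duplicate sample id in metadata: {sid!r}")
        rep = getattr(row, "replicate", None)
        if rep is not None and (pd.isna(rep) or rep == ""):
            rep = None
        metadata[sid] = SampleKey(str(row.compartment), int(row.time_index), rep)

    counts.index = counts.index.map(str)
    counts.columns = counts.columns.map(str)
    counts.index.name = None
    return OTUTable(counts, metadata)


def write_otu_table(
    table: OTUTable, table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the count matrix and metadata as TSV (inverse of read_otu_table)."""
    table.counts.to_csv(table_path, sep="\t", index_label="otu_id")
    rows = [
        {
            "sample_id": sid,
            "compartment": key.compartment,
            "time_index": key.time_index,
            "replicate": "" if key.replicate is None else key.replicate,
        }
        for sid, key in table.metadata.items()
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def filter_rare_otus(table: OTUTable, min_total_reads: int = 3) -> OTUTable:
    """Drop OTUs whose read total across *all* samples is below the threshold.

    The default ``min_total_reads=3`` discards OTUs with only 1 or 2 mapped
    reads dataset-wide, the usual denoising rule for pooled 454/Illumina OTU
    tables.  Idempotent; the sample set is never changed.
    """
    if min_total_reads < 0:
        raise ValidationError("min_total_reads must be >= 0")
    totals = table.counts.sum(axis=1)
    kept = table.counts.loc[totals >= min_total_reads]
    if kept.shape[0] == 0 and table.shape[0] > 0:
        logger.warning(
            "filter_rare_otus removed all %d OTUs (min_total_reads=%d)",
            table.shape[0],
            min_total_reads,
        )
    return OTUTable(kept, table.metadata)


def to_relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances (each column sums to 1)."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"samples with zero total count cannot be normalized: {list(zero.index)}"
        )
    return table.counts / totals


def rarefy_table(
    table: OTUTable, depth: int | None = None, seed: int | None = None
) -> OTUTable:
    """Subsample each sample to a common depth without replacement.

    ``depth`` defaults to the minimum sample total.  A seeded alternative to
    relative-abundance normalization for depth-sensitive comparisons.
    """
    totals = table.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    low = totals[totals < depth]
    if len(low):
        raise ValidationError(
            f"samples shallower than depth {depth}: {list(low.index)}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy()
        out[sid] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index)
    return OTUTable(rarefied, table.metadata)


# ---------------------------------------------------------------------------
# FASTQ read QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadQCRule:
    """Read-level QC thresholds (strict inequalities).

    A read is kept iff length > ``min_length`` AND mean Phred quality >
    ``min_avg_quality`` AND (if ``forbid_ambiguous``) every base is one of
    A/C/G/T.
    """

    min_length: int = 200
    min_avg_quality: float = 25.0
    forbid_ambiguous: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_avg_quality < 0:
            raise ValidationError("QC thresholds must be non-negative")


@dataclass
class QCStats:
    """Partition of the input reads by QC outcome."""

    n_input: int = 0
    kept: int = 0
    dropped_length: int = 0
    dropped_ambiguous: int = 0
    dropped_quality: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_length + self.dropped_ambiguous + self.dropped_quality


_UNAMBIGUOUS = frozenset("ACGT")
_FASTQ_FORMATS = {"phred33": "fastq", "phred64": "fastq-illumina"}


def qc_filter_reads(
    fastq_path: str | Path,
    rule: ReadQCRule = ReadQCRule(),
    out_path: str | Path | None = None,
    encoding: str = "phred33",
) -> tuple[Path, QCStats]:
    """Filter a FASTQ file by the read-QC rule; returns (kept_path, stats).

    Checks are applied in the order length, ambiguity, quality, and each
    dropped read is counted under the first failed check.
    """
    from Bio import SeqIO

    if encoding not in _FASTQ_FORMATS:
        raise ValidationError(f"unknown quality encoding {encoding!r}")
    fmt = _FASTQ_FORMATS[encoding]
    fastq_path = Path(fastq_path)
    if out_path is None:
        out_path = fastq_path.with_suffix(".kept.fastq")
    out_path = Path(out_path)

    stats = QCStats()
    with open(fastq_path) as fin, open(out_path, "w") as fout:
        records = SeqIO.parse(fin, fmt)
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValidationError(
                    f"malformed FASTQ record at index {index}: {exc}"
                ) from exc
            stats.n_input += 1
            seq = str(rec.seq).upper()
            quals = rec.letter_annotations["phred_quality"]
            if len(seq) <= rule.min_length:
                stats.dropped_length += 1
            elif rule.forbid_ambiguous and not set(seq) <= _UNAMBIGUOUS:
                stats.dropped_ambiguous += 1
            elif float(np.mean(quals)) <= rule.min_avg_quality:
                stats.dropped_quality += 1
            else:
                stats.kept += 1
                SeqIO.write(rec, fout, fmt)
            index += 1
    return out_path, stats
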