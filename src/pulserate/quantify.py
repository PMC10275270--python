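"""Loading, filtering and premature/mature decomposition of intron/exon count tables.

Gene-level quantifications arrive as a long table with one exonic row per gene
and, for intron-containing genes, one intronic row.  The intronic signal is a
proxy for unprocessed (premature) transcripts; the exonic signal covers the
whole transcript pool, so mature RNA is obtained by subtraction.  Libraries are
described by a sidecar metadata table mapping each library column to its
fraction (``total`` or ``pulldown``), condition and replicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGION_EXONIC = "exonic"
REGION_INTRONIC = "intronic"
FRACTION_TOTAL = "total"
FRACTION_PULLDOWN = "pulldown"

_META_COLUMNS = ("fraction", "condition", "replicate")


@dataclass
class CountTable:
    """Gene x library matrix of counts or TPM with per-row region tags.

    ``data`` is indexed by ``(gene_id, region)``; ``lengths`` (nucleotides,
    same index) is required for count-mode tables and used to recompute TPM.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame
    lengths: pd.Series | None = None
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.units not in ("counts", "tpm"):
            raise ValueError(f"unknown units {self.units!r}")
        if (self.data.values < 0).any():
            raise ValueError("negative values in count table")
        if self.lengths is not None and (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"nonpositive effective length for row {bad}")
        missing = set(self.data.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index.get_level_values("gene_id").unique()

    def libraries(self, fraction: str | None = None, condition: str | None = None) -> list[str]:
        meta = self.metadata.loc[list(self.data.columns)]
        if fraction is not None:
            meta = meta[meta["fraction"] == fraction]
        if condition is not None:
            meta = meta[meta["condition"] == condition]
        return list(meta.index)

    def region(self, region: str) -> pd.DataFrame:
        """Per-gene matrix for one region tag (index collapsed to gene_id)."""
        sub = self.data.xs(region, level="region")
        return sub


def load_tables(counts_path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read a count/TPM table plus its library metadata table.

    The counts file is tab-separated with columns ``gene_id``, ``region``,
    optionally ``length``, then one column per library.  Absence of the
    ``length`` column flags the table as TPM-mode; count-only operations
    (expression filtering, TPM recomputation) refuse TPM-mode tables.
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    raw = pd.read_csv(counts_path, sep="\t")
    for col in ("gene_id", "region"):
        if col not in raw.columns:
            raise ValueError(f"{counts_path}: missing required column {col!r}")
    bad_regions = set(raw["region"]) - {REGION_EXONIC, REGION_INTRONIC}
    if bad_regions:
        raise ValueError(f"{counts_path}: unknown region tags {sorted(bad_regions)}")
    dup = raw.duplicated(["gene_id", "region"])
    if dup.any():
        gene = raw.loc[dup.idxmax(), "gene_id"]
        raise ValueError(f"{counts_path}: duplicated gene/region row for {gene!r}")

    meta = pd.read_csv(metadata_path, sep="\t")
    if "library_id" not in meta.columns:
        raise ValueError(f"{metadata_path}: missing 'library_id' column")
    for col in _META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: missing {col!r} column")
    meta = meta.set_index("library_id")

    has_lengths = "length" in raw.columns
    lib_cols = [c for c in raw.columns if c not in ("gene_id", "region", "length")]
    unknown = set(lib_cols) - set(meta.index)
    if unknown:
        raise ValueError(f"{counts_path}: libraries missing from metadata: {sorted(unknown)}")

    indexed = raw.set_index(["gene_id", "region"])
    data = indexed[lib_cols].astype(float)
    lengths = indexed["length"].astype(float) if has_lengths else None
    units = "counts" if has_lengths else "tpm"
    return CountTable(data=data, metadata=meta, lengths=lengths, units=units)


def recompute_tpm(table: CountTable, exclude_ids: Iterable[str] = ()) -> CountTable:
    """Recompute per-library TPM after dropping excluded genes (rRNA, spike-ins).

    Excluded rows are removed *before* normalization so they do not contribute
    to the per-library denominator.  Each library column of the result sums to
    1e6 over the retained rows.
    """
    if table.units != "counts" or table.lengths is None:
        raise ValueError("recompute_tpm requires a count-mode table with lengths")
    exclude = set(exclude_ids)
    keep = ~table.data.index.get_level_values("gene_id").isin(exclude)
    data = table.data.loc[keep]
    lengths = table.lengths.loc[keep]
    if data.empty:
        raise ValueError("no rows left after exclusion")
    rate = data.div(lengths / 1e3, axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValueError(f"all-zero library after exclusion: {zero.index[0]!r}")
    tpm = rate.div(denom, axis=1) * 1e6
    return CountTable(data=tpm, metadata=table.metadata, lengths=lengths, units="tpm")


def filter_expressed(
    table: CountTable,
    min_count: float = 10,
    min_frac: float = 2 / 3,
    group_by: Sequence[str] = ("condition", "fraction"),
) -> set[str]:
    """Expression filter: keep genes with >= ``min_count`` exonic counts in at
    least ``min_frac`` of the libraries of at least one library group.

    Library groups default to (condition, fraction) sets; the required number
    of passing libraries per group is ``ceil(min_frac * group size)``.
    """
    if table.units != "counts":
        raise ValueError("expression filtering requires a count-mode table")
    exonic = table.region(REGION_EXONIC)
    if exonic.empty:
        raise ValueError("empty count table")
    keep: set[str] = set()
    meta = table.metadata.loc[list(table.data.columns)]
    for _, group in meta.groupby(list(group_by)):
        libs = list(group.index)
        need = math.ceil(min_frac * len(libs))
        passing = (exonic[libs] >= min_count).sum(axis=1) >= need
        keep.update(exonic.index[passing])
    return keep


@dataclass
class ExpressionProfile:
    """Per gene x library premature / mature / total abundances (TPM).

    ``total`` is the exonic signal, ``premature`` the intronic signal (zero for
    intronless genes), ``mature = max(total - premature, 0)``.  Genes whose
    mean premature signal reaches or exceeds the mean total signal in the
    total-RNA libraries are flagged ``degenerate`` and excluded from rate
    estimation downstream.
    """

    premature: pd.DataFrame
    mature: pd.DataFrame
    total: pd.DataFrame
    metadata: pd.DataFrame
    degenerate: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def gene_ids(self) -> pd.Index:
        return self.total.index

    def libraries(self, fraction: str | None = None, condition: str | None = None) -> list[str]:
        meta = self.metadata.loc[list(self.total.columns)]
        if fraction is not None:
            meta = meta[meta["fraction"] == fraction]
        if condition is not None:
            meta = meta[meta["condition"] == condition]
        return list(meta.index)

    def _stat(self, func: str, fraction, condition, ddof: int = 1) -> pd.DataFrame:
        libs = self.libraries(fraction, condition)
        if not libs:
            raise ValueError(f"no libraries for fraction={fraction} condition={condition}")
        out = {}
        for name, frame in (("premature", self.premature), ("mature", self.mature), ("total", self.total)):
            sub = frame[libs]
            out[name] = sub.mean(axis=1) if func == "mean" else sub.var(axis=1, ddof=ddof)
        return pd.DataFrame(out)

    def mean(self, fraction: str | None = None, condition: str | None = None) -> pd.DataFrame:
        return self._stat("mean", fraction, condition)

    def var(self, fraction: str | None = None, condition: str | None = None, ddof: int = 1) -> pd.DataFrame:
        return self._stat("var", fraction, condition, ddof=ddof)

    def restrict(self, gene_ids: Iterable[str]) -> "ExpressionProfile":
        idx = self.total.index.intersection(pd.Index(gene_ids))
        return ExpressionProfile(
            premature=self.premature.loc[idx],
            mature=self.mature.loc[idx],
            total=self.total.loc[idx],
            metadata=self.metadata,
            degenerate=self.degenerate.loc[idx],
        )


def split_premature_mature(table: CountTable) -> ExpressionProfile:
    """Decompose exonic/intronic signals into premature, mature and total RNA.

    Works on TPM-mode tables (the decay-rate formula operates on TPM).  Genes
    without an intronic row get premature = 0.
    """
    total = table.region(REGION_EXONIC)
    try:
        intronic = table.region(REGION_INTRONIC)
    except KeyError:
        intronic = pd.DataFrame(index=total.index[:0], columns=total.columns, dtype=float)
    premature = intronic.reindex(total.index).fillna(0.0)
    mature = (total - premature).clip(lower=0.0)

    meta = table.metadata.loc[list(total.columns)]
    total_libs = list(meta.index[meta["fraction"] == FRACTION_TOTAL])
    basis = total_libs if total_libs else list(total.columns)
    prem_mean = premature[basis].mean(axis=1)
    tot_mean = total[basis].mean(axis=1)
    degenerate = (prem_mean >= tot_mean) & (tot_mean > 0)
    degenerate |= (prem_mean > 0) & (tot_mean == 0)

    return ExpressionProfile(
        premature=premature,
        mature=mature,
        total=total,
        metadata=table.metadata,
        degenerate=degenerate,
    )


def library_unspliced_fraction(profile: ExpressionProfile) -> pd.Series:
    """Percent unspliced signal per library: 100 * sum(premature) / sum(total)."""
    if profile.total.empty:
        raise ValueError("empty expression profile")
    totals = profile.total.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"zero total signal in library {bad!r}")
    return 100.0 * profile.premature.sum(axis=0) / totals


def read_id_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored; duplicates removed (order kept)."""
    ids: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and token not in seen:
            seen.add(token)
            ids.append(token)
    if not ids:
        raise ValueError(f"empty gene list: {path}")
    return ids
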