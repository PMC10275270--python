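"""Gene-feature assignment: TF lists, cell-type specificity, H3K27me3 category.

Three binary/categorical features drive the downstream stability statistics:

* ``tf`` - membership in a transcription-factor gene list (plain id list);
* ``cts`` - cell-type specificity, from a single-cell enrichment table
  (enriched in some cell type with p < 0.05 and fold-change >= 2);
* ``me3_category`` - the combination of gene regions carrying an H3K27me3
  peak: within 1 kb of the TSS (A), over the gene body (B), within 1 kb of
  the TES (C); the ``ABC`` combination is the "extended" class used as the
  regression feature.

GTF spans are 1-based closed, BED peaks 0-based half-open; everything is
normalized to 0-based half-open internally and overlap means nonempty
intersection.  Upstream/downstream are strand-aware (upstream of a minus
strand gene lies at higher coordinates) but the +/-1 kb windows are
symmetric, so strand only selects which end is the TSS.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .quantify import read_id_list

logger = logging.getLogger(__name__)

ME3_CATEGORIES = ("none", "A", "B", "C", "AB", "AC", "BC", "ABC")


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models from GTF/GFF (via gffutils) or a minimal TSV.

    Returns a frame indexed by gene_id with chrom, strand, start, end
    (1-based, closed, outermost gene span).
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique", disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        rows = []
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("gene_id", [feat.id])[0]
            rows.append((gene_id, feat.seqid, feat.strand, feat.start, feat.end))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    else:
        df = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "chrom", "strand", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("gene model with start > end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df.set_index("gene_id")


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED3(+) peak file (0-based, half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    if (df["start"] >= df["end"]).any():
        raise ValueError("peak with start >= end")
    return df


def classify_h3k27me3(
    genes: pd.DataFrame, peaks: pd.DataFrame, window: int = 1000
) -> pd.Series:
    """Assign each gene one of the 8 H3K27me3 categories.

    A = any peak within ``window`` nt of the TSS, C = within ``window`` of the
    TES, B = any peak overlapping the gene span; the category is the exact
    combination of set flags.  Genes on chromosomes without peaks get 'none'.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int))
        )
    empty = IntervalTree()

    categories = []
    for _, row in genes.iterrows():
        tree = trees.get(row["chrom"], empty)
        start0, end0 = int(row["start"]) - 1, int(row["end"])  # to 0-based half-open
        if row["strand"] == "+":
            tss0, tes0 = start0, end0 - 1
        else:
            tss0, tes0 = end0 - 1, start0
        a = bool(tree.overlap(tss0 - window, tss0 + window + 1))
        b = bool(tree.overlap(start0, end0))
        c = bool(tree.overlap(tes0 - window, tes0 + window + 1))
        cat = "".join(letter for letter, flag in zip("ABC", (a, b, c)) if flag)
        categories.append(cat or "none")
    return pd.Series(categories, index=genes.index, name="me3_category")


def classify_cts(
    enrichment: pd.DataFrame,
    p_max: float = 0.05,
    min_fc: float = 2.0,
    universe: Iterable[str] | None = None,
) -> tuple[pd.Series, dict[str, set[str]]]:
    """Cell-type-specific flags from a gene x cell-type enrichment table.

    A gene is CTS iff some cell type has p < ``p_max`` and fold-change >=
    ``min_fc`` (linear scale).  Also returns the per-cell-type enriched gene
    sets for composition analyses.
    """
    required = {"gene_id", "cell_type", "fold_change", "p_value"}
    missing = required - set(enrichment.columns)
    if missing:
        raise ValueError(f"enrichment table missing columns {sorted(missing)}")
    hits = enrichment[(enrichment["p_value"] < p_max) & (enrichment["fold_change"] >= min_fc)]
    per_cell_type = {
        ct: set(sub["gene_id"]) for ct, sub in hits.groupby("cell_type")
    }
    if universe is None:
        index = pd.Index(sorted(set(enrichment["gene_id"])), name="gene_id")
    else:
        index = pd.Index(universe, name="gene_id")
    cts_genes = set(hits["gene_id"])
    flags = pd.Series(index.isin(cts_genes), index=index, name="cts")
    return flags, per_cell_type


def load_gene_lists(
    paths: Mapping[str, str | Path], universe: Iterable[str]
) -> pd.DataFrame:
    """Boolean membership flags for named id-list files.

    Ids absent from the universe (e.g. not expressed / no rate estimate) are
    logged and dropped.
    """
    index = pd.Index(universe, name="gene_id")
    flags = {}
    for name, path in paths.items():
        ids = read_id_list(path)
        missing = [g for g in ids if g not in index]
        if missing:
            logger.info(
                "gene list %s: %d of %d ids not in universe (e.g. %s)",
                name, len(missing), len(ids), missing[:3],
            )
        flags[name] = index.isin(ids)
    return pd.DataFrame(flags, index=index)


def nonoverlapping_groups(flags: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Partition genes into the 8 (TF, me3, CTS) combinations.

    ``flags`` must have boolean columns tf, me3, cts.  Returns per-gene group
    labels '(t,m,c)' and group sizes over all 8 combinations (including empty
    ones); sizes sum to the number of genes.
    """
    for col in ("tf", "me3", "cts"):
        if col not in flags.columns:
            raise ValueError(f"flags table missing column {col!r}")
    labels = flags.apply(
        lambda row: f"({int(row['tf'])},{int(row['me3'])},{int(row['cts'])})", axis=1
    )
    all_labels = [f"({t},{m},{c})" for t, m, c in itertools.product((0, 1), repeat=3)]
    sizes = labels.value_counts().reindex(all_labels, fill_value=0)
    return labels, sizes


def build_annotation(
    universe: Iterable[str],
    tf_ids: Iterable[str] | None = None,
    enrichment: pd.DataFrame | None = None,
    gene_models: pd.DataFrame | None = None,
    peaks: pd.DataFrame | None = None,
    extra_lists: Mapping[str, str | Path] | None = None,
    me3_window: int = 1000,
    cts_p_max: float = 0.05,
    cts_min_fc: float = 2.0,
) -> pd.DataFrame:
    """Combine all feature sources into one annotation frame over ``universe``."""
    index = pd.Index(universe, name="gene_id")
    out = pd.DataFrame(index=index)
    if tf_ids is not None:
        tf_ids = set(tf_ids)
        out["tf"] = index.isin(tf_ids)
    if enrichment is not None:
        cts, _ = classify_cts(enrichment, cts_p_max, cts_min_fc, universe=index)
        out["cts"] = cts
    if gene_models is not None and peaks is not None:
        models = gene_models.loc[gene_models.index.intersection(index)]
        cat = classify_h3k27me3(models, peaks, window=me3_window)
        out["me3_category"] = cat.reindex(index).fillna("none")
        out["me3"] = out["me3_category"] == "ABC"
    if extra_lists:
        out = out.join(load_gene_lists(extra_lists, index))
    return out
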