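"""Nascent vs total RNA response to a perturbation (derepression analysis).

If a knockdown acts purely transcriptionally, total RNA fold-changes mirror
nascent fold-changes and the per-gene ratio shift

    delta = log2(total_kd / total_ctrl) - log2(nascent_kd / nascent_ctrl)

is zero; a positive shift for a target set is the signature of an RNA
stability increase on top of transcriptional derepression.  The shift is
invariant to any gene-independent scaling of the four libraries, so the
normalization of the inputs cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .stats import _mannwhitney

COLUMNS = ("nascent_ctrl", "nascent_kd", "total_ctrl", "total_kd")


@dataclass
class DerepressionResult:
    delta: pd.Series
    n_targets: int
    n_background: int
    median_target: float
    median_background: float
    U: float
    p: float


def ratio_shift(
    table: pd.DataFrame,
    targets: Iterable[str],
    pseudocount: float | None = None,
) -> DerepressionResult:
    """Per-gene total-vs-nascent ratio shift plus a target-vs-background test.

    ``table`` holds per-gene normalized abundances in the four libraries;
    the pseudocount defaults to the minimum positive value across all four
    columns and is added before the log2 ratios.  Because per-library
    normalization shifts every gene's raw ratio by the same constant, the
    returned shifts are centred so the background (non-target) median is
    zero; a positive target median then reads directly as a stability
    increase relative to the rest of the genome.  The group test is a
    two-sided Mann-Whitney U of the target genes' shifts against all others.
    """
    missing = set(COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if len(table) < 2:
        raise ValueError("need at least 2 genes")
    if (table[list(COLUMNS)] < 0).any().any():
        raise ValueError("abundances must be nonnegative")

    targets = set(targets) & set(table.index)
    if not targets:
        raise ValueError("no target genes present in the table")

    if pseudocount is None:
        vals = table[list(COLUMNS)].to_numpy(float)
        positive = vals[vals > 0]
        if positive.size == 0:
            raise ValueError("no positive abundances")
        pseudocount = float(positive.min())

    t = table[list(COLUMNS)] + pseudocount
    delta = (
        np.log2(t["total_kd"] / t["total_ctrl"])
        - np.log2(t["nascent_kd"] / t["nascent_ctrl"])
    ).rename("delta")

    is_target = delta.index.isin(targets)
    # library normalization only identifies the shift up to a constant, so
    # anchor the background (non-target) median at zero
    delta = delta - float(np.median(delta[~is_target]))
    x = delta[is_target].to_numpy(float)
    y = delta[~is_target].to_numpy(float)
    if y.size == 0:
        raise ValueError("target set covers the whole universe")
    u, p = _mannwhitney(x, y)
    return DerepressionResult(
        delta=delta,
        n_targets=int(is_target.sum()),
        n_background=int((~is_target).sum()),
        median_target=float(np.median(x)),
        median_background=float(np.median(y)),
        U=u,
        p=p,
    )
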