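"""Steady-state kinetic rate estimation from paired pull-down / total libraries.

Single-timepoint design: synthesis rates come directly from the labeled
(pull-down) signal accumulated over the pulse, decay rates from the printed
steady-state identity

    decay rate = synthesis rate / (total RNA - pre-mRNA)

and processing rates from ``synthesis / pre-mRNA``.  Pull-down and total
libraries are each internally TPM-normalized, so a scale factor ``s`` is
needed to express labeled abundances in total-library TPM units; it is
estimated from thiolated spike-ins present at known amounts in both library
types (with fixed-factor and median-half-life-anchor fallbacks).

Purification specificity bounds the longest resolvable half-life: with an
unlabeled:labeled carryover ratio ``r`` and pulse length ``t``, apparent decay
can never fall below ``r/t``, i.e. measured half-lives saturate at
``ln2 * t / r`` (1386 min for r = 1:100 and t = 20 min); half-lives are
therefore capped (default 1000 min) for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import (
    CountTable,
    ExpressionProfile,
    FRACTION_PULLDOWN,
    FRACTION_TOTAL,
    recompute_tpm,
    filter_expressed,
    split_premature_mature,
)

LN2 = float(np.log(2.0))


@dataclass
class ScalePolicy:
    """How to convert pull-down TPM into total-library TPM units.

    mode 'spike_in' uses thiolated spike-ins (default); 'fixed_factor' uses
    ``value`` directly; 'median_half_life_anchor' picks the factor that makes
    the post-hoc median half-life equal ``value`` minutes.
    """

    mode: str = "spike_in"
    value: float | None = None

    def validate(self) -> None:
        if self.mode not in ("spike_in", "fixed_factor", "median_half_life_anchor"):
            raise ValueError(f"unknown scale mode {self.mode!r}")
        if self.mode != "spike_in" and (self.value is None or self.value <= 0):
            raise ValueError(f"scale mode {self.mode!r} needs a positive value")


def _relative_signal(table: CountTable, exclude_ids: set[str]) -> pd.DataFrame:
    """Length-normalized signal relative to the analysis denominator.

    Spike rows are normalized against the sum over *non-excluded* rows so the
    result is on the same scale as TPM recomputed after exclusion (up to 1e6).
    """
    rate = table.data.div(table.lengths / 1e3, axis=0)
    keep = ~rate.index.get_level_values("gene_id").isin(exclude_ids)
    denom = rate.loc[keep].sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("library with zero analysis signal")
    return rate.div(denom, axis=1)


def estimate_scale(
    counts: CountTable,
    spike_ins: pd.DataFrame | None,
    policy: ScalePolicy = ScalePolicy(),
    exclude_ids: Iterable[str] = (),
    t_label: float | None = None,
) -> float:
    """Estimate the pull-down -> total TPM scale factor ``s``."""
    policy.validate()
    if policy.mode == "fixed_factor":
        return float(policy.value)

    if policy.mode == "median_half_life_anchor":
        if t_label is None or t_label <= 0:
            raise ValueError("anchor mode needs t_label")
        spike_ids = set() if spike_ins is None else set(spike_ins.index)
        tpm = recompute_tpm(counts, set(exclude_ids) | spike_ids)
        profile = split_premature_mature(tpm)
        alpha1, _ = estimate_synthesis(
            profile.mean(fraction=FRACTION_PULLDOWN)["total"], t_label, 1.0
        )
        tot = profile.mean(fraction=FRACTION_TOTAL)
        decay1 = estimate_decay(alpha1, tot["total"], tot["premature"])
        m1 = float(decay1["half_life"].median())
        return m1 / float(policy.value)

    if spike_ins is None or spike_ins.empty:
        raise ValueError("spike_in scale mode requires a spike-in table")
    if counts.units != "counts" or counts.lengths is None:
        raise ValueError("spike_in scale mode requires a count-mode table")
    spike_ids = set(spike_ins.index)
    rel = _relative_signal(counts, set(exclude_ids) | spike_ids)
    present = [s for s in spike_ins.index if (s, "exonic") in rel.index]
    if not present:
        raise ValueError("no spike-in rows found in the count table")
    rel_spikes = rel.loc[[(s, "exonic") for s in present]]
    rel_spikes.index = present

    tot_libs = counts.libraries(fraction=FRACTION_TOTAL)
    pd_libs = counts.libraries(fraction=FRACTION_PULLDOWN)
    if not tot_libs or not pd_libs:
        raise ValueError("need both total and pulldown libraries")
    per_total = rel_spikes[tot_libs].mean(axis=1) / spike_ins.loc[present, "amount_total"]
    per_pull = rel_spikes[pd_libs].mean(axis=1) / spike_ins.loc[present, "amount_pulldown"]
    ratios = per_total / per_pull
    ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
    if ratios.empty:
        raise ValueError("no usable spike-in signal")
    return float(ratios.median())


def estimate_synthesis(
    pulldown_exonic: pd.Series,
    t_label: float,
    s: float,
    mode: str = "linear",
    total: pd.Series | None = None,
    premature: pd.Series | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[pd.Series, pd.Series]:
    """Per-gene synthesis rate (TPM/min) from mean pull-down exonic TPM.

    linear mode: ``alpha = s * labeled / t`` (short-pulse approximation; a
    slight underestimate because labeled RNA already decays during the pulse).
    exact mode inverts the closed-form labeled-pool solution by fixed-point
    iteration, using the linear estimate as initializer and the total-library
    total/premature TPM to tie processing and decay rates to alpha.

    Returns ``(alpha, converged)``; nonconverged genes are flagged False and
    keep their last iterate.
    """
    if t_label <= 0:
        raise ValueError("t_label must be positive")
    if s <= 0:
        raise ValueError("scale factor must be positive")
    labeled = s * pulldown_exonic
    alpha_lin = labeled / t_label
    converged = pd.Series(True, index=pulldown_exonic.index)
    if mode == "linear":
        return alpha_lin, converged
    if mode != "exact":
        raise ValueError(f"unknown synthesis mode {mode!r}")
    if total is None or premature is None:
        raise ValueError("exact mode needs total and premature TPM")

    from .simulate import _labeled_fractions  # closed-form pulse solution

    prem = premature.reindex(labeled.index).to_numpy(float)
    mat = (total.reindex(labeled.index) - premature.reindex(labeled.index)).to_numpy(float)
    L = labeled.to_numpy(float)
    alpha = alpha_lin.to_numpy(float).copy()
    ok = (mat > 0) & (L > 0)
    done = ~ok
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(max_iter):
            k_p = np.where(prem > 0, alpha / prem, np.inf)
            k_d = alpha / mat
            frac_p, frac_m = _labeled_fractions(k_p, k_d, t_label)
            predicted = prem * frac_p + mat * frac_m
            update = np.where(ok & (predicted > 0), L / predicted, 1.0)
            alpha_new = alpha * update
            done |= np.abs(alpha_new - alpha) <= tol * np.abs(alpha)
            alpha = alpha_new
            if done.all():
                break
    conv = pd.Series(done | ~ok, index=pulldown_exonic.index)
    out = pd.Series(np.where(ok, alpha, np.nan), index=pulldown_exonic.index)
    out[~ok] = np.where(L[~ok] == 0, 0.0, np.nan)
    return out, conv


def estimate_decay(synthesis: pd.Series, total: pd.Series, premature: pd.Series) -> pd.DataFrame:
    """decay = synthesis / (total - premature); half_life = ln2 / decay.

    Genes with total <= premature are flagged and get no rate.
    """
    mature = total - premature
    valid = mature > 0
    decay = pd.Series(np.where(valid, synthesis / mature.where(valid), np.nan), index=total.index)
    decay[decay <= 0] = np.nan
    return pd.DataFrame(
        {"decay": decay, "half_life": LN2 / decay, "degenerate": ~valid}
    )


def estimate_processing(synthesis: pd.Series, premature: pd.Series) -> pd.Series:
    """processing = synthesis / premature; missing for intronless genes."""
    valid = premature > 0
    return pd.Series(
        np.where(valid, synthesis / premature.where(valid), np.nan),
        index=premature.index,
        name="processing",
    )


def cap_from_specificity(ratio: float, t_label: float) -> float:
    """Longest resolvable half-life (min) given pull-down specificity.

    Short-pulse argument: carryover at ratio ``r`` mimics a labeled fraction
    of r per pulse, i.e. an apparent decay rate r / t, so
    ``t_half_max = ln2 * t / r`` (1386.29 min at r=0.01, t=20).
    """
    if ratio <= 0 or ratio > 1:
        raise ValueError("specificity ratio must lie in (0, 1]")
    if t_label <= 0:
        raise ValueError("t_label must be positive")
    return LN2 * t_label / ratio


def apply_cap(rates: pd.DataFrame, cap: float = 1000.0) -> pd.DataFrame:
    """Cap reported half-lives; decay rates themselves are left untouched."""
    out = rates.copy()
    capped = out["half_life"] > cap
    out["half_life"] = out["half_life"].where(~capped, cap)
    out["capped"] = capped.fillna(False)
    return out


def propagate_cv(
    var_synthesis: pd.Series,
    var_total: pd.Series,
    var_premature: pd.Series,
    synthesis: pd.Series,
    total: pd.Series,
    premature: pd.Series,
) -> pd.DataFrame:
    """Delta-method CVs for synthesis, total level and decay rate.

    Assuming independent errors in synthesis and in the (total - premature)
    denominator:  cv_decay^2 = cv_alpha^2 + (var_total + var_premature) /
    (total - premature)^2.
    """
    for v in (var_synthesis, var_total, var_premature):
        if (v < 0).any():
            raise ValueError("negative variance")
    cv_syn = np.sqrt(var_synthesis) / synthesis
    cv_tot = np.sqrt(var_total) / total
    mature = total - premature
    denom = mature.where(mature > 0)
    cv_dec = np.sqrt(cv_syn**2 + (var_total + var_premature) / denom**2)
    return pd.DataFrame({"cv_synthesis": cv_syn, "cv_total": cv_tot, "cv_decay": cv_dec})


def deg_proc_ratio(profile: ExpressionProfile, fraction: str = FRACTION_TOTAL) -> pd.Series:
    """Premature/mature ratio in total RNA, a proxy for decay/processing."""
    m = profile.mean(fraction=fraction)
    # undefined without both pools: intronless genes have no premature signal
    valid = (m["mature"] > 0) & (m["premature"] > 0)
    return pd.Series(
        np.where(valid, m["premature"] / m["mature"].where(valid), np.nan),
        index=m.index,
        name="deg_proc_ratio",
    )


def steady_state_check(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    fraction: str = FRACTION_TOTAL,
) -> float:
    """r^2 of log10 total-RNA levels between two profiles (steady-state test).

    Pseudocount = minimum positive mean TPM across both inputs, added before
    the log transform.
    """
    a = profile_a.mean(fraction=fraction)["total"]
    b = profile_b.mean(fraction=fraction)["total"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    a, b = a.loc[shared], b.loc[shared]
    pooled = pd.concat([a, b])
    positive = pooled[pooled > 0]
    if positive.empty:
        raise ValueError("no positive values")
    pseudo = float(positive.min())
    r, _ = sps.pearsonr(np.log10(a + pseudo), np.log10(b + pseudo))
    return float(r**2)


def estimate_rates(
    counts: CountTable,
    spike_ins: pd.DataFrame | None = None,
    *,
    t_label: float = 20.0,
    scale_policy: ScalePolicy = None,
    synthesis_mode: str = "linear",
    cap: float = 1000.0,
    exclude_ids: Iterable[str] = (),
    min_count: float = 10,
    min_frac: float = 2 / 3,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Full rate-estimation stage on a count table.

    Applies the expression filter, recomputes TPM without spike-ins/excluded
    ids, splits premature/mature, estimates the library scale and per-gene
    synthesis/processing/decay rates with delta-method CVs, and caps reported
    half-lives.  Degenerate genes (premature >= total) are excluded from the
    output.  Returns ``(rates_table, info)`` where ``info`` carries the TPM
    table, profile, and scale factor for downstream stages.
    """
    if scale_policy is None:
        scale_policy = ScalePolicy()
    spike_ids = set() if spike_ins is None else set(spike_ins.index)
    exclude = set(exclude_ids) | spike_ids

    keep: set[str] | None = None
    if apply_filter and counts.units == "counts":
        keep = filter_expressed(counts, min_count=min_count, min_frac=min_frac)

    tpm = recompute_tpm(counts, exclude) if counts.units == "counts" else counts
    profile = split_premature_mature(tpm)
    if keep is not None:
        profile = profile.restrict(keep)

    s = estimate_scale(counts, spike_ins, scale_policy, exclude_ids=set(exclude_ids), t_label=t_label)

    tot_mean = profile.mean(fraction=FRACTION_TOTAL)
    pd_mean = profile.mean(fraction=FRACTION_PULLDOWN)
    alpha, converged = estimate_synthesis(
        pd_mean["total"],
        t_label,
        s,
        mode=synthesis_mode,
        total=tot_mean["total"],
        premature=tot_mean["premature"],
    )
    decay = estimate_decay(alpha, tot_mean["total"], tot_mean["premature"])
    processing = estimate_processing(alpha, tot_mean["premature"])

    n_tot = len(profile.libraries(fraction=FRACTION_TOTAL))
    n_pd = len(profile.libraries(fraction=FRACTION_PULLDOWN))
    if n_tot > 1 and n_pd > 1:
        tot_var = profile.var(fraction=FRACTION_TOTAL)
        pd_var = profile.var(fraction=FRACTION_PULLDOWN)
        var_alpha = pd_var["total"] * (s / t_label) ** 2
        cvs = propagate_cv(
            var_alpha, tot_var["total"], tot_var["premature"],
            alpha, tot_mean["total"], tot_mean["premature"],
        )
    else:
        cvs = pd.DataFrame(
            np.nan, index=alpha.index, columns=["cv_synthesis", "cv_total", "cv_decay"]
        )

    rates = pd.DataFrame(
        {
            "synthesis": alpha,
            "processing": processing,
            "decay": decay["decay"],
            "half_life": decay["half_life"],
            "converged": converged,
        }
    ).join(cvs)
    bad = profile.degenerate | decay["degenerate"] | rates["decay"].isna()
    rates = rates.loc[~bad].copy()
    rates = apply_cap(rates, cap=cap)
    rates.index.name = "gene_id"

    info = {"scale": s, "tpm": tpm, "profile": profile, "n_filtered_out": None}
    if keep is not None:
        info["n_filtered_out"] = len(set(map(str, counts.gene_ids)) - keep - exclude)
    return rates, info
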