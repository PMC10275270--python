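"""End-to-end orchestration: quantify -> rates -> annotate -> stats (-> derepression).

``RunConfig`` collects every input path and tunable parameter; defaults match
the analysis settings of the labeling experiment this pipeline reproduces
(20-min pulse, 1:100 specificity -> 1000-min cap, 10-count/2-3 expression
filter, CTS thresholds p<0.05 & fold-change>=2, 1-kb me3 windows, 1%
winsorizing, 10,000 stratified bootstrap iterations at the minimum group
size).  Every stage output is written to the run directory and a JSON summary
collects the headline numbers; with a fixed seed a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, derepression, quantify, rates, stats

logger = logging.getLogger("pulserate")


@dataclass
class RunConfig:
    counts: str = ""
    libraries: str = ""
    spike_ins: str | None = None
    gene_models: str | None = None
    peaks: str | None = None
    tf_list: str | None = None
    enrichment: str | None = None
    gene_lists: dict = field(default_factory=dict)
    derepression_table: str | None = None
    derepression_targets: str | None = None
    outdir: str = "run"

    t_label: float = 20.0
    specificity_ratio: float = 0.01
    cap: float = 1000.0
    min_count: float = 10
    min_frac: float = 2 / 3
    cts_p_max: float = 0.05
    cts_min_fc: float = 2.0
    me3_window: int = 1000
    winsor_tail: float = 0.01
    bootstrap_n_iter: int = 10000
    per_group_n: int | str = "min"
    scale_mode: str = "spike_in"
    scale_value: float | None = None
    synthesis_mode: str = "linear"
    exclude_ids: list = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for name in ("counts", "libraries"):
            path = getattr(self, name)
            if not path:
                raise ValueError(f"config field {name!r} is required")
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        optional = [
            ("spike_ins", self.spike_ins),
            ("gene_models", self.gene_models),
            ("peaks", self.peaks),
            ("tf_list", self.tf_list),
            ("enrichment", self.enrichment),
            ("derepression_table", self.derepression_table),
            ("derepression_targets", self.derepression_targets),
        ] + [(f"gene_lists[{k}]", v) for k, v in self.gene_lists.items()]
        for name, path in optional:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if self.scale_mode != "spike_in" and self.scale_value is None:
            raise ValueError("scale_value required for non-spike-in scale modes")
        if self.scale_mode == "spike_in" and self.spike_ins is None:
            raise ValueError("spike_in scale mode requires a spike_ins table")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns (and writes) the summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        summary = _run_stages(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return summary


def _run_stages(config: RunConfig, outdir: Path) -> dict:
    logger.info("config: %s", config.to_dict())
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # --- quantify + rates -------------------------------------------------
    counts = quantify.load_tables(config.counts, config.libraries)
    spikes = None
    if config.spike_ins:
        spikes = pd.read_csv(config.spike_ins, sep="\t").set_index("spike_id")
    policy = rates.ScalePolicy(mode=config.scale_mode, value=config.scale_value)
    rate_table, info = rates.estimate_rates(
        counts,
        spikes,
        t_label=config.t_label,
        scale_policy=policy,
        synthesis_mode=config.synthesis_mode,
        cap=config.cap,
        exclude_ids=config.exclude_ids,
        min_count=config.min_count,
        min_frac=config.min_frac,
    )
    logger.info("estimated rates for %d genes (scale=%.6g)", len(rate_table), info["scale"])
    _write(rate_table, outdir / "rates.tsv")

    unspliced = quantify.library_unspliced_fraction(info["profile"])
    unspliced.rename("percent_unspliced").to_frame().to_csv(outdir / "unspliced.tsv", sep="\t")

    frac_meta = info["profile"].metadata
    summary: dict = {
        "n_genes_with_rates": len(rate_table),
        "scale_factor": info["scale"],
        "median_half_life_min": float(rate_table["half_life"].median()),
        "sigma_log10_synthesis": float(np.log10(rate_table["synthesis"][rate_table["synthesis"] > 0]).std(ddof=1)),
        "sigma_log10_decay": float(np.log10(rate_table["decay"]).std(ddof=1)),
        "frac_half_life_capped": float(rate_table["capped"].mean()),
        "max_resolvable_half_life_min": rates.cap_from_specificity(
            config.specificity_ratio, config.t_label
        ),
        "percent_unspliced": {
            frac: float(unspliced[[l for l in unspliced.index if frac_meta.loc[l, "fraction"] == frac]].mean())
            for frac in ("total", "pulldown")
        },
    }

    # --- annotation -------------------------------------------------------
    universe = rate_table.index
    tf_ids = quantify.read_id_list(config.tf_list) if config.tf_list else None
    enrichment = pd.read_csv(config.enrichment, sep="\t") if config.enrichment else None
    models = annotate.read_gene_models(config.gene_models) if config.gene_models else None
    peaks = annotate.read_peaks(config.peaks) if config.peaks else None
    annotation = annotate.build_annotation(
        universe,
        tf_ids=tf_ids,
        enrichment=enrichment,
        gene_models=models,
        peaks=peaks,
        extra_lists=config.gene_lists,
        me3_window=config.me3_window,
        cts_p_max=config.cts_p_max,
        cts_min_fc=config.cts_min_fc,
    )
    _write(annotation, outdir / "annotation.tsv")

    # --- stability statistics --------------------------------------------
    percentiles = stats.stability_percentile(rate_table["decay"])
    _write(percentiles.to_frame(), outdir / "stability_percentiles.tsv")

    group_rows = []
    for name in ("tf", "me3", "cts"):
        if name not in annotation.columns:
            continue
        group = set(annotation.index[annotation[name]])
        if not group or len(group) == len(universe):
            continue
        test = stats.group_stability_test(rate_table["decay"], percentiles, group)
        group_rows.append({"group": name, **test})
        summary[f"{name}_median_stability_percentile"] = test["median_percentile"]
    if group_rows:
        pd.DataFrame(group_rows).to_csv(outdir / "group_tests.tsv", sep="\t", index=False)

    have_all = {"tf", "me3", "cts"} <= set(annotation.columns)
    if have_all:
        flags = annotation[["tf", "me3", "cts"]]
        labels, sizes = annotate.nonoverlapping_groups(flags)
        summary["group_sizes"] = sizes.to_dict()
        if (sizes > 0).all():
            y = stats.winsorize_log(rate_table["decay"], tail=config.winsor_tail)
            fits = {}
            for interactions in (False, True):
                fit = stats.fit_linear_model(y, flags, interactions=interactions)
                fits[fit.model] = fit
            boot = stats.bootstrap_model(
                y, flags,
                n_iter=config.bootstrap_n_iter,
                per_group_n=config.per_group_n,
                seed=config.seed,
            )
            reg_rows = []
            for model, fit in fits.items():
                for name, term in zip(fit.params.index, fit.terms):
                    reg_rows.append(
                        {
                            "model": model,
                            "coefficient": name,
                            "term": term,
                            "estimate": fit.params[name],
                            "p": fit.pvalues[name],
                        }
                    )
            pd.DataFrame(reg_rows).to_csv(outdir / "regression.tsv", sep="\t", index=False)
            boot.summary().to_csv(outdir / "bootstrap.tsv", sep="\t", index=False)
            changes = stats.group_mean_changes(y, flags)
            changes.to_csv(outdir / "mean_changes.tsv", sep="\t", index=False)
            summary["regression"] = {
                model: {
                    "coefficients": fit.params.to_dict(),
                    "p_values": fit.pvalues.to_dict(),
                }
                for model, fit in fits.items()
            }
            summary["bootstrap_per_group_n"] = boot.per_group_n
            summary["bootstrap_frac_positive"] = boot.frac_positive("additive").to_dict()
        else:
            logger.warning("empty feature groups %s; regression skipped",
                           list(sizes.index[sizes == 0]))

    # --- derepression ------------------------------------------------------
    if config.derepression_table and config.derepression_targets:
        table = pd.read_csv(config.derepression_table, sep="\t").set_index("gene_id")
        targets = quantify.read_id_list(config.derepression_targets)
        result = derepression.ratio_shift(table, targets)
        result.delta.to_frame().to_csv(outdir / "derepression_delta.tsv", sep="\t")
        summary["derepression"] = {
            "median_target_delta": result.median_target,
            "median_background_delta": result.median_background,
            "p": result.p,
        }

    summary = _jsonable(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run complete: %s", outdir / "summary.json")
    return summary
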