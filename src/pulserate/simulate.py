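"""Forward simulation of 4sU pulse-labeling RNA-seq experiments.

The generator emulates the statistical structure the steady-state estimator
assumes: per-gene first-order kinetics (synthesis ``alpha`` in TPM/min,
processing ``k_p`` and decay ``k_d`` in 1/min) at steady state, a short
labeling pulse that fills labeled premature/mature pools according to the
closed-form solution of

    dP/dt = alpha - k_p * P        dM/dt = k_p * P - k_d * M,

a streptavidin pull-down with a configurable carryover of unlabeled RNA
(default 1:100), thiolated spike-ins at known amounts, and negative-binomial
sequencing noise over replicate libraries.  Every draw is determined by the
config seed, and the true kinetic parameters are retained so downstream
estimators have a parameter-recovery test surface.

Rate distributions are log-normal on the log10 scale; defaults reproduce the
calibration of the larval-brain experiment this pipeline targets (median RNA
half-life 82 min, sigma_log10 = 0.79 for synthesis and 0.44 for decay, 20-min
pulse).  Binary gene features (TF / extended-H3K27me3 / cell-type-specific)
can be planted with additive log10 effects on decay so the regression and
bootstrap stages can be validated against known effect sizes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import quantify
from .quantify import CountTable, FRACTION_PULLDOWN, FRACTION_TOTAL

LN2 = float(np.log(2.0))

_CHROMS = ("chr2L", "chr2R", "chr3L", "chr3R", "chrX")
_CELL_TYPES = (
    "neuroblast",
    "immature_neuron",
    "cholinergic_neuron",
    "glutamatergic_neuron",
    "gabaergic_neuron",
    "glia",
    "hemocyte",
    "neuroepithelium",
)
# categories other than the planted extended (ABC) class, with sampling weights
_ME3_CATEGORIES = ("none", "A", "B", "C", "AB", "BC", "AC")
_ME3_WEIGHTS = (0.82, 0.05, 0.05, 0.03, 0.02, 0.02, 0.01)


@dataclass(frozen=True)
class SpikeIn:
    """A thiolated spike-in with known abundance in each library type."""

    spike_id: str
    amount_total: float
    amount_pulldown: float
    length: float = 1000.0


def default_spike_ins() -> tuple[SpikeIn, ...]:
    # ten thiolated spike-ins mixed at equal final concentrations
    return tuple(SpikeIn(f"SPIKE_{i:02d}", 500.0, 120.0) for i in range(1, 11))


@dataclass
class SimulationConfig:
    """All generator parameters; the seed fully determines the output."""

    n_genes: int = 5000
    median_half_life: float = 82.0          # minutes
    sigma_log10_synthesis: float = 0.79
    sigma_log10_decay: float = 0.44
    median_synthesis: float = 0.5           # TPM/min, before TPM renormalization
    processing_rate_law: dict = field(
        default_factory=lambda: {"dist": "log10normal", "median_ratio": 10.0, "sigma": 0.25}
    )
    t_label: float = 20.0                   # minutes
    contamination_frac: float = 0.01        # unlabeled carryover in the pull-down
    labeling_efficiency: float = 1.0
    n_replicates: int = 3
    nb_dispersion: float = 0.05             # var = mu * (1 + phi * mu); 0 = noise-free
    library_depth: float = 1.0e8            # reads per library
    intronless_frac: float = 0.15
    feature_prevalence: dict = field(default_factory=lambda: {"tf": 0.15, "me3": 0.06, "cts": 0.25})
    feature_effects: dict = field(default_factory=lambda: {"tf": 0.25, "me3": 0.30, "cts": -0.05})
    spike_ins: tuple[SpikeIn, ...] = field(default_factory=default_spike_ins)
    condition: str = "ctrl"
    normalize_to_tpm: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.median_half_life <= 0 or self.median_synthesis <= 0:
            raise ValueError("medians must be positive")
        if self.sigma_log10_synthesis < 0 or self.sigma_log10_decay < 0:
            raise ValueError("sigma values must be nonnegative")
        if self.t_label <= 0:
            raise ValueError("t_label must be positive")
        if not (0 <= self.contamination_frac < 1):
            raise ValueError("contamination_frac must lie in [0, 1)")
        if not (0 < self.labeling_efficiency <= 1):
            raise ValueError("labeling_efficiency must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not (0 <= self.intronless_frac < 1):
            raise ValueError("intronless_frac must lie in [0, 1)")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def sample_features(config: SimulationConfig) -> pd.DataFrame:
    """Draw binary gene features (tf, me3, cts) and intron status."""
    config.validate()
    rng = _rng(config, 1)
    n = config.n_genes
    prev = config.feature_prevalence
    df = pd.DataFrame(index=pd.Index(_gene_ids(n), name="gene_id"))
    for name in ("tf", "me3", "cts"):
        df[name] = rng.random(n) < float(prev.get(name, 0.0))
    df["has_introns"] = rng.random(n) >= config.intronless_frac
    return df


def sample_kinetic_params(
    config: SimulationConfig, features: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Draw per-gene synthesis, processing and decay rates.

    log10 rates are normal; after adding any planted feature effects on decay,
    each log10 vector is recentred so the sample median equals the configured
    median exactly (median half-life = ``median_half_life``, median synthesis
    = ``median_synthesis``).  Intronless genes (per ``features``) get
    ``k_p = inf``: processing is effectively instantaneous and their premature
    pool is empty.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_genes
    ids = features.index.to_numpy() if features is not None else np.array(_gene_ids(n))
    if len(ids) != n:
        raise ValueError("features table does not match n_genes")

    log_alpha = np.log10(config.median_synthesis) + config.sigma_log10_synthesis * rng.standard_normal(n)
    log_alpha += np.log10(config.median_synthesis) - np.median(log_alpha)

    median_kd = LN2 / config.median_half_life
    log_kd = np.log10(median_kd) + config.sigma_log10_decay * rng.standard_normal(n)
    if features is not None:
        for name, effect in (config.feature_effects or {}).items():
            if name in features.columns and effect:
                log_kd += float(effect) * features[name].to_numpy(dtype=float)
    log_kd += np.log10(median_kd) - np.median(log_kd)

    law = config.processing_rate_law
    if law.get("dist") == "fixed":
        k_p = np.full(n, float(law["value"]))
    elif law.get("dist") == "log10normal":
        median_kp = float(law.get("median_ratio", 10.0)) * median_kd
        k_p = 10 ** (np.log10(median_kp) + float(law.get("sigma", 0.25)) * rng.standard_normal(n))
    else:
        raise ValueError(f"unknown processing_rate_law {law!r}")
    if features is not None:
        k_p = np.where(features["has_introns"].to_numpy(), k_p, np.inf)

    return pd.DataFrame(
        {"alpha": 10 ** log_alpha, "k_p": k_p, "k_d": 10 ** log_kd},
        index=pd.Index(ids, name="gene_id"),
    )


def steady_state_pools(params: pd.DataFrame) -> pd.DataFrame:
    """Steady-state premature (alpha/k_p) and mature (alpha/k_d) pools."""
    for col in ("alpha", "k_p", "k_d"):
        vals = params[col]
        if (vals <= 0).any() or vals.isna().any():
            raise ValueError(f"nonpositive or missing {col}")
    premature = params["alpha"] / params["k_p"]  # alpha/inf -> 0 for intronless
    mature = params["alpha"] / params["k_d"]
    return pd.DataFrame({"premature": premature, "mature": mature})


def _labeled_fractions(k_p: np.ndarray, k_d: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of each steady-state pool that is labeled after a pulse of t min.

    Uses the cancellation-free rearrangement

        frac_m = -expm1(-k_p t) - k_p t e^(-k_p t) phi((k_d - k_p) t),
        phi(x) = -expm1(-x)/x  (phi(0) = 1),

    with a series for phi near the removable singularity k_p == k_d and a
    direct two-exponential form when the rates are far apart (avoids overflow
    in expm1 for large negative arguments).
    """
    with np.errstate(over="ignore"):
        frac_p = -np.expm1(-k_p * t)
    frac_m = np.empty_like(np.asarray(k_d, dtype=float))
    intronless = np.isinf(k_p)
    # no premature compartment: mature labels like a single first-order pool
    frac_m[intronless] = -np.expm1(-k_d[intronless] * t)

    rest = ~intronless
    kp, kd = k_p[rest], k_d[rest]
    a, b = kp * t, kd * t
    x = b - a
    term = np.empty_like(a)
    far = np.abs(x) >= 1.0
    term[far] = kp[far] * (np.exp(-a[far]) - np.exp(-b[far])) / (kd[far] - kp[far])
    near = (~far) & (np.abs(x) >= 1e-8)
    term[near] = a[near] * np.exp(-a[near]) * (-np.expm1(-x[near]) / x[near])
    tiny = np.abs(x) < 1e-8
    xt = x[tiny]
    term[tiny] = a[tiny] * np.exp(-a[tiny]) * (1.0 - xt / 2.0 + xt * xt / 6.0)
    frac_m[rest] = np.clip(-np.expm1(-a) - term, 0.0, 1.0)
    return frac_p, frac_m


def labeled_pools(params: pd.DataFrame, t: float) -> pd.DataFrame:
    """Labeled premature/mature pools after a pulse of duration ``t`` minutes.

    Closed form of the two-compartment linear system with zero initial labeled
    pools; a series branch handles the removable singularity at k_p == k_d.
    """
    if t < 0:
        raise ValueError("labeling time must be nonnegative")
    pools = steady_state_pools(params)
    frac_p, frac_m = _labeled_fractions(
        params["k_p"].to_numpy(float), params["k_d"].to_numpy(float), float(t)
    )
    return pd.DataFrame(
        {
            "labeled_premature": pools["premature"].to_numpy() * frac_p,
            "labeled_mature": pools["mature"].to_numpy() * frac_m,
        },
        index=params.index,
    )


def sample_gene_models(config: SimulationConfig, features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay genes out on a toy genome and plant H3K27me3 peaks per category.

    Returns ``(models, peaks)``.  ``models`` holds 1-based closed spans plus
    exonic/intronic effective lengths and the planted ``me3_category``; peaks
    are 0-based half-open intervals engineered so that re-classification with
    a +/-1 kb TSS/TES window recovers the planted category exactly.  Genes are
    spaced 10 kb apart so neighboring peaks cannot leak into each other's
    windows.
    """
    rng = _rng(config, 3)
    n = config.n_genes
    exonic = np.round(10 ** (np.log10(1500.0) + 0.2 * rng.standard_normal(n))).clip(min=200)
    intronic = np.round(10 ** (np.log10(2000.0) + 0.3 * rng.standard_normal(n))).clip(min=100)
    intronic = np.where(features["has_introns"].to_numpy(), intronic, 0.0)
    span = np.maximum(exonic + intronic, 3000.0).astype(int)
    strand = np.where(rng.random(n) < 0.5, "+", "-")

    chrom = np.array([_CHROMS[i % len(_CHROMS)] for i in range(n)])
    start = np.empty(n, dtype=int)
    cursor = {c: 10_001 for c in _CHROMS}
    for i in range(n):
        start[i] = cursor[chrom[i]]
        cursor[chrom[i]] += span[i] + 10_000
    end = start + span - 1  # 1-based closed

    me3 = features["me3"].to_numpy()
    category = np.where(me3, "ABC", rng.choice(_ME3_CATEGORIES, size=n, p=_ME3_WEIGHTS))

    peaks: list[tuple[str, int, int]] = []
    for i in range(n):
        cat = category[i]
        if cat == "none":
            continue
        s0, e0 = start[i] - 1, end[i]  # 0-based half-open gene body
        if strand[i] == "+":
            tss0, tes0, sign = s0, e0 - 1, 1
        else:
            tss0, tes0, sign = e0 - 1, s0, -1

        c = chrom[i]
        if "A" in cat and "B" not in cat:
            a, b = (tss0 - 700, tss0 - 500) if sign > 0 else (tss0 + 501, tss0 + 701)
            peaks.append((c, a, b))
        if "C" in cat and "B" not in cat:
            a, b = (tes0 + 501, tes0 + 701) if sign > 0 else (tes0 - 700, tes0 - 500)
            peaks.append((c, a, b))
        if cat == "B":
            mid = (s0 + e0) // 2
            peaks.append((c, mid - 100, mid + 100))
        elif cat == "AB":
            a, b = (tss0 - 300, tss0 + 700) if sign > 0 else (tss0 - 699, tss0 + 301)
            peaks.append((c, a, b))
        elif cat == "BC":
            a, b = (tes0 - 699, tes0 + 301) if sign > 0 else (tes0 - 300, tes0 + 700)
            peaks.append((c, a, b))
        elif cat == "ABC":
            peaks.append((c, s0 - 300, e0 + 300))

    models = pd.DataFrame(
        {
            "chrom": chrom,
            "strand": strand,
            "start": start,
            "end": end,
            "exonic_length": exonic,
            "intronic_length": intronic,
            "me3_category": category,
        },
        index=features.index,
    )
    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], kind="mergesort", ignore_index=True
    )
    return models, peaks_df


def sample_enrichment(config: SimulationConfig, features: pd.DataFrame) -> pd.DataFrame:
    """Single-cell style enrichment table (gene x cell type, fold_change + p).

    CTS genes get one row passing both thresholds (p < 0.05, fold-change >= 2);
    every other row is constructed to fail at least one threshold.
    """
    rng = _rng(config, 4)
    rows = []
    cts = features["cts"].to_numpy()
    for i, gene in enumerate(features.index):
        if cts[i]:
            ct = _CELL_TYPES[rng.integers(len(_CELL_TYPES))]
            rows.append((gene, ct, 2.0 + rng.exponential(2.0), 10.0 ** -rng.uniform(2, 6)))
        for _ in range(rng.integers(1, 3)):
            ct = _CELL_TYPES[rng.integers(len(_CELL_TYPES))]
            if rng.random() < 0.2:
                # significant but weakly enriched
                rows.append((gene, ct, rng.uniform(0.3, 1.9), rng.uniform(0.001, 0.049)))
            else:
                rows.append((gene, ct, rng.lognormal(0.0, 0.5), rng.uniform(0.051, 1.0)))
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "fold_change", "p_value"])


def simulate_libraries(
    pools: pd.DataFrame,
    lengths: pd.DataFrame,
    config: SimulationConfig,
    stream: int = 5,
) -> CountTable:
    """Draw total and pull-down replicate count libraries from pool states.

    Expected pull-down signal per gene is ``efficiency * labeled +
    contamination_frac * unlabeled``; exonic signal covers premature + mature,
    intronic signal the premature pool only.  Expected counts are depth-scaled
    by fragment mass (signal x length); replicate counts are gamma-Poisson
    (negative binomial, var = mu(1 + phi mu)).  ``nb_dispersion == 0`` returns
    the real-valued expectations unrounded (noise-free mode).
    """
    config.validate()
    if config.library_depth <= 0:
        raise ValueError("library_depth must be positive")
    rng = _rng(config, stream)
    eff, c = config.labeling_efficiency, config.contamination_frac

    has_intron = lengths["intronic_length"] > 0
    gene_rows = [(g, quantify.REGION_EXONIC) for g in pools.index]
    gene_rows += [(g, quantify.REGION_INTRONIC) for g in pools.index[has_intron]]
    spike_rows = [(s.spike_id, quantify.REGION_EXONIC) for s in config.spike_ins]
    index = pd.MultiIndex.from_tuples(gene_rows + spike_rows, names=["gene_id", "region"])

    row_length = np.concatenate(
        [
            lengths["exonic_length"].to_numpy(float),
            lengths.loc[has_intron, "intronic_length"].to_numpy(float),
            np.array([s.length for s in config.spike_ins]),
        ]
    )

    P = pools["premature"].to_numpy(float)
    M = pools["mature"].to_numpy(float)
    LP = pools["labeled_premature"].to_numpy(float)
    LM = pools["labeled_mature"].to_numpy(float)
    mask = has_intron.to_numpy()

    sig_total = np.concatenate([P + M, P[mask], np.array([s.amount_total for s in config.spike_ins])])
    sig_pull = np.concatenate(
        [
            eff * (LP + LM) + c * (P + M),
            eff * LP[mask] + c * P[mask],
            np.array([s.amount_pulldown for s in config.spike_ins]),
        ]
    )

    libs, meta_rows, columns = [], [], {}
    for fraction, sig in ((FRACTION_TOTAL, sig_total), (FRACTION_PULLDOWN, sig_pull)):
        w = sig * row_length / 1e3
        mu = config.library_depth * w / w.sum()
        for rep in range(1, config.n_replicates + 1):
            lib = f"{config.condition}_{fraction}_rep{rep}"
            libs.append(lib)
            meta_rows.append((lib, fraction, config.condition, rep))
            if config.nb_dispersion == 0:
                columns[lib] = mu.copy()
            else:
                # genes: gamma-Poisson (biological + technical variability);
                # spike-ins are technical standards from a common stock, so
                # they carry Poisson counting noise only
                lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * mu)
                n_spikes = len(config.spike_ins)
                if n_spikes:
                    lam[-n_spikes:] = mu[-n_spikes:]
                columns[lib] = rng.poisson(lam).astype(float)

    data = pd.DataFrame(columns, index=index)
    metadata = pd.DataFrame(
        meta_rows, columns=["library_id", "fraction", "condition", "replicate"]
    ).set_index("library_id")
    lengths_series = pd.Series(row_length, index=index, name="length")
    return CountTable(data=data, metadata=metadata, lengths=lengths_series, units="counts")


@dataclass
class Simulation:
    """A complete simulated experiment with its ground truth."""

    config: SimulationConfig
    features: pd.DataFrame
    gene_models: pd.DataFrame
    peaks: pd.DataFrame
    params: pd.DataFrame
    pools: pd.DataFrame
    counts: CountTable
    enrichment: pd.DataFrame

    @property
    def truth(self) -> pd.DataFrame:
        out = self.params.copy()
        out["half_life"] = LN2 / out["k_d"]
        out = out.join(self.pools).join(self.features)
        out["me3_category"] = self.gene_models["me3_category"]
        return out

    @property
    def spike_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.config.spike_ins]).set_index("spike_id")

    @property
    def generative_scale(self) -> float:
        """True pull-down-to-total library scale factor S_pd / S_tot.

        Sums run over quantification rows (exonic + intronic), matching the
        denominator of the TPM recomputation the estimator sees.
        """
        eff, c = self.config.labeling_efficiency, self.config.contamination_frac
        pools = self.pools
        intron = self.features["has_introns"]
        s_tot = (pools["premature"] + pools["mature"]).sum() + pools.loc[intron, "premature"].sum()
        s_pd = (
            eff * (pools["labeled_premature"] + pools["labeled_mature"]).sum()
            + c * (pools["premature"] + pools["mature"]).sum()
            + (eff * pools.loc[intron, "labeled_premature"] + c * pools.loc[intron, "premature"]).sum()
        )
        return float(s_pd / s_tot)


def simulate_experiment(config: SimulationConfig) -> Simulation:
    """Run the full generator: features -> genome -> kinetics -> pools -> counts."""
    config.validate()
    features = sample_features(config)
    models, peaks = sample_gene_models(config, features)
    params = sample_kinetic_params(config, features)

    pools = steady_state_pools(params)
    if config.normalize_to_tpm:
        # rescale synthesis so the total-library analysis signal sums to 1e6
        # over quantification rows (exonic = premature+mature, intronic =
        # premature): abundances and synthesis rates are then in the same TPM
        # units the estimator reports, making truth directly comparable
        intron = features["has_introns"]
        row_sum = (pools["premature"] + pools["mature"]).sum() + pools.loc[intron, "premature"].sum()
        params = params.assign(alpha=params["alpha"] * (1e6 / row_sum))
        pools = steady_state_pools(params)
    pools = pools.join(labeled_pools(params, config.t_label))

    counts = simulate_libraries(pools, models, config)
    enrichment = sample_enrichment(config, features)
    return Simulation(
        config=config,
        features=features,
        gene_models=models,
        peaks=peaks,
        params=params,
        pools=pools,
        counts=counts,
        enrichment=enrichment,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", index=False)


def write_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete runnable fixture (counts, metadata, truth, annotation).

    Re-running with the same config produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_experiment(config)
    paths: dict[str, Path] = {}

    counts = sim.counts.data.copy()
    counts.insert(0, "length", sim.counts.lengths)
    counts = counts.reset_index()
    paths["counts"] = outdir / "counts.tsv"
    _write_tsv(counts, paths["counts"])

    paths["libraries"] = outdir / "libraries.tsv"
    _write_tsv(sim.counts.metadata.reset_index(), paths["libraries"])

    paths["truth"] = outdir / "truth.tsv"
    _write_tsv(sim.truth.reset_index(), paths["truth"])

    paths["gene_models_tsv"] = outdir / "gene_models.tsv"
    _write_tsv(
        sim.gene_models.reset_index()[["gene_id", "chrom", "strand", "start", "end"]],
        paths["gene_models_tsv"],
    )

    paths["gene_models_gtf"] = outdir / "gene_models.gtf"
    with open(paths["gene_models_gtf"], "w") as fh:
        for gene, row in sim.gene_models.iterrows():
            fh.write(
                f"{row['chrom']}\tpulserate_sim\tgene\t{row['start']}\t{row['end']}"
                f"\t.\t{row['strand']}\t.\tgene_id \"{gene}\";\n"
            )

    paths["peaks"] = outdir / "peaks.bed"
    with open(paths["peaks"], "w") as fh:
        for _, row in sim.peaks.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\tH3K27me3\n")

    paths["tf_list"] = outdir / "tf_genes.txt"
    paths["tf_list"].write_text("".join(f"{g}\n" for g in sim.features.index[sim.features["tf"]]))

    paths["enrichment"] = outdir / "enrichment.tsv"
    _write_tsv(sim.enrichment, paths["enrichment"])

    paths["spike_ins"] = outdir / "spike_ins.tsv"
    _write_tsv(sim.spike_table.reset_index(), paths["spike_ins"])

    cfg = dataclasses.asdict(config)
    cfg["spike_ins"] = [dataclasses.asdict(s) for s in config.spike_ins]
    paths["config"] = outdir / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def simulate_derepression(
    n_genes: int = 4000,
    n_targets: int = 300,
    synthesis_fc: float = 2.0,
    decay_fc: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Nascent + total abundances for a control vs knockdown comparison.

    Targets get their synthesis multiplied by ``synthesis_fc`` and their decay
    by ``decay_fc`` in the knockdown; nascent signal tracks synthesis, total
    signal tracks synthesis/decay.  The expected total-vs-nascent ratio shift
    for targets is ``-log2(decay_fc)`` (zero for a purely transcriptional
    response).
    """
    rng = np.random.default_rng(seed)
    ids = _gene_ids(n_genes)
    alpha = 10 ** (0.6 * rng.standard_normal(n_genes))
    k = 10 ** (-2.0 + 0.44 * rng.standard_normal(n_genes))
    targets = set(rng.choice(ids, size=n_targets, replace=False))
    is_target = np.array([g in targets for g in ids])

    alpha_kd = np.where(is_target, alpha * synthesis_fc, alpha)
    k_kd = np.where(is_target, k * decay_fc, k)

    def noisy(x: np.ndarray) -> np.ndarray:
        if noise_cv == 0:
            return x
        return x * rng.lognormal(0.0, noise_cv, size=x.shape)

    df = pd.DataFrame(
        {
            "nascent_ctrl": noisy(alpha),
            "nascent_kd": noisy(alpha_kd),
            "total_ctrl": noisy(alpha / k),
            "total_kd": noisy(alpha_kd / k_kd),
        },
        index=pd.Index(ids, name="gene_id"),
    )
    df = df / df.sum(axis=0) * 1e6  # per-library TPM normalization
    return df, targets
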