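"""Synthetic factorial multi-omics data with planted, recoverable ground truth.

The generator emulates the statistical structure of a crossed field-trial
design — varieties x locations x developmental stages with replicates —
profiled at two molecular layers:

* log2-scale gene expression in which co-expression modules are driven by
  latent eigengene profiles carrying additive factor effects (stage trends,
  location and variety offsets) plus Gaussian noise;
* a metabolite layer whose module latents are linearly coupled (with sign)
  to gene-module eigengenes;
* a two-component coefficient-of-variation mixture (a fraction of genes get
  their noise shrunk 5-fold, giving a distinguishable low-variability
  component);
* one planted regulator gene that carries signal in every evidence channel:
  a hub loading in its module, true effects for all three factors, and a set
  of targets generated as noisy sigmoid functions of the regulator so that
  the dependence is strongly detectable by mutual information.

Every draw flows from a single seeded generator, so identical configurations
produce bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    FeatureMatrix,
    PathwaySets,
    SampleDesign,
    ValidationError,
    write_design,
    write_feature_matrix,
    write_gmt,
)

# Which factors each gene module's eigengene responds to, cycling if there
# are more modules than patterns. Module 1 (the planted regulator's module)
# responds to all three factors.
_MODULE_PATTERNS: list[tuple[str, ...]] = [
    ("variety", "location", "stage"),
    ("stage",),
    ("location",),
    ("variety", "stage"),
    ("location", "stage"),
    ("variety",),
]


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_metabolites: int = 500
    n_modules_gene: int = 5
    n_modules_metab: int = 4
    design: tuple[int, int, int, int] = (3, 3, 6, 2)  # varieties, locations, stages, replicates
    effect_size: float = 2.0          # log2 units spanned by a planted factor effect
    within_module_cor: float = 0.8    # expected pairwise correlation of module members
    noise_sd: float = 0.5             # residual SD on the log2 scale
    latent_noise_sd: float = 0.5      # SD of the eigengene's sample-level noise
    cv_low_frac: float = 0.5          # fraction of genes in the low-variability component
    seed: int = 0
    module_size_gene: int | None = None    # default: n_genes // (2 * n_modules_gene)
    module_size_metab: int | None = None   # default: n_metabolites // (2 * n_modules_metab)
    coupling_r: float = 0.8           # |cor| between linked gene/metabolite module latents
    n_links: int | None = None        # coupled metabolite modules; default all of them
    plant_regulator: bool = True
    n_regulator_targets: int = 8
    baseline_mean: float = 8.0        # log2 abundance baseline for genes
    baseline_sd: float = 1.5
    metab_baseline_mean: float = 5.0
    metab_baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_metabolites, self.n_modules_gene, self.n_modules_metab)
        if any(c < 1 for c in counts):
            raise ValidationError("all feature/module counts must be positive")
        if not (0 < self.within_module_cor < 1):
            raise ValidationError("within_module_cor must lie in (0, 1)")
        if not (0 <= self.cv_low_frac < 1):
            raise ValidationError("cv_low_frac must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0 < self.coupling_r < 1):
            raise ValidationError("coupling_r must lie in (0, 1)")
        if self.gene_module_size * self.n_modules_gene > self.n_genes:
            raise ValidationError("gene module sizes exceed n_genes")
        if self.metab_module_size * self.n_modules_metab > self.n_metabolites:
            raise ValidationError("metabolite module sizes exceed n_metabolites")
        n_links = self.n_modules_metab if self.n_links is None else self.n_links
        if n_links > self.n_modules_gene:
            raise ValidationError(
                f"{n_links} gene-metabolite links requested but only "
                f"{self.n_modules_gene} gene modules exist"
            )

    @property
    def gene_module_size(self) -> int:
        return self.module_size_gene or max(2, self.n_genes // (2 * self.n_modules_gene))

    @property
    def metab_module_size(self) -> int:
        return self.module_size_metab or max(2, self.n_metabolites // (2 * self.n_modules_metab))


@dataclass
class GroundTruth:
    """Planted structure: module membership, DE sets, cross-layer links,
    regulator targets. Background features carry the label ``"none"``."""

    module_assignment_true: dict[str, str] = field(default_factory=dict)
    de_features_true: dict[str, set[str]] = field(default_factory=dict)
    gene_metab_links_true: list[tuple[str, str, int]] = field(default_factory=list)
    regulator_targets_true: dict[str, set[str]] = field(default_factory=dict)
    planted_regulator: str | None = None
    low_cv_features: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_assignment_true": self.module_assignment_true,
            "de_features_true": {k: sorted(v) for k, v in self.de_features_true.items()},
            "gene_metab_links_true": [list(t) for t in self.gene_metab_links_true],
            "regulator_targets_true": {k: sorted(v) for k, v in self.regulator_targets_true.items()},
            "planted_regulator": self.planted_regulator,
            "low_cv_features": sorted(self.low_cv_features),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            module_assignment_true=d["module_assignment_true"],
            de_features_true={k: set(v) for k, v in d["de_features_true"].items()},
            gene_metab_links_true=[tuple(t) for t in d["gene_metab_links_true"]],
            regulator_targets_true={k: set(v) for k, v in d["regulator_targets_true"].items()},
            planted_regulator=d["planted_regulator"],
            low_cv_features=set(d["low_cv_features"]),
        )


@dataclass
class SyntheticDataset:
    genes: FeatureMatrix
    metabolites: FeatureMatrix
    design: SampleDesign
    truth: GroundTruth
    regulators: list[str]
    config: SimulationConfig


def simulate_design(cfg: SimulationConfig) -> SampleDesign:
    """Full factorial crossing of variety x location x stage with replicates."""
    n_v, n_l, n_s, n_r = cfg.design
    if min(n_v, n_l, n_s) < 2:
        raise ValidationError(
            f"every factor needs >=2 levels for the ANOVA stage, got {cfg.design[:3]}"
        )
    if n_r < 1:
        raise ValidationError("replicate count must be >=1")
    rows = []
    for v in range(n_v):
        for l in range(n_l):
            for s in range(n_s):
                for r in range(n_r):
                    rows.append(
                        {
                            "sample_id": f"V{v + 1}_L{l + 1}_S{s + 1}_r{r + 1}",
                            "variety": f"V{v + 1}",
                            "location": f"L{l + 1}",
                            "stage": f"S{s + 1}",
                            "replicate": r + 1,
                        }
                    )
    df = pd.DataFrame(rows).set_index("sample_id")
    df["stage"] = pd.Categorical(
        df["stage"], categories=[f"S{s + 1}" for s in range(n_s)], ordered=True
    )
    return SampleDesign(df)


def _factor_effect(design: SampleDesign, factor: str, effect: float, sign: int) -> np.ndarray:
    """Per-sample additive effect: a monotone span for stage, a +/- split of
    extreme levels otherwise; total span equals ``effect`` log2 units."""
    levels = design.levels(factor)
    L = len(levels)
    if factor == "stage":
        offsets = sign * effect * (np.arange(L) / max(L - 1, 1) - 0.5)
    else:
        offsets = np.zeros(L)
        offsets[0], offsets[-1] = -sign * effect / 2.0, sign * effect / 2.0
    lut = dict(zip(levels, offsets))
    return np.array([lut[x] for x in design.table[factor]], dtype=float)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_expression(
    cfg: SimulationConfig, design: SampleDesign, rng: np.random.Generator | None = None
) -> tuple[FeatureMatrix, GroundTruth, dict[str, np.ndarray]]:
    """Simulate the gene layer; returns the matrix, partial truth and the
    latent eigengene profile of each planted module (needed downstream)."""
    rng = rng or np.random.default_rng(cfg.seed)
    n_samples = len(design.sample_ids)
    size = cfg.gene_module_size
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    truth = GroundTruth(de_features_true={f: set() for f in ("variety", "location", "stage")})
    latents: dict[str, np.ndarray] = {}
    values = np.empty((cfg.n_genes, n_samples))

    # low-variability component: noise shrunk x0.2; loadings shrink with it so
    # within-module correlations stay calibrated
    low_cv = rng.random(cfg.n_genes) < cfg.cv_low_frac
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    lam_ratio = np.sqrt(cfg.within_module_cor / (1.0 - cfg.within_module_cor))

    regulator_idx = -1
    target_idx: list[int] = []
    pos = 0
    for m in range(cfg.n_modules_gene):
        label = f"gm{m + 1}"
        pattern = _MODULE_PATTERNS[m % len(_MODULE_PATTERNS)]
        sign = 1 if m % 2 == 0 else -1
        e = np.zeros(n_samples)
        for f in pattern:
            e += _factor_effect(design, f, cfg.effect_size, sign)
        e += rng.normal(0.0, cfg.latent_noise_sd, size=n_samples)
        latents[label] = e
        sd_e = e.std()

        members = list(range(pos, pos + size))
        pos += size
        if cfg.plant_regulator and m == 0:
            regulator_idx = members[0]
            low_cv[regulator_idx] = False
            n_t = min(cfg.n_regulator_targets, size - 1)
            target_idx = members[1 : 1 + n_t]
            for t in target_idx:
                low_cv[t] = False

        for g in members:
            sigma = cfg.noise_sd * (0.2 if low_cv[g] else 1.0)
            mult = rng.uniform(0.8, 1.2)
            if g == regulator_idx:
                mult = 1.5  # hub: strongest loading in its module
            lam = mult * sigma * lam_ratio / sd_e
            if g in target_idx:
                continue  # filled in after the regulator profile exists
            values[g] = baselines[g] + lam * e + rng.normal(0.0, sigma, size=n_samples)
            truth.module_assignment_true[gene_ids[g]] = label
            if cfg.effect_size > 0:
                for f in pattern:
                    truth.de_features_true[f].add(gene_ids[g])

        if cfg.plant_regulator and m == 0:
            z = _standardize(values[regulator_idx])
            for t in target_idx:
                # monotone saturating dependence: strong MI, understated by
                # linear correlation in the tails
                values[t] = (
                    baselines[t]
                    + 4.0 / (1.0 + np.exp(-2.0 * z))
                    + rng.normal(0.0, 0.3, size=n_samples)
                )
                truth.module_assignment_true[gene_ids[t]] = label
                if cfg.effect_size > 0:
                    for f in pattern:
                        truth.de_features_true[f].add(gene_ids[t])
            truth.planted_regulator = gene_ids[regulator_idx]
            truth.regulator_targets_true = {
                gene_ids[regulator_idx]: {gene_ids[t] for t in target_idx}
            }

    for g in range(pos, cfg.n_genes):  # background: pure noise
        sigma = cfg.noise_sd * (0.2 if low_cv[g] else 1.0)
        values[g] = baselines[g] + rng.normal(0.0, sigma, size=n_samples)
        truth.module_assignment_true[gene_ids[g]] = "none"

    truth.low_cv_features = {gene_ids[g] for g in range(cfg.n_genes) if low_cv[g]}
    fm = FeatureMatrix(
        pd.DataFrame(values, index=gene_ids, columns=design.sample_ids), "transcript"
    )
    return fm, truth, latents


def simulate_metabolome(
    cfg: SimulationConfig,
    design: SampleDesign,
    truth: GroundTruth,
    gene_latents: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[FeatureMatrix, GroundTruth]:
    """Simulate the metabolite layer: linked module latents are signed copies
    of gene-module eigengenes plus noise, calibrated to ``coupling_r``."""
    n_samples = len(design.sample_ids)
    size = cfg.metab_module_size
    metab_ids = [f"M{i + 1:04d}" for i in range(cfg.n_metabolites)]
    n_links = cfg.n_modules_metab if cfg.n_links is None else cfg.n_links

    values = np.empty((cfg.n_metabolites, n_samples))
    baselines = rng.normal(cfg.metab_baseline_mean, cfg.metab_baseline_sd, size=cfg.n_metabolites)
    lam_ratio = np.sqrt(cfg.within_module_cor / (1.0 - cfg.within_module_cor))
    sigma_link = np.sqrt(1.0 / cfg.coupling_r**2 - 1.0)

    pos = 0
    for m in range(cfg.n_modules_metab):
        label = f"mm{m + 1}"
        if m < n_links:
            gene_label = f"gm{m + 1}"
            if gene_label not in gene_latents:
                raise ValidationError(f"link references unknown gene module {gene_label}")
            sign = 1 if m % 2 == 0 else -1
            e = sign * _standardize(gene_latents[gene_label]) + rng.normal(
                0.0, sigma_link, size=n_samples
            )
            truth.gene_metab_links_true.append((gene_label, label, sign))
        else:
            e = rng.normal(0.0, 1.0, size=n_samples)  # uncoupled: independent latent
        sd_e = e.std()
        for i in range(pos, pos + size):
            lam = rng.uniform(0.8, 1.2) * cfg.noise_sd * lam_ratio / sd_e
            values[i] = baselines[i] + lam * e + rng.normal(0.0, cfg.noise_sd, size=n_samples)
            truth.module_assignment_true[metab_ids[i]] = label
        pos += size

    for i in range(pos, cfg.n_metabolites):
        values[i] = baselines[i] + rng.normal(0.0, cfg.noise_sd, size=n_samples)
        truth.module_assignment_true[metab_ids[i]] = "none"

    fm = FeatureMatrix(
        pd.DataFrame(values, index=metab_ids, columns=design.sample_ids), "metabolite"
    )
    return fm, truth


def _regulator_list(cfg: SimulationConfig, truth: GroundTruth) -> list[str]:
    """Curated-pathway stand-in: the planted regulator plus two decoy members
    per gene module (decoys have no planted targets)."""
    regs: list[str] = []
    if truth.planted_regulator:
        regs.append(truth.planted_regulator)
    by_module: dict[str, list[str]] = {}
    for fid, mod in sorted(truth.module_assignment_true.items()):
        if fid.startswith("G") and mod != "none":
            by_module.setdefault(mod, []).append(fid)
    exclude = set(regs) | set().union(*truth.regulator_targets_true.values(), set())
    for mod in sorted(by_module):
        # prefer high-variability members: decoys should survive the variance
        # filter so every module's network stage has a regulator to test
        candidates = [g for g in by_module[mod] if g not in exclude]
        high = [g for g in candidates if g not in truth.low_cv_features]
        regs.extend((high + [g for g in candidates if g in truth.low_cv_features])[:2])
    return regs


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full two-layer dataset from one seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    design = simulate_design(cfg)
    genes, truth, latents = simulate_expression(cfg, design, rng)
    metabolites, truth = simulate_metabolome(cfg, design, truth, latents, rng)
    return SyntheticDataset(genes, metabolites, design, truth, _regulator_list(cfg, truth), cfg)


def true_module_gmt(truth: GroundTruth) -> PathwaySets:
    """The planted modules as pathway sets (enrichment ground truth)."""
    sets: dict[str, set[str]] = {}
    for fid, mod in truth.module_assignment_true.items():
        if mod != "none":
            sets.setdefault(mod, set()).add(fid)
    return PathwaySets(sets, {name: "planted module" for name in sets})


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.json",
        "regulators": outdir / "regulators.txt",
        "true_modules": outdir / "true_modules.gmt",
    }
    write_feature_matrix(ds.genes, paths["genes"])
    write_feature_matrix(ds.metabolites, paths["metabolites"])
    write_design(ds.design, paths["design"])
    ds.truth.to_json(paths["truth"])
    paths["regulators"].write_text("\n".join(ds.regulators) + "\n")
    write_gmt(true_module_gmt(ds.truth), paths["true_modules"])
    return paths


def simulate_de_matrix(
    design: SampleDesign,
    n_features: int,
    n_de: int,
    factor: str,
    effect: float,
    noise_sd: float = 0.5,
    baseline: float = 8.0,
    seed: int = 0,
) -> tuple[FeatureMatrix, set[str]]:
    """Minimal planted-DE generator for power/FDR studies of the ANOVA stage:
    ``n_de`` features get a ``factor`` effect spanning ``effect`` log2 units
    (extreme levels at +/- effect/2), the rest are pure Gaussian noise."""
    if n_de > n_features:
        raise ValidationError("n_de exceeds n_features")
    rng = np.random.default_rng(seed)
    n_samples = len(design.sample_ids)
    ids = [f"F{i + 1:05d}" for i in range(n_features)]
    values = baseline + rng.normal(0.0, noise_sd, size=(n_features, n_samples))
    shift = _factor_effect(design, factor, effect, sign=1)
    values[:n_de] += shift
    fm = FeatureMatrix(
        pd.DataFrame(values, index=ids, columns=design.sample_ids), "transcript"
    )
    return fm, set(ids[:n_de])
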