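"""End-to-end orchestration: simulate -> qc -> filter -> de -> modules ->
grn -> integrate -> prioritize -> enrich, from one config with one seed.

Each stage writes its tables under ``outdir/<stage>/`` plus a ``.done``
marker, and appends a manifest record (stage, parameters, row counts, wall
time) to ``outdir/manifest.jsonl``. A stage whose marker and outputs are
present is reloaded instead of recomputed, so deleting one intermediate and
rerunning re-executes only that stage and everything downstream of it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, differential, enrich, integrate, mi, prioritize, variance_filter
from .io import (
    FACTORS,
    FeatureMatrix,
    SampleDesign,
    ValidationError,
    align_to_design,
    read_design,
    read_feature_matrix,
    read_gmt,
    write_feature_matrix,
    write_table,
)
from .simulate import GroundTruth, SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "filter", "de", "modules", "grn", "integrate",
          "prioritize", "enrich")


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    # inputs: either simulate (default) or explicit file paths
    genes_path: str | None = None
    metabolites_path: str | None = None
    design_path: str | None = None
    regulators_path: str | None = None
    gmt_path: str | None = None
    simulation: dict = field(default_factory=dict)
    # per-stage parameters
    filter_params: dict = field(default_factory=lambda: {"cv_scale": "linear", "cutoff": 0.5,
                                                         "tol": 1e-8, "max_iter": 500})
    de_params: dict = field(default_factory=lambda: {"alpha": 0.01, "sd_mult": 2.0})
    module_params: dict = field(default_factory=lambda: {"beta": 7.0, "min_size_gene": 30,
                                                         "min_size_metab": 10})
    grn_params: dict = field(default_factory=lambda: {"p_target": 1e-8, "n_perm": 100_000,
                                                      "dpi_tolerance": 0.0})
    integrate_params: dict = field(default_factory=lambda: {"alpha": 0.01, "bh": False})
    prioritize_params: dict = field(default_factory=lambda: {"top_n": 50,
                                                             "use_adjusted": False})
    enrich_params: dict = field(default_factory=lambda: {"fdr": 0.05})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        base = cls(**{k: v for k, v in raw.items() if k in known})
        return base

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        if "design" in params:
            params["design"] = tuple(params["design"])
        return SimulationConfig(**params)


@dataclass
class PipelineResult:
    outdir: Path
    genes: FeatureMatrix | None = None
    metabolites: FeatureMatrix | None = None
    design: SampleDesign | None = None
    truth: GroundTruth | None = None
    regulators: list[str] = field(default_factory=list)
    filtered_genes: FeatureMatrix | None = None
    de_genes: differential.DeTable | None = None
    de_metabolites: differential.DeTable | None = None
    gene_modules: coexpression.ModuleSet | None = None
    metab_modules: coexpression.ModuleSet | None = None
    networks: dict[str, mi.MiNetwork] = field(default_factory=dict)
    integration_forward: integrate.IntegrationResult | None = None
    integration_reverse: integrate.IntegrationResult | None = None
    links: pd.DataFrame | None = None
    ranked: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    stages_run: dict[str, str] = field(default_factory=dict)


def qc_pca(
    fm: FeatureMatrix, design: SampleDesign, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature-centered PCA of the samples; returns per-sample scores annotated
    with the design factors, plus the variance-explained fractions."""
    if fm.n_samples < 3:
        raise ValidationError("PCA needs >=3 samples")
    if n_components > min(fm.n_features, fm.n_samples):
        raise ValidationError(
            f"n_components={n_components} exceeds matrix rank bound "
            f"{min(fm.n_features, fm.n_samples)}"
        )
    X = fm.values.T  # samples x features
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):  # deterministic sign: largest |score| positive
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    var_explained = (s**2) / (s**2).sum()
    out = pd.DataFrame(
        scores, index=fm.sample_ids,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    out = out.join(design.table.loc[out.index, list(FACTORS) + ["replicate"]])
    return out, var_explained[:n_components]


class _Runner:
    def __init__(self, cfg: PipelineConfig, force: bool = False):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.force = force
        self.result = PipelineResult(outdir=self.out)

    def _dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def _marker(self, stage: str) -> Path:
        return self.out / stage / ".done"

    def _manifest(self, stage: str, status: str, t0: float, **info) -> None:
        rec = {
            "stage": stage,
            "status": status,
            "seed": self.cfg.seed,
            "wall_time_s": round(time.time() - t0, 3),
            **info,
        }
        with open(self.out / "manifest.jsonl", "a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
        self.result.stages_run[stage] = status

    def cached(self, stage: str, *files: Path) -> bool:
        return (
            not self.force
            and self._marker(stage).exists()
            and all(f.exists() for f in files)
        )

    # ---------------- stages ----------------

    def simulate(self) -> None:
        t0 = time.time()
        d = self._dir("simulate")
        res = self.result
        if self.cfg.genes_path:  # user-supplied inputs: no simulation
            res.genes = read_feature_matrix(self.cfg.genes_path, "transcript")
            res.metabolites = read_feature_matrix(self.cfg.metabolites_path, "metabolite")
            res.design = read_design(self.cfg.design_path)
            if self.cfg.regulators_path:
                res.regulators = [
                    l.strip() for l in Path(self.cfg.regulators_path).read_text().splitlines()
                    if l.strip()
                ]
            self._manifest("simulate", "external_inputs", t0,
                           n_genes=res.genes.n_features,
                           n_metabolites=res.metabolites.n_features)
        else:
            files = [d / f for f in ("genes.tsv", "metabolites.tsv", "design.tsv",
                                     "truth.json", "regulators.txt")]
            if self.cached("simulate", *files):
                res.genes = read_feature_matrix(files[0], "transcript")
                res.metabolites = read_feature_matrix(files[1], "metabolite")
                res.design = read_design(files[2])
                res.truth = GroundTruth.from_json(files[3])
                res.regulators = files[4].read_text().split()
                self._manifest("simulate", "cached", t0)
            else:
                ds = simulate_dataset(self.cfg.simulation_config())
                write_dataset(ds, d)
                res.genes, res.metabolites = ds.genes, ds.metabolites
                res.design, res.truth, res.regulators = ds.design, ds.truth, ds.regulators
                self._marker("simulate").touch()
                self._manifest("simulate", "computed", t0,
                               n_genes=res.genes.n_features,
                               n_metabolites=res.metabolites.n_features,
                               n_samples=res.genes.n_samples)
        res.genes = align_to_design(res.genes, res.design)
        res.metabolites = align_to_design(res.metabolites, res.design)

    def qc(self) -> None:
        t0 = time.time()
        d = self._dir("qc")
        res = self.result
        for layer, fm in (("genes", res.genes), ("metabolites", res.metabolites)):
            scores, ve = qc_pca(fm, res.design)
            scores.index.name = "sample_id"
            scores.to_csv(d / f"pca_{layer}.tsv", sep="\t")
            (d / f"pca_{layer}_variance.json").write_text(
                json.dumps({"variance_explained": ve.tolist()})
            )
        self._marker("qc").touch()
        self._manifest("qc", "computed", t0)

    def filter(self) -> None:
        t0 = time.time()
        d = self._dir("filter")
        res = self.result
        out_file = d / "filtered_genes.tsv"
        if self.cached("filter", out_file):
            res.filtered_genes = read_feature_matrix(out_file, "transcript")
            self._manifest("filter", "cached", t0)
            return
        p = self.cfg.filter_params
        cv = variance_filter.compute_cv(res.genes, scale=p.get("cv_scale", "linear"))
        fit = variance_filter.fit_gaussian_mixture_em(
            cv, tol=p.get("tol", 1e-8), max_iter=p.get("max_iter", 500), seed=self.cfg.seed
        )
        res.filtered_genes = variance_filter.select_high_variance(
            res.genes, fit, cutoff=p.get("cutoff", 0.5)
        )
        write_feature_matrix(res.filtered_genes, out_file)
        (d / "mixture_fit.json").write_text(json.dumps({
            "weights": fit.weights.tolist(), "means": fit.means.tolist(),
            "sds": fit.sds.tolist(), "loglik": fit.loglik, "n_iter": fit.n_iter,
            "converged": fit.converged,
        }, sort_keys=True))
        self._marker("filter").touch()
        self._manifest("filter", "computed", t0,
                       kept=res.filtered_genes.n_features, total=res.genes.n_features)

    def _run_de(self, fm: FeatureMatrix) -> differential.DeTable:
        p = self.cfg.de_params
        anova = differential.fit_factorial_anova(fm, self.result.design)
        fc = pd.DataFrame(
            {f"fc_{f}": differential.compute_group_fold_changes(fm, self.result.design, f)
             for f in FACTORS}
        )
        return differential.select_differential_features(
            anova.p[list(FACTORS)], fc,
            alpha=p.get("alpha", 0.01), sd_mult=p.get("sd_mult", 2.0),
        )

    @staticmethod
    def _write_de(de: differential.DeTable, path: Path) -> None:
        t = de.table.copy()
        t.index.name = "feature_id"
        t.to_csv(path, sep="\t")

    @staticmethod
    def _read_de(path: Path, alpha: float, sd_mult: float) -> differential.DeTable:
        t = pd.read_csv(path, sep="\t", index_col=0)
        for f in FACTORS:
            t[f"de_{f}"] = t[f"de_{f}"].astype(bool)
        return differential.DeTable(t, alpha, sd_mult, {})

    def de(self) -> None:
        t0 = time.time()
        d = self._dir("de")
        res = self.result
        p = self.cfg.de_params
        fg, fm_ = d / "de_genes.tsv", d / "de_metabolites.tsv"
        if self.cached("de", fg, fm_):
            res.de_genes = self._read_de(fg, p["alpha"], p["sd_mult"])
            res.de_metabolites = self._read_de(fm_, p["alpha"], p["sd_mult"])
            self._manifest("de", "cached", t0)
            return
        res.de_genes = self._run_de(res.filtered_genes)
        res.de_metabolites = self._run_de(res.metabolites)
        self._write_de(res.de_genes, fg)
        self._write_de(res.de_metabolites, fm_)
        (d / "summary.json").write_text(json.dumps({
            "genes": res.de_genes.summary(), "metabolites": res.de_metabolites.summary(),
        }, sort_keys=True))
        self._marker("de").touch()
        self._manifest("de", "computed", t0, **{
            "deg_union": res.de_genes.summary()["union"],
            "dem_union": res.de_metabolites.summary()["union"],
        })

    def _de_union(self, de: differential.DeTable) -> list[str]:
        union: set[str] = set()
        for f in FACTORS:
            union |= de.de_features(f)
        return [f for f in de.table.index if f in union]

    def _build_layer_modules(
        self, fm: FeatureMatrix, de: differential.DeTable, min_size: int
    ) -> coexpression.ModuleSet:
        keep = self._de_union(de)
        if len(keep) < max(min_size, 10):
            raise ValidationError(
                f"only {len(keep)} differential features; too few for module detection"
            )
        sub = fm.subset(keep)
        mp = self.cfg.module_params
        _, modules = coexpression.build_modules(
            sub, beta=mp.get("beta", 7.0), min_size=min_size,
            cut_height=mp.get("cut_height"), cut_quantile=mp.get("cut_quantile"),
        )
        return modules

    @staticmethod
    def _write_modules(modules: coexpression.ModuleSet, d: Path, layer: str) -> None:
        a = modules.assignment.to_frame()
        a.index.name = "feature_id"
        a.to_csv(d / f"{layer}_assignment.tsv", sep="\t")
        for name, df in (("eigengenes", modules.eigengenes), ("kme", modules.kme),
                         ("kme_p", modules.kme_p)):
            if df is not None:
                df2 = df.copy()
                df2.index.name = "sample_id" if name == "eigengenes" else "feature_id"
                df2.to_csv(d / f"{layer}_{name}.tsv", sep="\t")

    @staticmethod
    def _read_modules(d: Path, layer: str) -> coexpression.ModuleSet:
        a = pd.read_csv(d / f"{layer}_assignment.tsv", sep="\t", index_col=0)["module"]
        ms = coexpression.ModuleSet(a)
        for name in ("eigengenes", "kme", "kme_p"):
            f = d / f"{layer}_{name}.tsv"
            if f.exists():
                setattr(ms, name, pd.read_csv(f, sep="\t", index_col=0))
        return ms

    def modules(self) -> None:
        t0 = time.time()
        d = self._dir("modules")
        res = self.result
        mp = self.cfg.module_params
        need = [d / "gene_assignment.tsv", d / "gene_eigengenes.tsv",
                d / "metab_assignment.tsv", d / "metab_eigengenes.tsv"]
        if self.cached("modules", *need):
            res.gene_modules = self._read_modules(d, "gene")
            res.metab_modules = self._read_modules(d, "metab")
            self._manifest("modules", "cached", t0)
            return
        res.gene_modules = self._build_layer_modules(
            res.filtered_genes, res.de_genes, mp.get("min_size_gene", 30))
        res.metab_modules = self._build_layer_modules(
            res.metabolites, res.de_metabolites, mp.get("min_size_metab", 10))
        self._write_modules(res.gene_modules, d, "gene")
        self._write_modules(res.metab_modules, d, "metab")
        self._marker("modules").touch()
        self._manifest("modules", "computed", t0,
                       n_gene_modules=len(res.gene_modules.module_names),
                       n_metab_modules=len(res.metab_modules.module_names))

    def grn(self) -> None:
        t0 = time.time()
        d = self._dir("grn")
        res = self.result
        gp = self.cfg.grn_params
        out_file = d / "edges.tsv"
        if self.cached("grn", out_file):
            edges = pd.read_csv(out_file, sep="\t")
            for mod, grp in edges.groupby("module"):
                res.networks[mod] = mi.MiNetwork(
                    grp.drop(columns="module").reset_index(drop=True),
                    set(grp["regulator"]), mod, float("nan"), 0)
            self._manifest("grn", "cached", t0)
            return
        if not res.regulators:
            log.warning("no regulator list; skipping GRN stage")
            write_table(pd.DataFrame(
                columns=["module", "regulator", "target", "mi", "kept_after_dpi"]), out_file)
            self._marker("grn").touch()
            self._manifest("grn", "computed", t0, n_edges=0)
            return
        n = res.filtered_genes.n_samples
        bins = gp.get("bins") or mi.default_bins(n)
        threshold = mi.calibrate_mi_threshold(
            n, bins=bins, p_target=gp.get("p_target", 1e-8),
            n_perm=gp.get("n_perm", 100_000), seed=self.cfg.seed,
        )
        all_edges = []
        for mod in res.gene_modules.module_names:
            members = res.gene_modules.members(mod)
            sub = res.filtered_genes.subset(members)
            net = mi.build_regulator_network(sub, set(res.regulators), threshold,
                                             bins=bins, module=mod)
            net = mi.apply_dpi(net, tolerance=gp.get("dpi_tolerance", 0.0))
            res.networks[mod] = net
            e = net.edges.copy()
            e.insert(0, "module", mod)
            all_edges.append(e)
        non_empty = [e for e in all_edges if len(e)]
        edges = pd.concat(non_empty, ignore_index=True) if non_empty else pd.DataFrame(
            columns=["module", "regulator", "target", "mi", "kept_after_dpi"])
        write_table(edges, out_file)
        (d / "threshold.json").write_text(json.dumps(
            {"mi_threshold": threshold, "bins": bins,
             "p_target": gp.get("p_target", 1e-8)}, sort_keys=True))
        self._marker("grn").touch()
        self._manifest("grn", "computed", t0, n_edges=int(len(edges)),
                       mi_threshold=threshold)

    def integrate(self) -> None:
        t0 = time.time()
        d = self._dir("integrate")
        res = self.result
        ip = self.cfg.integrate_params
        f1, f2, f3 = d / "metab_vs_geneME.tsv", d / "gene_vs_metabME.tsv", d / "links.tsv"
        if self.cached("integrate", f1, f2, f3):
            res.integration_forward = integrate.IntegrationResult(
                "metabolite_vs_geneME", pd.read_csv(f1, sep="\t"), ip["alpha"])
            res.integration_reverse = integrate.IntegrationResult(
                "gene_vs_metabME", pd.read_csv(f2, sep="\t"), ip["alpha"])
            res.links = pd.read_csv(f3, sep="\t")
            self._manifest("integrate", "cached", t0)
            return
        res.integration_forward = integrate.correlate_features_to_eigenvectors(
            res.metabolites, res.gene_modules.eigengenes,
            alpha=ip.get("alpha", 0.01), bh=ip.get("bh", False))
        gene_universe = res.filtered_genes.subset(
            res.gene_modules.assignment.index[
                res.gene_modules.assignment != coexpression.GREY])
        res.integration_reverse = integrate.correlate_features_to_eigenvectors(
            gene_universe, res.metab_modules.eigengenes,
            alpha=ip.get("alpha", 0.01), bh=ip.get("bh", False))
        # attribute forward rows to metabolite modules via the metabolite layer's
        # own module assignment
        res.links = integrate.significant_links(
            res.integration_forward, res.integration_reverse,
            res.gene_modules.assignment, res.metab_modules.assignment)
        write_table(res.integration_forward.table, f1)
        write_table(res.integration_reverse.table, f2)
        write_table(res.links, f3)
        self._marker("integrate").touch()
        self._manifest("integrate", "computed", t0,
                       n_reciprocal=int(res.links["reciprocal"].sum()))

    def prioritize(self) -> None:
        t0 = time.time()
        d = self._dir("prioritize")
        res = self.result
        pp = self.cfg.prioritize_params
        evidence = prioritize.assemble_evidence_pvalues(
            res.de_genes, res.gene_modules, res.integration_reverse,
            use_adjusted=pp.get("use_adjusted", False))
        res.ranked = prioritize.rank_genes(evidence)
        out = res.ranked.copy()
        out.index.name = "gene_id"
        out.to_csv(d / "evidence.tsv", sep="\t")
        prioritize.top_genes(res.ranked, pp.get("top_n", 50)).to_csv(
            d / "top_genes.tsv", sep="\t")
        self._marker("prioritize").touch()
        self._manifest("prioritize", "computed", t0, n_genes=len(res.ranked))

    def enrich(self) -> None:
        t0 = time.time()
        d = self._dir("enrich")
        res = self.result
        gmt_path = self.cfg.gmt_path or (self.out / "simulate" / "true_modules.gmt")
        if not Path(gmt_path).exists():
            log.warning("no GMT available; skipping enrichment")
            self._manifest("enrich", "skipped", t0)
            return
        pathways = read_gmt(gmt_path)
        universe = set(res.filtered_genes.feature_ids)
        selected = set(self._de_union(res.de_genes)) & universe
        res.enrichment = enrich.fisher_enrichment(
            selected, universe, pathways,
            fdr_threshold=self.cfg.enrich_params.get("fdr", 0.05))
        write_table(res.enrichment, d / "enrichment.tsv")
        self._marker("enrich").touch()
        self._manifest("enrich", "computed", t0,
                       n_significant=int(res.enrichment["significant"].sum())
                       if len(res.enrichment) else 0)


def run_pipeline(
    cfg: PipelineConfig, force: bool = False, upto: str | None = None
) -> PipelineResult:
    """Execute stages in dependency order; returns in-memory results.

    ``force=True`` ignores stage markers and recomputes everything;
    ``upto`` stops after the named stage (inclusive).
    """
    if upto is not None and upto not in STAGES:
        raise ValidationError(f"unknown stage {upto!r}; expected one of {STAGES}")
    runner = _Runner(cfg, force=force)
    for stage in STAGES:
        getattr(runner, stage)()
        if stage == upto:
            break
    return runner.result


def reset_pipeline(outdir: str | Path) -> None:
    out = Path(outdir)
    if out.exists():
        shutil.rmtree(out)
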