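"""Two-way correlation integration of the gene and metabolite layers.

Each metabolite is correlated against every gene-module eigengene, and each
gene against every metabolite-module eigengene (Pearson r with a two-sided
t-test, df = n - 2). Links at p < alpha (default 0.01, uncorrected by
default) are tabulated per (gene module, metabolite module) pair, flagging
reciprocal support: the pair is supported from both directions when at least
one member metabolite is significant against the gene eigengene AND at least
one member gene is significant against the metabolite eigengene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import adjust_bh, correlation_pvalues, pearson_matrix_matrix
from .io import FeatureMatrix, ValidationError


@dataclass
class IntegrationResult:
    direction: str  # "metabolite_vs_geneME" or "gene_vs_metabME"
    table: pd.DataFrame  # feature_id, module, r, r2, p, significant
    alpha: float

    def significant_rows(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def correlate_features_to_eigenvectors(
    fm: FeatureMatrix,
    eigengenes: pd.DataFrame,
    alpha: float = 0.01,
    direction: str = "",
    bh: bool = False,
) -> IntegrationResult:
    """Pearson r and p for every feature x eigengene pair; the significance
    flag uses raw p < alpha (or BH-adjusted p when ``bh=True``)."""
    shared = [s for s in fm.sample_ids if s in eigengenes.index]
    if len(shared) < 4:
        missing = [s for s in fm.sample_ids if s not in eigengenes.index]
        raise ValidationError(
            f"fewer than 4 shared samples between matrix and eigengenes; "
            f"matrix samples missing from eigengenes: {missing[:5]}"
        )
    X = fm.data.loc[:, shared].to_numpy()
    E = eigengenes.loc[shared].to_numpy().T  # modules x samples
    r = pearson_matrix_matrix(X, E)
    p = correlation_pvalues(r, len(shared))
    modules = list(eigengenes.columns)
    long = pd.DataFrame(
        {
            "feature_id": np.repeat(fm.feature_ids, len(modules)),
            "module": np.tile(modules, fm.n_features),
            "r": r.ravel(),
            "r2": (r**2).ravel(),
            "p": p.ravel(),
        }
    )
    p_eff = adjust_bh(long["p"].to_numpy()) if bh else long["p"].to_numpy()
    long["significant"] = p_eff < alpha
    if not direction:
        direction = (
            "metabolite_vs_geneME" if fm.omics_kind == "metabolite" else "gene_vs_metabME"
        )
    return IntegrationResult(direction, long, alpha)


def module_summary(result: IntegrationResult) -> pd.DataFrame:
    """Per-eigengene counts of significant positive / negative correlations."""
    sig = result.significant_rows()
    rows = []
    for mod, grp in sig.groupby("module"):
        rows.append(
            {
                "module": mod,
                "n_significant": len(grp),
                "n_positive": int((grp["r"] > 0).sum()),
                "n_negative": int((grp["r"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["module", "n_significant", "n_positive", "n_negative"])


def significant_links(
    forward: IntegrationResult,
    reverse: IntegrationResult,
    gene_modules: pd.Series,
    metab_modules: pd.Series,
) -> pd.DataFrame:
    """Join the two correlation directions into one table per
    (gene module, metabolite module) pair.

    ``forward`` is metabolite-vs-gene-eigengene, ``reverse`` is
    gene-vs-metabolite-eigengene; the module series give each feature's own
    module so cross-layer support can be attributed to a pair of modules.
    """
    fwd = forward.significant_rows()
    rev = reverse.significant_rows()
    gene_mods = sorted(m for m in gene_modules.unique() if m != "grey" and m != "none")
    metab_mods = sorted(m for m in metab_modules.unique() if m != "grey" and m != "none")

    rows = []
    for gm in gene_mods:
        gm_genes = set(gene_modules.index[gene_modules == gm])
        for mm in metab_mods:
            mm_metabs = set(metab_modules.index[metab_modules == mm])
            f = fwd[(fwd["module"] == gm) & fwd["feature_id"].isin(mm_metabs)]
            r = rev[(rev["module"] == mm) & rev["feature_id"].isin(gm_genes)]
            signs = np.concatenate([np.sign(f["r"]), np.sign(r["r"])])
            consistency = float(np.abs(signs.mean())) if signs.size else 0.0
            sign = int(np.sign(signs.sum())) if signs.size else 0
            rows.append(
                {
                    "gene_module": gm,
                    "metab_module": mm,
                    "n_metab_significant": len(f),
                    "n_gene_significant": len(r),
                    "support": len(f) + len(r),
                    "sign": sign,
                    "sign_consistency": consistency,
                    "reciprocal": bool(len(f) > 0 and len(r) > 0),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_module", "metab_module", "n_metab_significant",
            "n_gene_significant", "support", "sign", "sign_consistency", "reciprocal",
        ],
    )
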