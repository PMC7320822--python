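"""Gene prioritization by Fisher's combined probability test.

Five evidence channels per gene:

1. kME p-value against the gene's own co-expression module;
2-4. raw factorial-ANOVA p-values for location, variety and stage;
5. the best (minimum) p-value of the gene's correlation with any
   metabolite-module eigengene.

Fisher's statistic X^2 = -2 sum ln p_i is referred to a chi-square with
2k degrees of freedom (k = number of available channels; a gene missing a
channel is combined over the rest with reduced df). The final score is
-log10(combined p); genes are ranked by descending score with lexicographic
id tie-breaking. Raw (not BH-adjusted) DE p-values are combined by default:
adjusted p-values are not uniform under the null, which Fisher's method
assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import GREY, ModuleSet
from .differential import DeTable
from .integrate import IntegrationResult
from .io import ValidationError

log = logging.getLogger(__name__)

CHANNELS = ("p_kme_own", "p_de_location", "p_de_variety", "p_de_stage", "p_metab_best")


def fisher_combine(p: np.ndarray, eps: float = 1e-300) -> tuple[float, int, float]:
    """Fisher's method: X^2 = -2 sum ln p_i ~ chi-square with df = 2k."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    p = np.clip(p, eps, 1.0)
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return x2, df, float(stats.chi2.sf(x2, df))


def assemble_evidence_pvalues(
    de: DeTable,
    modules: ModuleSet,
    integration: IntegrationResult,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """One row per gene in the evidence universe (assigned to a non-grey
    module AND present in the DE table) with the five channel p-values and
    the available-channel count k."""
    if modules.kme_p is None:
        raise ValidationError("module set lacks kME p-values")
    assigned = modules.assignment[modules.assignment != GREY]
    universe = [g for g in assigned.index if g in de.table.index]
    dropped = len(assigned) - len(universe)
    if dropped:
        log.info("%d module genes absent from the DE table were excluded", dropped)
    if not universe:
        raise ValidationError("empty evidence universe")

    best_metab = (
        integration.table.groupby("feature_id")["p"].min()
        if len(integration.table)
        else pd.Series(dtype=float)
    )

    prefix = "padj_" if use_adjusted else "p_"
    rows = []
    for g in universe:
        own = assigned[g]
        rec = {
            "gene_id": g,
            "module": own,
            "p_kme_own": float(modules.kme_p.loc[g, own]),
            "p_de_location": float(de.table.loc[g, f"{prefix}location"]),
            "p_de_variety": float(de.table.loc[g, f"{prefix}variety"]),
            "p_de_stage": float(de.table.loc[g, f"{prefix}stage"]),
            "p_metab_best": float(best_metab.get(g, np.nan)),
        }
        rec["k"] = int(sum(not np.isnan(rec[c]) for c in CHANNELS))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


def rank_genes(evidence: pd.DataFrame) -> pd.DataFrame:
    """Combine the channels per gene, score = -log10(combined p), rank by
    descending score with deterministic id tie-breaking."""
    if evidence.empty:
        raise ValidationError("empty evidence table")
    x2s, dfs = [], []
    for g, row in evidence.iterrows():
        x2, df, _ = fisher_combine(row[list(CHANNELS)].to_numpy(dtype=float))
        x2s.append(x2)
        dfs.append(df)
    out = evidence.copy()
    out["x2"] = x2s
    out["df"] = dfs
    # score from the log survival function: stays exact where the combined p
    # itself would underflow
    logsf = stats.chi2.logsf(out["x2"].to_numpy(), out["df"].to_numpy())
    out["p_combined"] = np.maximum(np.exp(logsf), 1e-300)
    out["score"] = -logsf / np.log(10.0)
    out = (
        out.reset_index()
        .sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
        .set_index("gene_id")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_genes(ranked: pd.DataFrame, n: int = 50) -> pd.DataFrame:
    return ranked.nsmallest(n, "rank")
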