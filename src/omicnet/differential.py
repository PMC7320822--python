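"""Per-feature full factorial ANOVA and differential-feature calling.

The model for each feature's log2 abundance y is

    y = mu + variety + location + stage
           + variety:location + variety:stage + location:stage
           + variety:location:stage + error

fitted by least squares with sum-to-zero contrasts. Term sums of squares are
Type III (residual-SS increase when the term's columns are dropped from the
full model); on balanced designs this equals the classical orthogonal
decomposition. The fit is vectorized: the design matrix and its QR bases are
built once and applied to all features simultaneously.

Differential features are those with a BH-adjusted term p-value below alpha
AND a fold change of at least ``sd_mult`` standard deviations of the
all-feature fold-change distribution for that factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import adjust_bh
from .io import FACTORS, FeatureMatrix, SampleDesign, ValidationError

log = logging.getLogger(__name__)

TERMS = (
    "variety",
    "location",
    "stage",
    "variety:location",
    "variety:stage",
    "location:stage",
    "variety:location:stage",
)


def _sum_contrast(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n_levels - 1 columns."""
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        out[codes == j, j] = 1.0
        out[codes == n_levels - 1, j] = -1.0
    return out


def _design_matrix(design: SampleDesign) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Full-model matrix (intercept first) and per-term column indices."""
    main: dict[str, np.ndarray] = {}
    for f in FACTORS:
        levels = design.levels(f)
        codes = np.array([levels.index(x) for x in design.table[f]])
        main[f] = _sum_contrast(codes, len(levels))

    blocks: list[np.ndarray] = [np.ones((len(design.sample_ids), 1))]
    term_cols: dict[str, np.ndarray] = {}
    start = 1
    for term in TERMS:
        parts = term.split(":")
        block = main[parts[0]]
        for p in parts[1:]:
            block = np.einsum("ni,nj->nij", block, main[p]).reshape(block.shape[0], -1)
        blocks.append(block)
        term_cols[term] = np.arange(start, start + block.shape[1])
        start += block.shape[1]
    return np.hstack(blocks), term_cols


def _rss(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual SS of every row of Y against the column span of Q (orthonormal)."""
    proj = Y @ Q
    return (Y**2).sum(axis=1) - (proj**2).sum(axis=1)


@dataclass
class AnovaResults:
    """Per-feature ANOVA decomposition: one row per feature in each table."""

    sum_sq: pd.DataFrame    # columns: TERMS + "residual"
    df: pd.Series           # index: TERMS + "residual"
    F: pd.DataFrame         # columns: TERMS
    p: pd.DataFrame         # columns: TERMS
    grand_mean: pd.Series


def fit_factorial_anova(fm: FeatureMatrix, design: SampleDesign) -> AnovaResults:
    design.check_for_anova()
    fm = _aligned(fm, design)
    Y = fm.values
    n = Y.shape[1]

    X, term_cols = _design_matrix(design)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            "design matrix is rank deficient (empty design cells?); "
            "every variety x location x stage cell needs at least one sample"
        )
    df_res = n - X.shape[1]
    if df_res < 1:
        raise ValidationError("model saturated: replicates required for a residual df >= 1")

    counts = design.table.groupby(list(FACTORS), observed=True).size()
    if counts.nunique() > 1:
        log.warning("unbalanced design: using Type-III sums of squares")

    Q_full, _ = np.linalg.qr(X)
    rss_full = _rss(Y, Q_full)

    sum_sq = {}
    for term in TERMS:
        keep = np.setdiff1d(np.arange(X.shape[1]), term_cols[term])
        Q_red, _ = np.linalg.qr(X[:, keep])
        sum_sq[term] = np.maximum(_rss(Y, Q_red) - rss_full, 0.0)
    sum_sq["residual"] = np.maximum(rss_full, 0.0)

    df = pd.Series(
        {term: len(term_cols[term]) for term in TERMS} | {"residual": df_res}, dtype=int
    )
    ss = pd.DataFrame(sum_sq, index=fm.feature_ids)

    ms_res = ss["residual"].to_numpy() / df_res
    F = {}
    p = {}
    scale = np.maximum((Y**2).sum(axis=1), 1.0)
    zero_res = ms_res < 1e-14 * scale / n
    for term in TERMS:
        ms_term = ss[term].to_numpy() / df[term]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ms_term / ms_res
        p_term = stats.f.sf(f_stat, df[term], df_res)
        if zero_res.any():
            # zero residual variance: any effect SS > 0 is infinitely significant
            has_effect = ss[term].to_numpy() > 0
            f_stat = np.where(zero_res & has_effect, np.inf, f_stat)
            p_term = np.where(zero_res & has_effect, 0.0, p_term)
            p_term = np.where(zero_res & ~has_effect, np.nan, p_term)
            if (zero_res & ~has_effect).any():
                log.warning("features with zero residual and zero effect SS: p set to NaN")
        F[term] = f_stat
        p[term] = p_term

    return AnovaResults(
        sum_sq=ss,
        df=df,
        F=pd.DataFrame(F, index=fm.feature_ids),
        p=pd.DataFrame(p, index=fm.feature_ids),
        grand_mean=pd.Series(Y.mean(axis=1), index=fm.feature_ids, name="grand_mean"),
    )


def _aligned(fm: FeatureMatrix, design: SampleDesign) -> FeatureMatrix:
    from .io import align_to_design

    return align_to_design(fm, design)


def compute_group_fold_changes(
    fm: FeatureMatrix, design: SampleDesign, factor: str
) -> pd.Series:
    """Max |difference of level means| (log2 units) per feature, where level
    means are unweighted averages of cell means over the other two factors."""
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}")
    if design.n_levels(factor) < 2:
        raise ValidationError(f"factor {factor!r} has a single level")
    fm = _aligned(fm, design)
    cells = design.table.groupby(list(FACTORS), observed=True).indices

    level_means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    fpos = FACTORS.index(factor)
    for cell, idx in cells.items():
        lvl = cell[fpos]
        cell_mean = fm.values[:, idx].mean(axis=1)
        level_means[lvl] = level_means.get(lvl, 0.0) + cell_mean
        counts[lvl] = counts.get(lvl, 0) + 1
    means = np.stack([level_means[l] / counts[l] for l in sorted(counts)], axis=1)
    fc = np.zeros(fm.n_features)
    for i, j in combinations(range(means.shape[1]), 2):
        fc = np.maximum(fc, np.abs(means[:, i] - means[:, j]))
    return pd.Series(fc, index=fm.feature_ids, name=f"fc_{factor}")


@dataclass
class DeTable:
    """Per feature x factor: raw p, BH-adjusted p, fold change, DE flag."""

    table: pd.DataFrame  # columns p_<f>, padj_<f>, fc_<f>, de_<f> per factor
    alpha: float
    sd_mult: float
    fc_thresholds: dict[str, float]

    def de_features(self, factor: str) -> set[str]:
        return set(self.table.index[self.table[f"de_{factor}"]])

    def summary(self) -> dict:
        counts = {f: int(self.table[f"de_{f}"].sum()) for f in FACTORS}
        union: set[str] = set()
        for f in FACTORS:
            union |= self.de_features(f)
        overlaps = {
            f"{a}&{b}": len(self.de_features(a) & self.de_features(b))
            for a, b in combinations(FACTORS, 2)
        }
        return {
            "counts": counts,
            "union": len(union),
            "overlaps": overlaps,
            "all_three": len(
                self.de_features("variety")
                & self.de_features("location")
                & self.de_features("stage")
            ),
        }


def select_differential_features(
    p: pd.DataFrame,
    fc: pd.DataFrame,
    alpha: float = 0.01,
    sd_mult: float = 2.0,
) -> DeTable:
    """BH-adjust raw per-factor ANOVA p across features; call a feature DE for
    a factor when adjusted p < alpha and its fold change is at least
    ``sd_mult`` x SD of that factor's all-feature fold-change distribution."""
    if len(p) == 0:
        raise ValidationError("empty feature universe")
    if not p.index.equals(fc.index):
        raise ValidationError("p and fold-change tables cover different features")
    cols: dict[str, object] = {}
    thresholds: dict[str, float] = {}
    for f in FACTORS:
        raw = p[f].to_numpy()
        padj = adjust_bh(raw)
        fcs = fc[f"fc_{f}"].to_numpy()
        thr = sd_mult * float(np.std(fcs))
        thresholds[f] = thr
        cols[f"p_{f}"] = raw
        cols[f"padj_{f}"] = padj
        cols[f"fc_{f}"] = fcs
        cols[f"de_{f}"] = (padj < alpha) & (fcs >= thr)
    return DeTable(pd.DataFrame(cols, index=p.index), alpha, sd_mult, thresholds)
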