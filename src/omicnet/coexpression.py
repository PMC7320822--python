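"""Weighted co-expression network construction and module detection.

The network is an unsigned weighted graph: a_ij = |cor(x_i, x_j)|^beta, with
beta chosen to approximate scale-free topology (default 7 for both omics
layers). Topological overlap (TOM) re-weights each pair by its shared
neighbourhood:

    TOM_ij = (sum_u a_iu a_uj - a_ij^2 + a_ij) / (min(k_i, k_j) + 1 - a_ij)

(the sum runs over all u, so subtracting the u=i and u=j contributions
a_ii a_ij + a_ij a_jj = 2 a_ij leaves sum_{u != i,j} a_iu a_uj; with unit
diagonal the numerator above is the matrix product minus a_ij). Modules are
branches of an average-linkage tree on 1 - TOM, cut at the midpoint of the
largest gap in merge heights (a static quantile cut is available but saturates
when many background features merge at heights near 1). Each module is
summarized by its eigengene — the first principal component of the
standardized member profiles — and every feature gets a module membership
kME = cor(feature, eigengene) with a t-test p-value.

Module names follow the size-ranked colour convention (largest = turquoise);
unassigned features are "grey".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._stats import correlation_pvalues, pearson_matrix_matrix
from .io import FeatureMatrix, ValidationError

log = logging.getLogger(__name__)

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)
GREY = "grey"

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class CoexpressionNetwork:
    beta: float
    feature_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray | None = None

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1) - 1.0


@dataclass
class ModuleSet:
    assignment: pd.Series                       # feature id -> module colour (or grey)
    eigengenes: pd.DataFrame | None = None      # samples x modules, unit variance
    kme: pd.DataFrame | None = None             # features x modules
    kme_p: pd.DataFrame | None = None
    cut_height: float | None = None

    @property
    def module_names(self) -> list[str]:
        sizes = self.assignment[self.assignment != GREY].value_counts()
        return sizes.index.tolist()

    def members(self, module: str) -> list[str]:
        return self.assignment.index[self.assignment == module].tolist()


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit: regress log10(frequency) on log10(mean k) over
    equal-width connectivity bins (empty bins dropped); returns
    (-sign(slope) * R^2, slope)."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or k.max() == k.min():
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = float(((np.array(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.array(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2, slope


def pick_soft_threshold(
    fm: FeatureMatrix,
    powers: tuple[float, ...] = DEFAULT_POWERS,
    r2_min: float = 0.8,
    default_beta: float = 7.0,
) -> tuple[pd.DataFrame, float]:
    """Scale-free topology diagnostic per candidate power; the chosen beta is
    the smallest power whose signed fit reaches ``r2_min``, else
    ``default_beta`` with a warning."""
    if fm.n_features < 50:
        log.warning("soft-threshold diagnostics unreliable below 50 features")
    absr = np.abs(np.corrcoef(fm.values))
    np.fill_diagonal(absr, 1.0)
    rows = []
    for b in powers:
        a = absr**b
        k = a.sum(axis=1) - 1.0
        if np.allclose(k, 0):
            raise ValidationError("all connectivities are zero")
        fit, slope = scale_free_fit_index(k)
        rows.append(
            {"power": b, "sft_r2": fit, "slope": slope,
             "mean_k": float(k.mean()), "max_k": float(k.max())}
        )
    table = pd.DataFrame(rows)
    ok = table[table["sft_r2"] >= r2_min]
    if len(ok):
        beta = float(ok["power"].iloc[0])
    else:
        beta = float(default_beta)
        log.warning(
            "no power reached scale-free fit %.2f; falling back to beta=%g", r2_min, beta
        )
    return table, beta


def compute_adjacency(fm: FeatureMatrix, beta: float) -> CoexpressionNetwork:
    """Unsigned adjacency a_ij = |Pearson r|^beta with unit diagonal."""
    if fm.n_samples < 3:
        raise ValidationError("need >=3 samples to build a co-expression network")
    if beta <= 0:
        raise ValidationError("beta must be positive")
    sds = fm.values.std(axis=1)
    if (sds == 0).any():
        offenders = [fm.feature_ids[i] for i in np.flatnonzero(sds == 0)[:5]]
        raise ValidationError(f"zero-variance features (remove first): {offenders}")
    a = np.abs(np.corrcoef(fm.values)) ** beta
    np.fill_diagonal(a, 1.0)
    return CoexpressionNetwork(beta=beta, feature_ids=fm.feature_ids, adjacency=a)


def compute_tom(net: CoexpressionNetwork) -> CoexpressionNetwork:
    a = net.adjacency
    k = a.sum(axis=1) - 1.0
    shared = a @ a - a  # entry ij: sum_{u != i,j} a_iu a_uj + a_ij  (unit diagonal)
    denom = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below; avoid 0/0
    tom = shared / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize away float noise
    net.tom = tom
    return net


def _gap_candidates(heights: np.ndarray, n_candidates: int = 10) -> list[tuple[float, float]]:
    """(gap size, midpoint) for the largest gaps in sorted merge heights."""
    hs = np.sort(heights)
    if hs.size == 1:
        return [(hs[0], float(hs[0]) / 2.0)]
    gaps = np.diff(hs)
    order = np.argsort(gaps)[::-1][:n_candidates]
    return [(float(gaps[i]), float(hs[i] + hs[i + 1]) / 2.0) for i in order]


def _choose_gap_cut(Z: np.ndarray, min_size: int) -> float:
    """Pick, among the largest merge-height gaps, the cut producing the most
    clusters of at least ``min_size`` members (ties: larger gap wins).

    A single global largest gap is not reliable: tight clumps of
    near-duplicate features create spuriously large gaps at low heights, and
    background-dominated trees push most merges to heights near 1. Scoring a
    handful of candidate gaps by the module count they induce is cheap and
    deterministic.
    """
    best = None
    for gap, cut in _gap_candidates(Z[:, 2]):
        labels = fcluster(Z, t=cut, criterion="distance")
        n_modules = int((pd.Series(labels).value_counts() >= min_size).sum())
        key = (n_modules, gap)
        if best is None or key > best[0]:
            best = (key, cut)
    return best[1]


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 30,
    cut_height: float | None = None,
    cut_quantile: float | None = None,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM; branches below the cut height
    with >= min_size members become modules, named by decreasing size."""
    if net.tom is None:
        raise ValidationError("TOM not computed; call compute_tom first")
    n = len(net.feature_ids)
    if min_size > n:
        log.warning("min_size %d exceeds feature count %d: everything grey", min_size, n)
        return ModuleSet(pd.Series(GREY, index=net.feature_ids), cut_height=None)
    Z = linkage(squareform(1.0 - net.tom, checks=False), method="average")
    if cut_height is None:
        if cut_quantile is not None:
            cut_height = float(np.quantile(Z[:, 2], cut_quantile))
        else:
            cut_height = _choose_gap_cut(Z, min_size)
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].sort_values(ascending=False)
    names: dict[int, str] = {}
    for rank, cluster_id in enumerate(keep.index):
        names[cluster_id] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        )
    labels = [names.get(c, GREY) for c in raw]
    assignment = pd.Series(labels, index=net.feature_ids, name="module")
    if not keep.size:
        log.warning("no cluster reached min_size=%d; everything grey", min_size)
    return ModuleSet(assignment, cut_height=cut_height)


def compute_eigengenes(fm: FeatureMatrix, modules: ModuleSet) -> ModuleSet:
    """First principal component of each module's standardized member rows,
    scaled to unit variance and oriented so the mean member correlation is
    non-negative."""
    if not modules.module_names:
        raise ValidationError("no modules to summarize")
    profiles = {}
    for mod in modules.module_names:
        members = [f for f in modules.members(mod) if f in fm.data.index]
        if not members:
            raise ValidationError(f"module {mod!r} has no members in the matrix")
        if len(members) == 1:
            log.info("module %s has a single member; eigengene = its z-profile", mod)
        X = fm.data.loc[members].to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        # first right-singular vector = PC1 across samples
        _, _, vt = np.linalg.svd(Xs, full_matrices=False)
        me = vt[0]
        me = me / me.std()
        r = pearson_matrix_matrix(Xs, me[None, :])[:, 0]
        if r.mean() < 0:
            me = -me
        profiles[mod] = me
    modules.eigengenes = pd.DataFrame(profiles, index=fm.sample_ids)
    return modules


def compute_kme(fm: FeatureMatrix, modules: ModuleSet) -> ModuleSet:
    """kME(f, m) = cor(feature f, eigengene m) with two-sided t-test p-values."""
    if modules.eigengenes is None:
        raise ValidationError("eigengenes not computed")
    n = fm.n_samples
    if n < 4:
        raise ValidationError("kME p-values need >=4 samples")
    E = modules.eigengenes.to_numpy().T  # modules x samples
    r = pearson_matrix_matrix(fm.values, E)
    p = correlation_pvalues(r, n)
    cols = modules.eigengenes.columns
    modules.kme = pd.DataFrame(r, index=fm.feature_ids, columns=cols)
    modules.kme_p = pd.DataFrame(p, index=fm.feature_ids, columns=cols)
    return modules


def build_modules(
    fm: FeatureMatrix,
    beta: float = 7.0,
    min_size: int = 30,
    cut_height: float | None = None,
    cut_quantile: float | None = None,
) -> tuple[CoexpressionNetwork, ModuleSet]:
    """Convenience: adjacency -> TOM -> modules -> eigengenes -> kME."""
    net = compute_tom(compute_adjacency(fm, beta))
    modules = detect_modules(net, min_size=min_size, cut_height=cut_height,
                             cut_quantile=cut_quantile)
    if modules.module_names:
        modules = compute_kme(fm, compute_eigengenes(fm, modules))
    return net, modules
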