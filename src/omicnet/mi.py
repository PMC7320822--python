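"""Regulator-centred mutual information networks with DPI pruning.

MI between two profiles is the plug-in estimate on an equal-frequency
(rank-based) 2-D binning: with B bins per margin each holding n/B samples,

    MI = sum_ij p(i,j) ln( p(i,j) / (p(i) p(j)) )   [nats]

(B defaults to floor(sqrt(n/5)), minimum 2). Because binning is rank-based,
the null distribution of MI between independent profiles depends only on
(n, B): a significance threshold for any target tail probability is obtained
by permutation, fitting an exponential to the upper tail of the null and
extrapolating. Tail probabilities far beyond permutation reach (the
conventional network threshold is 1e-8) are reached by that extrapolation;
the calibration itself is verifiable at reachable levels (e.g. 1e-3).

Indirect edges are pruned with the data processing inequality (DPI): in any
fully connected triplet the weakest edge is presumed indirect and flagged as
removed (its MI value is retained for inspection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .io import FeatureMatrix, ValidationError

log = logging.getLogger(__name__)


def default_bins(n_samples: int) -> int:
    """Default bin count: the plug-in estimator's bias on independent data is
    approximately (B - 1)^2 / 2n nats, so B grows like sqrt(n) but slowly
    enough to keep that bias well below 0.05 nats at practical sample sizes."""
    return max(2, int(np.sqrt(n_samples) / 3.0))


def _equal_freq_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based bin index per sample; ties broken by original order so the
    binning is deterministic."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * bins) // x.size


def _mi_binned(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    n = bx.size
    joint = np.bincount(bx * bins + by, minlength=bins * bins).astype(float) / n
    px = joint.reshape(bins, bins).sum(axis=1)
    py = joint.reshape(bins, bins).sum(axis=0)
    mi = float(xlogy(joint, joint).sum() - xlogy(px, px).sum() - xlogy(py, py).sum())
    return max(mi, 0.0)


def estimate_mi(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Plug-in MI (nats) on equal-frequency bins. Symmetric and >= 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    if x.size < 8:
        raise ValidationError("MI estimation needs >= 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector: MI defined as 0")
        return 0.0
    B = bins or default_bins(x.size)
    return _mi_binned(_equal_freq_bins(x, B), _equal_freq_bins(y, B), B)


def null_mi_sample(
    n_samples: int, bins: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null MI values for independent profiles at this (n, B): one margin's
    bin labels are fixed, the other randomly permuted."""
    bx = _equal_freq_bins(np.arange(n_samples, dtype=float), bins)
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = _mi_binned(bx, bx[rng.permutation(n_samples)], bins)
    return out


def calibrate_mi_threshold(
    n_samples: int,
    bins: int | None = None,
    p_target: float = 1e-8,
    n_perm: int = 100_000,
    seed: int = 0,
    tail_frac: float = 0.05,
) -> float:
    """MI cutoff whose null tail probability is ``p_target``.

    The permutation null is generated at (n, B); an exponential is fitted to
    the excesses over the (1 - tail_frac) quantile and the threshold is read
    off the fitted tail: P(MI > u + d) = tail_frac * exp(-d / mean_excess).
    """
    if n_perm < 1000:
        raise ValidationError("n_perm must be >= 1000 for a usable tail fit")
    if not (0 < p_target < 1):
        raise ValidationError("p_target must lie in (0, 1)")
    B = bins or default_bins(n_samples)
    rng = np.random.default_rng(seed)
    null = null_mi_sample(n_samples, B, n_perm, rng)
    if np.ptp(null) == 0:
        raise ValidationError("degenerate null distribution (all MI identical)")
    if p_target >= tail_frac:
        return float(np.quantile(null, 1.0 - p_target))
    u = float(np.quantile(null, 1.0 - tail_frac))
    excess = null[null > u] - u
    if excess.size == 0 or excess.mean() == 0:
        raise ValidationError("degenerate null tail")
    return u + float(excess.mean()) * np.log(tail_frac / p_target)


@dataclass
class MiNetwork:
    """Undirected regulator-target edges weighted by MI. 'Regulator' is a
    labeling from the curated list, not a causal direction."""

    edges: pd.DataFrame  # columns: regulator, target, mi, kept_after_dpi
    regulators: set[str]
    module: str
    mi_threshold: float
    bins: int

    @property
    def kept_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["kept_after_dpi"]]


def build_regulator_network(
    fm: FeatureMatrix,
    regulators: set[str] | list[str],
    threshold: float,
    bins: int | None = None,
    module: str = "",
) -> MiNetwork:
    """MI for every regulator x feature pair in the (module-restricted)
    matrix; edges kept where MI >= threshold. Regulators missing from the
    matrix are ignored with a log entry."""
    regs = [r for r in regulators if r in fm.data.index]
    dropped = sorted(set(regulators) - set(regs))
    if dropped:
        log.info("regulators absent from matrix (ignored): %s", dropped[:10])
    B = bins or default_bins(fm.n_samples)
    rows = []
    if not regs:
        log.warning("no regulators present in the feature universe: empty network")
    else:
        binned = {
            f: _equal_freq_bins(fm.data.loc[f].to_numpy(), B) for f in fm.feature_ids
        }
        seen: set[frozenset] = set()
        for reg in regs:
            for feat in fm.feature_ids:
                if feat == reg:
                    continue
                key = frozenset((reg, feat))
                if key in seen:  # both endpoints regulators: one undirected edge
                    continue
                seen.add(key)
                mi = _mi_binned(binned[reg], binned[feat], B)
                if mi >= threshold:
                    rows.append({"regulator": reg, "target": feat, "mi": mi})
    edges = pd.DataFrame(rows, columns=["regulator", "target", "mi"])
    edges["kept_after_dpi"] = True
    edges = edges.sort_values(["regulator", "target"], ignore_index=True)
    return MiNetwork(edges, set(regs), module, threshold, B)


def apply_dpi(net: MiNetwork, tolerance: float = 0.0) -> MiNetwork:
    """Flag the weakest edge of every fully connected triplet as indirect
    when its MI < (1 - tolerance) * min(other two). Idempotent; MI values
    are retained."""
    edges = net.edges
    mi_of: dict[frozenset, float] = {}
    neighbours: dict[str, set[str]] = {}
    for row in edges.itertuples(index=False):
        mi_of[frozenset((row.regulator, row.target))] = row.mi
        neighbours.setdefault(row.regulator, set()).add(row.target)
        neighbours.setdefault(row.target, set()).add(row.regulator)

    removed: set[frozenset] = set()
    for key, mi_ab in mi_of.items():
        a, b = sorted(key)
        for c in neighbours.get(a, set()) & neighbours.get(b, set()):
            mi_ac = mi_of[frozenset((a, c))]
            mi_bc = mi_of[frozenset((b, c))]
            if mi_ab < (1.0 - tolerance) * min(mi_ac, mi_bc):
                removed.add(key)
                break
    kept = [
        frozenset((r, t)) not in removed
        for r, t in zip(edges["regulator"], edges["target"])
    ]
    new_edges = edges.assign(kept_after_dpi=np.array(kept, dtype=bool))
    return MiNetwork(new_edges, net.regulators, net.module, net.mi_threshold, net.bins)
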