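"""Over-representation analysis of pathway sets in a selected feature list.

One-sided Fisher's exact test (equivalently the hypergeometric upper tail)
per set against a declared universe, with Benjamini-Hochberg FDR across all
tested sets; FDR < 0.05 is called significant by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import adjust_bh
from .io import PathwaySets, ValidationError

log = logging.getLogger(__name__)


def fisher_enrichment(
    selected: set[str],
    universe: set[str],
    pathways: PathwaySets,
    fdr_threshold: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Enrichment of each pathway set in ``selected`` relative to ``universe``.

    Pathway members are intersected with the universe before testing; sets
    with no members in the universe are skipped with a log entry.
    """
    offenders = selected - universe
    if offenders:
        raise ValidationError(
            f"selected features outside the universe: {sorted(offenders)[:5]}"
        )
    if alternative not in ("greater", "two-sided"):
        raise ValidationError("alternative must be 'greater' or 'two-sided'")
    N = len(universe)
    n_sel = len(selected)
    rows = []
    for name in sorted(pathways.sets):
        members = pathways.sets[name] & universe
        if not members:
            log.info("pathway %r has no members in the universe; skipped", name)
            continue
        k = len(members & selected)
        n_set = len(members)
        table = [
            [k, n_sel - k],
            [n_set - k, N - n_set - n_sel + k],
        ]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append(
            {
                "set_name": name,
                "description": pathways.descriptions.get(name, ""),
                "n_universe": N,
                "n_set": n_set,
                "n_selected": n_sel,
                "n_overlap": k,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "description", "n_universe", "n_set", "n_selected",
                 "n_overlap", "odds_ratio", "p"],
    )
    if len(out):
        out["fdr"] = adjust_bh(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
        out = out.sort_values(["p", "set_name"], ignore_index=True)
    else:
        out["fdr"] = np.array([], dtype=float)
        out["significant"] = np.array([], dtype=bool)
    return out
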