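"""Docking-score aggregation.

Consumes externally produced compound x target grids of best-pose binding
energies (kcal/mol, more negative = more favorable) and summarizes them:
strongest binder per target, the conventional -5.00 kcal/mol biological
relevance cutoff, and best-pose selection under an RMSD constraint.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = ["best_per_target", "relevance_flags", "RelevanceReport",
           "select_best_pose", "to_long", "DEFAULT_RELEVANCE_CUTOFF",
           "DEFAULT_RMSD_MAX"]

#: Conventional cutoff for biologically relevant binding.
DEFAULT_RELEVANCE_CUTOFF = -5.0
#: Community convention for acceptable pose RMSD (Angstrom).
DEFAULT_RMSD_MAX = 2.0


def _as_matrix(m) -> pd.DataFrame:
    df = pd.DataFrame(m)
    if df.size == 0:
        raise ValidationError("empty docking matrix")
    vals = df.to_numpy(dtype=float)
    if np.any(np.isinf(vals)):
        raise ValidationError("docking energies must be finite (NaN = missing)")
    return df.astype(float)


def best_per_target(m) -> pd.DataFrame:
    """Minimum (most favorable) score per target with the tied compound list.

    Rows are targets; ``compounds`` lists every compound achieving the
    minimum. All-missing columns are reported with a NaN score and an empty
    tie list.
    """
    df = _as_matrix(m)
    rows = []
    for target in df.columns:
        col = df[target].dropna()
        if col.empty:
            rows.append({"target": target, "score": np.nan, "compounds": ()})
            continue
        best = col.min()
        ties = tuple(sorted(col.index[col == best]))
        rows.append({"target": target, "score": float(best),
                     "compounds": ties})
    return pd.DataFrame(rows).set_index("target")


@dataclass
class RelevanceReport:
    """Pairwise and per-compound relevance under an energy cutoff."""

    cutoff: float
    pair_flags: pd.DataFrame
    compound_flags: pd.Series

    @property
    def relevant_compounds(self) -> list[str]:
        return list(self.compound_flags.index[self.compound_flags])


def relevance_flags(m, cutoff: float = DEFAULT_RELEVANCE_CUTOFF,
                    ) -> RelevanceReport:
    """Flag compound-target pairs with score <= cutoff and compounds that
    are relevant for at least one target."""
    if cutoff >= 0:
        raise ConfigurationError("relevance cutoff must be negative")
    df = _as_matrix(m)
    pair = df.le(cutoff)
    pair = pair.where(df.notna(), other=False)
    return RelevanceReport(cutoff=cutoff, pair_flags=pair,
                           compound_flags=pair.any(axis=1))


def select_best_pose(poses: Sequence[tuple[float, float]],
                     rmsd_max: float = DEFAULT_RMSD_MAX,
                     ) -> tuple[float, float]:
    """Lowest-energy pose among those with RMSD <= rmsd_max.

    If no pose satisfies the constraint, the overall lowest-energy pose is
    returned with a warning.
    """
    poses = [(float(e), float(r)) for e, r in poses]
    if not poses:
        raise ValidationError("empty pose list")
    ok = [p for p in poses if p[1] <= rmsd_max]
    if not ok:
        warnings.warn("no pose satisfies the RMSD constraint; falling back "
                      "to the lowest-energy pose", stacklevel=2)
        ok = poses
    return min(ok, key=lambda p: (p[0], p[1]))


def to_long(m) -> pd.DataFrame:
    """Long-format (compound, target, score) export for heatmap plotting."""
    df = _as_matrix(m)
    out = (df.rename_axis(index="compound", columns="target")
           .stack(future_stack=True)
           .rename("score").reset_index())
    return out
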