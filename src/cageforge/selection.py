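"""Metric normalization, weighted ranking and filter cascades."""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_COMPARATORS = {
    "<": operator.lt, "<=": operator.le,
    ">": operator.gt, ">=": operator.ge, "==": operator.eq,
}


@dataclass
class WeightTerm:
    metric: str
    direction: str   # "higher" or "lower"
    weight: float


@dataclass
class WeightScheme:
    name: str
    terms: list = field(default_factory=list)

    def validate(self):
        total = sum(t.weight for t in self.terms)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"weights of scheme {self.name!r} sum to {total}, expected 1")
        for t in self.terms:
            if t.direction not in ("higher", "lower"):
                raise ValueError(f"bad direction {t.direction!r}")
        return self


def _scheme(name, *terms) -> WeightScheme:
    return WeightScheme(name, [WeightTerm(*t) for t in terms]).validate()


# Both published weighting schemes ship as named built-ins.
BUILTIN_SCHEMES = {
    "t33fn-pose": _scheme(
        "t33fn-pose",
        ("sc_fragment", "higher", 0.3),
        ("composition_similarity", "higher", 0.4),
        ("percent_fragment", "higher", 0.1),
        ("percent_hydrophobic_bsa", "lower", 0.2)),
    "t33fn-design": _scheme(
        "t33fn-design",
        ("interface_energy", "lower", 0.25),
        ("bound_configuration_energy", "lower", 0.15),
        ("atomic_density", "higher", 0.2),
        ("buried_unsat_density", "lower", 0.15),
        ("shape_complementarity", "higher", 0.1),
        ("bsa_sasa_ratio", "lower", 0.15)),
}

# The T33-ml candidate filter cascade; externally supplied metrics
# (neural-network scores, the multiple-fragment ratio) are pass-through
# columns, never computed here.
T33_ML_FILTERS = [
    ("new_collapse_sites", "==", 0),
    ("mutation_fraction", "<", 0.55),
    ("multiple_fragment_ratio", ">", 2.5),
    ("fragment_observations", ">", 20),
    ("proteinmpnn_score_unbound_total", "<", 880),
    ("proteinmpnn_score_complex_designed", "<", 1),
    ("evolution_profile_loss", "<", 2.5),
    ("fragment_profile_loss", "<", 5),
    ("spike_ratio", "<", 0.5),
]


# ---------------------------------------------------------------------------
# Normalization and ranking
# ---------------------------------------------------------------------------

def normalize(table: pd.DataFrame, directions=None) -> pd.DataFrame:
    """Per-column min-max scaling to [0, 1].

    Lower-is-better columns (per ``directions``) are flipped so that 1 is
    always best; constant columns map to 0.5; missing values receive the
    column median before scaling (flagged via a warning).  Raw columns are
    never modified.
    """
    directions = directions or {}
    out = {}
    for col in table.columns:
        series = pd.to_numeric(table[col], errors="coerce")
        if series.isna().all():
            log.warning("column %r is entirely missing; excluded", col)
            continue
        if series.isna().any():
            log.warning("column %r has missing values imputed with the median", col)
            series = series.fillna(series.median())
        lo, hi = series.min(), series.max()
        if hi - lo < 1e-300:
            scaled = pd.Series(0.5, index=series.index)
        else:
            scaled = (series - lo) / (hi - lo)
        if directions.get(col) == "lower":
            scaled = 1.0 - scaled
        out[col] = scaled
    return pd.DataFrame(out, index=table.index)


def weighted_rank(table: pd.DataFrame, scheme: WeightScheme) -> pd.DataFrame:
    """Rank rows by the weighted sum of normalized metric values.

    Returns a copy of the table ordered by descending score (row id breaks
    ties) with a ``selection_score`` column appended.
    """
    scheme.validate()
    missing = [t.metric for t in scheme.terms if t.metric not in table.columns]
    if missing:
        raise KeyError(f"scheme metrics absent from table: {missing}")
    directions = {t.metric: t.direction for t in scheme.terms}
    normed = normalize(table[[t.metric for t in scheme.terms]], directions)
    score = sum(t.weight * normed[t.metric] for t in scheme.terms)
    ranked = table.copy()
    ranked["selection_score"] = score
    ranked = ranked.sort_values(
        by="selection_score", ascending=False, kind="mergesort")
    # mergesort is stable, so equal scores keep row order (row-id tie-break)
    return ranked


def apply_filters(table: pd.DataFrame, filters) -> tuple[pd.DataFrame, list]:
    """Conjunction of (metric, comparator, threshold) filters.

    Returns the surviving rows and an attrition log recording how many rows
    each filter removed, in order.
    """
    surviving = table
    attrition = []
    for metric, op, threshold in filters:
        if metric not in surviving.columns:
            raise KeyError(f"unknown metric in filter: {metric!r}")
        if op not in _COMPARATORS:
            raise ValueError(f"unsupported comparator: {op!r}")
        before = len(surviving)
        values = pd.to_numeric(surviving[metric], errors="coerce")
        mask = _COMPARATORS[op](values, threshold).fillna(False)
        surviving = surviving[mask]
        attrition.append({"metric": metric, "op": op, "threshold": threshold,
                          "removed": before - len(surviving),
                          "remaining": len(surviving)})
    return surviving, attrition
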