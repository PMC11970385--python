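"""Marker subpopulation fractions from per-particle tables.

Downstream arithmetic for super-resolution (dSTORM) single-vesicle
data: given a table of particles with boolean marker positivity, the
particle universe is defined by a reference marker (e.g. the
tetraspanin-trio stain marking all EVs), and every combination of the
remaining markers is reported as a percentage of reference-positive
particles. Percentages are computed on raw counts, so a partition sums
to exactly 100 and the identity

    conditional_fraction x conditioning marginal == joint percentage

holds exactly on counts.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["subpopulation_percentages", "conditional_fraction"]


def _marker_columns(table: pd.DataFrame, exclude: tuple[str, ...]) -> list[str]:
    return [c for c in table.columns
            if c not in exclude and c != "particle_id"]


def _validate(table: pd.DataFrame, markers: list[str]) -> None:
    for m in markers:
        col = table[m]
        if col.isna().any():
            raise ValueError(f"marker column {m!r} contains missing values")
        if not set(col.unique()) <= {True, False, 0, 1}:
            raise ValueError(f"marker column {m!r} is not boolean")


def subpopulation_percentages(table: pd.DataFrame,
                              reference_marker: str) -> pd.DataFrame:
    """Percentage of every marker combination among reference+ particles.

    Returns one row per combination of the non-reference markers with
    columns ``count`` and ``percent``; rows partition the
    reference-positive universe, so percentages sum to 100 (counts are
    exact; only the division is floating point). Zero-count
    combinations are included.
    """
    if reference_marker not in table.columns:
        raise ValueError(f"reference marker {reference_marker!r} not in table")
    markers = _marker_columns(table, exclude=(reference_marker,))
    _validate(table, markers + [reference_marker])
    universe = table.loc[table[reference_marker].astype(bool)]
    n_ref = len(universe)
    if n_ref == 0:
        raise ValueError(f"no {reference_marker}+ particles: universe is empty")
    if not markers:
        return pd.DataFrame({"count": [n_ref], "percent": [100.0]})
    grouped = (universe.astype({m: bool for m in markers})
               .groupby(markers, sort=True).size())
    full = pd.MultiIndex.from_product([[False, True]] * len(markers),
                                      names=markers)
    counts = grouped.reindex(full, fill_value=0)
    out = counts.rename("count").reset_index()
    out["percent"] = 100.0 * out["count"] / n_ref
    return out


def conditional_fraction(table: pd.DataFrame, target_marker: str,
                         conditioning_marker: str,
                         reference_marker: str) -> float:
    """100 x P(target+ | conditioning+, reference+).

    E.g. the percentage of L1CAM+ EVs that also carry alpha-synuclein,
    within the tetraspanin-positive universe. Raises when the
    conditioning subset is empty.
    """
    for m in (target_marker, conditioning_marker, reference_marker):
        if m not in table.columns:
            raise ValueError(f"marker {m!r} not in table")
    _validate(table, [target_marker, conditioning_marker, reference_marker])
    sub = table.loc[table[reference_marker].astype(bool)
                    & table[conditioning_marker].astype(bool)]
    if len(sub) == 0:
        raise ValueError(
            f"empty conditioning subset {conditioning_marker}+/{reference_marker}+")
    return 100.0 * sub[target_marker].astype(bool).sum() / len(sub)
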