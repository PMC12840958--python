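"""Odor activity values (OAV) and OAV-derived screens.

The OAV of compound *i* in a sample is the ratio of its content to its
odor threshold in the same medium, ``OAV_i = C_i / OT_i``; a compound
with OAV > 1 is conventionally taken to contribute perceptibly to the
aroma. OAVs are computed on cultivar-level mean contents against
thresholds in water (cooked rice being mostly water), and are undefined
for compounds without a documented threshold — those are excluded from
both numerator and denominator of every share, since "total OAV" only
exists over thresholded compounds.

Screens built on top of the matrix:

* **key odor-active compounds** — GC-O detected and OAV strictly > 1.0
  in at least one cultivar;
* **shared key odorants** — key compounds with OAV strictly > 1.0 in
  every cultivar;
* **OAV shares** — the fraction of a cultivar's total OAV carried by a
  compound subset.

All comparisons with 1.0 are strict: a boundary OAV of exactly 1.0 does
not qualify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volatile_table import CompoundTable, CultivarMeans

__all__ = [
    "OAVMatrix",
    "compute_oav",
    "oav_matrix",
    "key_odorants",
    "shared_key_odorants",
    "oav_share",
    "share_range",
]


@dataclass
class OAVMatrix:
    """Compound x cultivar odor activity values.

    ``values`` holds NaN for compounds without a documented threshold;
    ``defined`` marks the thresholded rows.
    """

    values: pd.DataFrame
    defined: pd.Series

    @property
    def cultivars(self) -> list[str]:
        return list(self.values.columns)

    @property
    def defined_compounds(self) -> list[str]:
        return list(self.defined.index[self.defined])


def compute_oav(content: float, threshold: float | None) -> float | None:
    """OAV of one compound in one sample; None when the threshold is absent."""
    if threshold is None:
        return None
    if threshold <= 0:
        raise ValueError("odor threshold must be positive")
    if content < 0:
        raise ValueError("content must be non-negative")
    return content / threshold


def oav_matrix(means: CultivarMeans, table: CompoundTable) -> OAVMatrix:
    """OAVs of every compound of ``means`` joined on compound_id.

    Rows without a documented threshold are marked undefined (NaN), not 0.
    """
    unknown = [c for c in means.compounds if c not in table]
    if unknown:
        raise ValueError(f"compounds missing from metadata table: {unknown[:5]}")
    thresholds = pd.Series(
        {c: (table[c].odor_threshold if table[c].odor_threshold is not None else np.nan)
         for c in means.compounds},
        dtype=float,
    )
    values = means.values.div(thresholds, axis=0)
    defined = thresholds.notna()
    defined.name = "defined"
    return OAVMatrix(values=values, defined=defined)


def key_odorants(oav: OAVMatrix, table: CompoundTable) -> set[str]:
    """Compounds detected by GC-O whose OAV exceeds 1.0 in >= 1 cultivar."""
    max_oav = oav.values.max(axis=1)
    return {
        c
        for c in oav.defined_compounds
        if table[c].gco_detected and max_oav[c] > 1.0
    }


def shared_key_odorants(oav: OAVMatrix, table: CompoundTable) -> set[str]:
    """Key odor-active compounds with OAV > 1.0 in *every* cultivar."""
    if not oav.cultivars:
        raise ValueError("OAV matrix has no cultivars")
    min_oav = oav.values.min(axis=1)
    return {c for c in key_odorants(oav, table) if min_oav[c] > 1.0}


def oav_share(oav: OAVMatrix, subset: set[str], cultivar: str) -> float:
    """Fraction of ``cultivar``'s total OAV carried by ``subset``.

    The total runs over all threshold-defined compounds; undefined rows
    and n.d. contents contribute nothing.
    """
    if cultivar not in oav.cultivars:
        raise ValueError(f"cultivar {cultivar!r} not in OAV matrix")
    undefined = subset - set(oav.defined_compounds)
    if undefined:
        raise ValueError(
            f"subset contains compounds without defined OAV: {sorted(undefined)[:5]}"
        )
    col = oav.values.loc[oav.defined_compounds, cultivar]
    total = float(col.sum())
    if total <= 0:
        raise ValueError(f"total OAV of cultivar {cultivar!r} is zero")
    return float(col.loc[sorted(subset)].sum()) / total if subset else 0.0


def share_range(oav: OAVMatrix, subset: set[str]) -> tuple[float, float]:
    """(min, max) of a subset's OAV share across cultivars."""
    shares = [oav_share(oav, subset, cv) for cv in oav.cultivars]
    return min(shares), max(shares)
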