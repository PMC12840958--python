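"""Synthetic replicate generator for volatile content matrices.

Emulates the statistical structure the screening pipeline assumes of
GC-MS replicate data: per-(compound, cultivar) log-normal replicate
noise around cultivar-level mean contents, a hard detection limit below
which a draw is recorded as n.d., and plantable between-group fold
changes for power and calibration studies.

The log-normal is parameterized on the *arithmetic* mean mu and
coefficient of variation cv:

    sigma_log^2 = ln(1 + cv^2),    mu_log = ln(mu) - sigma_log^2 / 2

so the generating distribution's arithmetic mean equals mu exactly, and
cv = 0 degenerates to every replicate equal to mu.

Seeding: one master seed; each (compound, cultivar) cell draws from its
own substream keyed by a stable CRC32 hash, so adding or removing a
compound never shifts another cell's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .volatile_table import ContentMatrix, CultivarMeans

__all__ = ["SynthSpec", "generate_replicates", "plant_effect"]


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic replicate draw.

    ``effects`` multiply the base mean of specific (compound, cultivar)
    cells; a multiplier of 0 knocks the compound out of that cultivar.
    """

    base_means: CultivarMeans
    cv: float = 0.05
    n_replicates: int = 3
    detection_limit: float = 1.0
    effects: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0
    distribution: str = "lognormal"  # or "normal", for t-test calibration

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError("distribution must be 'lognormal' or 'normal'")
        for cid, cultivar, mult in self.effects:
            if mult < 0:
                raise ValueError(f"effect multiplier must be >= 0, got {mult}")


def plant_effect(spec: SynthSpec, compound_id: str, cultivar: str, multiplier: float) -> SynthSpec:
    """Return a spec with ``multiplier`` applied to one mean cell."""
    if compound_id not in spec.base_means.compounds:
        raise ValueError(f"unknown compound {compound_id!r}")
    if cultivar not in spec.base_means.cultivars:
        raise ValueError(f"unknown cultivar {cultivar!r}")
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0 (0 = knock-out)")
    return replace(spec, effects=spec.effects + ((compound_id, cultivar, multiplier),))


def _cell_rng(seed: int, compound_id: str, cultivar: str) -> np.random.Generator:
    key = zlib.crc32(f"{compound_id}|{cultivar}".encode("utf-8"))
    return np.random.default_rng([seed, key])


def generate_replicates(spec: SynthSpec) -> ContentMatrix:
    """Draw a replicate-level content matrix under ``spec``.

    Identical specs (including seed) give bit-identical matrices. Draws
    below the detection limit — and cells with mean 0 — are censored to
    n.d.
    """
    means = spec.base_means.values.copy()
    for cid, cultivar, mult in spec.effects:
        means.loc[cid, cultivar] = means.loc[cid, cultivar] * mult

    cultivars = list(means.columns)
    compounds = list(means.index)
    columns = pd.MultiIndex.from_tuples(
        [(cv, r + 1) for cv in cultivars for r in range(spec.n_replicates)],
        names=["cultivar", "replicate"],
    )
    values = pd.DataFrame(0.0, index=compounds, columns=columns)
    detected = pd.DataFrame(False, index=compounds, columns=columns)

    sigma2 = np.log1p(spec.cv**2)
    sigma = np.sqrt(sigma2)
    for cid in compounds:
        for cultivar in cultivars:
            mu = float(means.loc[cid, cultivar])
            if mu <= 0:
                continue  # stays n.d.
            rng = _cell_rng(spec.seed, cid, cultivar)
            if spec.cv == 0:
                draws = np.full(spec.n_replicates, mu)
            elif spec.distribution == "lognormal":
                draws = rng.lognormal(np.log(mu) - sigma2 / 2.0, sigma, spec.n_replicates)
            else:
                draws = rng.normal(mu, spec.cv * mu, spec.n_replicates)
                draws = np.clip(draws, 0.0, None)
            keep = draws >= spec.detection_limit
            values.loc[cid, (cultivar, slice(None))] = np.where(keep, draws, 0.0)
            detected.loc[cid, (cultivar, slice(None))] = keep
    return ContentMatrix(values=values, detected=detected)
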