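"""Kovats retention indices and internal-standard semi-quantification.

For temperature-programmed GC the linear (van den Dool-Kratz) retention
index is used: a peak eluting between the C_n and C_{n+1} n-alkanes gets

    RI = 100*n + 100 * (rt - t_n) / (t_{n+1} - t_n)

so each alkane sits exactly at 100 x carbon number and the index is
piecewise linear and strictly increasing in retention time. No
extrapolation outside the alkane ladder is performed: an early or late
eluter is an error, not a guess.

Relative contents are semi-quantified against a single internal-standard
spike: content (ug/kg) = (peak area / IS area) x spiked IS mass (ug) /
sample mass (kg). The spike mass is computed volumetrically with no
purity correction. A 10 uL spike of 8.16 ug/mL into a 4 g sample gives
20.4 ug/kg per unit area ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlkaneLadder",
    "PeakObservation",
    "SpikeConfig",
    "kovats_ri",
    "ri_match",
    "semi_quantify",
]


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: (carbon number, retention time in min)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("alkane ladder needs at least 2 entries")
        carbons = [c for c, _ in self.entries]
        rts = [t for _, t in self.entries]
        if any(not (5 <= c <= 30) for c in carbons):
            raise ValueError("alkane carbon numbers must lie in [5, 30]")
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValueError("alkane carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("alkane retention times must be strictly increasing")

    @property
    def carbons(self) -> np.ndarray:
        return np.array([c for c, _ in self.entries])

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([t for _, t in self.entries])


@dataclass(frozen=True)
class PeakObservation:
    """A single integrated chromatographic peak."""

    compound_id: str
    retention_time: float  # minutes
    area: float  # arbitrary detector units

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention time must be positive")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass(frozen=True)
class SpikeConfig:
    """Internal-standard spike parameters.

    ``is_volume`` in uL, ``is_concentration`` in ug/mL, ``sample_mass``
    in g; all strictly positive.
    """

    is_volume: float
    is_concentration: float
    sample_mass: float

    def __post_init__(self) -> None:
        if min(self.is_volume, self.is_concentration, self.sample_mass) <= 0:
            raise ValueError("spike parameters must all be positive")

    @property
    def spiked_mass_ug(self) -> float:
        """Mass of internal standard added, in ug (volume uL x conc ug/mL / 1000)."""
        return self.is_volume * self.is_concentration / 1000.0

    @property
    def sample_mass_kg(self) -> float:
        return self.sample_mass / 1000.0


def kovats_ri(rt: float, ladder: AlkaneLadder) -> float:
    """Linear retention index of a peak at ``rt`` minutes on ``ladder``."""
    rts = ladder.retention_times
    carbons = ladder.carbons
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(
            f"retention time {rt} min outside alkane ladder range "
            f"[{rts[0]}, {rts[-1]}]; refusing to extrapolate"
        )
    # right-most bracketing segment; exact alkane hits return 100*n
    i = int(np.searchsorted(rts, rt, side="right") - 1)
    if i == len(rts) - 1:  # rt == last alkane
        return 100.0 * carbons[-1]
    n, t_n = carbons[i], rts[i]
    n_next, t_next = carbons[i + 1], rts[i + 1]
    return 100.0 * n + 100.0 * (n_next - n) * (rt - t_n) / (t_next - t_n)


def ri_match(ri_exp: float, ri_lit: float, tol: float = 10.0) -> bool:
    """True iff experimental and literature indices agree within ``tol`` units.

    Default tolerance 10 RI units covers typical experimental-vs-library
    gaps on a nonpolar column.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    return abs(ri_exp - ri_lit) <= tol


def semi_quantify(peak: PeakObservation, is_area: float, spike: SpikeConfig) -> float:
    """Relative content (ug/kg) of ``peak`` from the IS area ratio."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    return (peak.area / is_area) * spike.spiked_mass_ug / spike.sample_mass_kg
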