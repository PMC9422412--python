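"""Place-frequency mapping for the guinea-pig cochlea.

Two interchangeable forms:

* ``octave``: the species-specific constant-slope scaling in which 2.59 mm
  of cochlear distance corresponds to one octave,
  ``f(d) = f_base * 2**(-d / 2.59 mm)``.  The default anchor
  ``f_base = 33.6 kHz`` is a calibration constant chosen so that a
  5.34 mm insertion depth maps near 8.04 kHz (the median lowest
  characteristic frequency of reconstructed insertions); it is not a
  species constant.
* ``greenwood``: the full Greenwood form ``f = A * (10**(a*x) - k)`` with
  ``x`` the relative distance from the apex, using standard guinea-pig
  constants ``A = 0.35 kHz, a = 2.1, k = 0.85`` over an 18.5 mm membrane.

Both are strictly decreasing in depth and exactly invertible on (0, L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MM_PER_OCTAVE = 2.59


@dataclass(frozen=True)
class PlaceFrequencyMap:
    form: str = "octave"
    f_base_hz: float = 33600.0
    mm_per_octave: float = MM_PER_OCTAVE
    greenwood_A_khz: float = 0.35
    greenwood_a: float = 2.1
    greenwood_k: float = 0.85
    length_mm: float = 18.5

    def __post_init__(self) -> None:
        if self.form not in ("octave", "greenwood"):
            raise ValueError("form must be 'octave' or 'greenwood'")
        if min(self.f_base_hz, self.mm_per_octave, self.length_mm) <= 0:
            raise ValueError("map parameters must be positive")

    @property
    def length_um(self) -> float:
        return self.length_mm * 1000.0

    def frequency_range_hz(self) -> tuple[float, float]:
        lo = place_to_frequency(self.length_um, self)
        hi = place_to_frequency(0.0, self)
        return float(lo), float(hi)


def place_to_frequency(depth_um, pfm: PlaceFrequencyMap | None = None):
    """Characteristic frequency (Hz) at arc depth ``depth_um`` from the base."""
    pfm = pfm or PlaceFrequencyMap()
    depth = np.asarray(depth_um, dtype=float)
    if np.any(depth < -1e-9) or np.any(depth > pfm.length_um + 1e-9):
        raise ValueError("depth outside the basilar membrane")
    if pfm.form == "octave":
        out = pfm.f_base_hz * 2.0 ** (-depth / (pfm.mm_per_octave * 1000.0))
    else:
        x = (pfm.length_um - depth) / pfm.length_um
        out = pfm.greenwood_A_khz * 1000.0 * (10.0 ** (pfm.greenwood_a * x) - pfm.greenwood_k)
    return float(out) if out.ndim == 0 else out


def frequency_to_place(f_hz, pfm: PlaceFrequencyMap | None = None):
    """Exact inverse of :func:`place_to_frequency` (micrometre depth)."""
    pfm = pfm or PlaceFrequencyMap()
    f = np.asarray(f_hz, dtype=float)
    lo, hi = pfm.frequency_range_hz()
    if np.any(f < lo * (1 - 1e-12)) or np.any(f > hi * (1 + 1e-12)):
        raise ValueError("frequency outside the map range")
    if pfm.form == "octave":
        out = pfm.mm_per_octave * 1000.0 * np.log2(pfm.f_base_hz / f)
    else:
        x = np.log10(f / (pfm.greenwood_A_khz * 1000.0) + pfm.greenwood_k) / pfm.greenwood_a
        out = pfm.length_um * (1.0 - x)
    return float(out) if out.ndim == 0 else out


def octaves_to_distance(octaves: float, mm_per_octave: float = MM_PER_OCTAVE) -> float:
    """Cochlear distance (mm) spanned by a frequency extent in octaves."""
    if octaves < 0:
        raise ValueError("octaves must be >= 0")
    return octaves * mm_per_octave


def lowest_cf(metrics, pfm: PlaceFrequencyMap | None = None) -> float:
    """Lowest characteristic frequency reached by an implanted track.

    ``metrics`` is an :class:`~cisim.cochlear_geometry.InsertionMetrics`
    (its apical-contact depth is used) or a bare depth in micrometres.
    """
    depth = getattr(metrics, "depth_ch1_um", metrics)
    return float(place_to_frequency(depth, pfm))


def contact_frequency_table(depths_um, contact_ids=None, pfm: PlaceFrequencyMap | None = None):
    """Per-contact characteristic-frequency table (pandas DataFrame)."""
    import pandas as pd

    depths = np.atleast_1d(np.asarray(depths_um, dtype=float))
    ids = np.arange(1, depths.size + 1) if contact_ids is None else np.asarray(contact_ids)
    return pd.DataFrame(
        {
            "contact_id": ids,
            "depth_um": depths,
            "cf_hz": place_to_frequency(depths, pfm),
        }
    )
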