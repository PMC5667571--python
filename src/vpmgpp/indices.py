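"""Vegetation indices from surface reflectance and QA screening.

EVI and LSWI are computed from MOD09A1-style 8-day surface reflectance
composites (blue, red, NIR, SWIR bands plus a per-pixel QA bit field).
Observations flagged as cloudy or aerosol-laden in the QA word are
masked before gap-filling; LSWI is deliberately not masked here because
cloud/snow contamination raises LSWI, which only relaxes the water
stress scalar downstream, and the series keeps its variance (see
:mod:`vpmgpp.lswi`).

EVI = 2.5 (rho_NIR - rho_red) / (rho_NIR + 6 rho_red - 7.5 rho_blue + 1)
LSWI = (rho_NIR - rho_SWIR) / (rho_NIR + rho_SWIR)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVI_CLIP_RANGE = (-0.2, 1.2)

# QA register layouts, keyed by dialect name.  The default mirrors the
# MOD09A1 500 m state-QA word: cloud state in bits 0-1 (00 = clear),
# aerosol quantity in bits 6-7 (01 = low, 10 = average are acceptable),
# snow/ice flag in bit 12.
QA_DIALECTS: dict[str, dict[str, int]] = {
    "mod09a1_state": {"cloud_shift": 0, "aerosol_shift": 6, "snow_bit": 12},
}


@dataclass
class QAFlags:
    """Boolean per-observation quality flags decoded from the QA word."""

    cloud_clear: np.ndarray
    aerosol_acceptable: np.ndarray
    snow_ice: np.ndarray

    @property
    def evi_usable(self) -> np.ndarray:
        return self.cloud_clear & self.aerosol_acceptable


@dataclass
class ReflectanceCube:
    """Scaled band reflectances + QA for one tile, stacked over composites.

    Arrays are shaped (n_composites, rows, cols); ``calendar`` lists the
    (year, composite_index) pair for each layer, composite_index 1..46.
    """

    blue: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    qa_word: np.ndarray
    calendar: list[tuple[int, int]]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.blue, self.red, self.nir, self.swir, self.qa_word)}
        if len(shapes) != 1:
            raise ValueError(f"band arrays disagree in shape: {shapes}")
        if self.blue.shape[0] != len(self.calendar):
            raise ValueError("calendar length does not match leading array axis")
        if len(set(self.calendar)) != len(self.calendar):
            raise ValueError("duplicate (year, composite) entries in calendar")

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.calendar})


@dataclass
class VISeries:
    """EVI and LSWI stacks with validity masks on a shared calendar."""

    evi: np.ndarray
    lswi: np.ndarray
    evi_valid: np.ndarray
    lswi_valid: np.ndarray
    calendar: list[tuple[int, int]]
    evi_clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.evi_clipped is None:
            self.evi_clipped = np.zeros(self.evi.shape, dtype=bool)

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.calendar})

    def copy(self) -> "VISeries":
        return VISeries(
            self.evi.copy(),
            self.lswi.copy(),
            self.evi_valid.copy(),
            self.lswi_valid.copy(),
            list(self.calendar),
            self.evi_clipped.copy(),
        )


def _valid_reflectance(*bands: np.ndarray) -> np.ndarray:
    ok = np.ones(np.broadcast(*bands).shape, dtype=bool)
    for b in bands:
        ok &= np.isfinite(b) & (b >= 0.0) & (b <= 1.0)
    return ok


def compute_evi(blue, red, nir):
    """EVI with validity mask and a flag for values clipped to [-0.2, 1.2].

    Returns (evi, valid, clipped).  Invalid or fill reflectances and
    vanishing denominators yield NaN with valid=False, never an
    exception.
    """
    blue, red, nir = np.broadcast_arrays(
        np.asarray(blue, float), np.asarray(red, float), np.asarray(nir, float)
    )
    valid = _valid_reflectance(blue, red, nir)
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = 2.5 * (nir - red) / denom
    valid &= np.isfinite(evi) & (denom != 0)
    lo, hi = EVI_CLIP_RANGE
    clipped = valid & ((evi < lo) | (evi > hi))
    evi = np.where(valid, np.clip(evi, lo, hi), np.nan)
    return evi, valid, clipped


def compute_lswi(nir, swir):
    """LSWI with validity mask; zero NIR+SWIR denominator is invalid."""
    nir, swir = np.broadcast_arrays(np.asarray(nir, float), np.asarray(swir, float))
    valid = _valid_reflectance(nir, swir)
    denom = nir + swir
    with np.errstate(divide="ignore", invalid="ignore"):
        lswi = (nir - swir) / denom
    valid &= np.isfinite(lswi) & (denom != 0)
    lswi = np.where(valid, lswi, np.nan)
    return lswi, valid


def decode_qa(qa_word: np.ndarray, dialect: str = "mod09a1_state") -> QAFlags:
    """Decode cloud / aerosol / snow flags from the QA bit field.

    cloud_clear: bits 0-1 == 00; aerosol_acceptable: bits 6-7 == 01 or
    10 (low or average aerosol); snow_ice from the dialect's snow bit.
    """
    try:
        layout = QA_DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown QA dialect {dialect!r}; known: {sorted(QA_DIALECTS)}"
        ) from None
    word = np.asarray(qa_word).astype(np.int64)
    cloud = (word >> layout["cloud_shift"]) & 0b11
    aerosol = (word >> layout["aerosol_shift"]) & 0b11
    snow = (word >> layout["snow_bit"]) & 0b1
    return QAFlags(
        cloud_clear=cloud == 0b00,
        aerosol_acceptable=(aerosol == 0b01) | (aerosol == 0b10),
        snow_ice=snow == 1,
    )


def compute_vi_series(cube: ReflectanceCube) -> VISeries:
    """EVI + LSWI stacks for a reflectance cube (no QA masking yet)."""
    evi, evi_valid, clipped = compute_evi(cube.blue, cube.red, cube.nir)
    lswi, lswi_valid = compute_lswi(cube.nir, cube.swir)
    return VISeries(evi, lswi, evi_valid, lswi_valid, list(cube.calendar), clipped)


def mask_bad_observations(vi: VISeries, flags: QAFlags) -> VISeries:
    """Invalidate EVI where the QA word shows cloud or unacceptable aerosol.

    LSWI validity is left untouched: the water index is screened only
    through year substitution and the snow-free LSWI_max rule.
    """
    if flags.cloud_clear.shape != vi.evi.shape:
        raise ValueError(
            f"QA flags shape {flags.cloud_clear.shape} does not match "
            f"VI series shape {vi.evi.shape}"
        )
    out = vi.copy()
    bad = ~flags.evi_usable
    out.evi_valid &= ~bad
    out.evi = np.where(out.evi_valid, out.evi, np.nan)
    return out
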