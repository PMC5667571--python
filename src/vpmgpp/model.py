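"""The VPM light-use-efficiency GPP equations.

GPP is the product of the PAR absorbed by chlorophyll and a realized
light-use efficiency:

    GPP      = APAR_chl * eps_g              [g C m-2 day-1]
    APAR_chl = PAR * fPAR_chl
    fPAR_chl = (EVI - 0.1) * 1.25            clamped to [0, 1]
    eps_g    = eps0 * T_scalar * W_scalar
    T_scalar = (T-Tmax)(T-Tmin) / [(T-Tmax)(T-Tmin) - (T-Topt)^2]
    W_scalar = (1 + LSWI) / (1 + LSWI_max)   clamped to [0, 1]

T_scalar is forced to 0 outside (T_min, T_max) and clamped to [0, 1]
inside; both stress scalars are dimensionless down-regulation factors
on the biome/pathway maximum efficiency eps0.  All functions are pure,
vectorized over numpy arrays, and propagate NaN as nodata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lue import BiomeParameters

FPAR_EVI_OFFSET = 0.1
FPAR_EVI_SLOPE = 1.25


@dataclass
class GppResult:
    """GPP with its diagnostic scalars, all on the input shape."""

    gpp: np.ndarray  # g C m-2 day-1
    t_scalar: np.ndarray
    w_scalar: np.ndarray
    fpar_chl: np.ndarray


def fpar_chl(evi, offset: float = FPAR_EVI_OFFSET, slope: float = FPAR_EVI_SLOPE):
    """Fraction of PAR absorbed by chlorophyll, linear in EVI.

    The offset (0.1) zeroes the fraction over sparse/barren surfaces;
    the slope (1.25) makes fully vegetated canopies (EVI ~0.9) absorb
    everything.  Clamped to [0, 1].
    """
    return np.clip((np.asarray(evi, float) - offset) * slope, 0.0, 1.0)


def t_scalar(t, t_min, t_max, t_opt):
    """Temperature down-regulation, 1 at T_opt, 0 outside [T_min, T_max]."""
    t = np.asarray(t, float)
    t_min = np.asarray(t_min, float)
    t_max = np.asarray(t_max, float)
    t_opt = np.asarray(t_opt, float)
    num = (t - t_max) * (t - t_min)
    denom = num - (t - t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = num / denom
    ts = np.where((t <= t_min) | (t >= t_max), 0.0, ts)
    ts = np.where(np.isnan(t), np.nan, ts)
    return np.clip(ts, 0.0, 1.0)


def w_scalar(lswi, lswi_max):
    """Water down-regulation (1+LSWI)/(1+LSWI_max), clamped to [0, 1].

    Smoothing can leave LSWI above LSWI_max; the clamp enforces the
    scalar's stated range.  LSWI_max <= -1 has no defined water status
    and yields NaN.
    """
    lswi = np.asarray(lswi, float)
    lswi_max = np.asarray(lswi_max, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ws = (1.0 + lswi) / (1.0 + lswi_max)
    ws = np.where(lswi_max <= -1.0, np.nan, ws)
    return np.clip(ws, 0.0, 1.0)


def light_use_efficiency(eps0, ts, ws):
    """Realized LUE eps_g = eps0 * T_scalar * W_scalar (g C/mol APAR)."""
    return np.asarray(eps0, float) * np.asarray(ts, float) * np.asarray(ws, float)


def gpp(par, fpar, eg):
    """GPP = PAR * fPAR_chl * eps_g, in g C m-2 day-1."""
    return np.asarray(par, float) * np.asarray(fpar, float) * np.asarray(eg, float)


def run_pixels(
    evi: np.ndarray,
    lswi: np.ndarray,
    lswi_max: np.ndarray,
    t_day: np.ndarray,
    par: np.ndarray,
    igbp: np.ndarray,
    eps0: np.ndarray,
    params: BiomeParameters,
) -> GppResult:
    """Evaluate the model over aligned (time, rows, cols) stacks.

    ``lswi_max``, ``igbp`` and ``eps0`` are per-pixel (broadcast over
    time) or already time-expanded; nodata (NaN EVI, NaN eps0, unknown
    class) propagates to NaN GPP.
    """
    shapes = {np.shape(a) for a in (evi, lswi, t_day, par)}
    if len(shapes) != 1:
        raise ValueError(f"misaligned forcing stacks: {shapes}")
    igbp = np.asarray(igbp)
    t_min = np.full(igbp.shape, np.nan)
    t_max = np.full(igbp.shape, np.nan)
    t_opt = np.full(igbp.shape, np.nan)
    for code in np.unique(igbp):
        if code in params.table.index:
            sel = igbp == code
            row = params.table.loc[code]
            t_min[sel], t_max[sel], t_opt[sel] = row.t_min, row.t_max, row.t_opt

    ts = t_scalar(t_day, t_min, t_max, t_opt)
    ws = w_scalar(lswi, lswi_max)
    fp = fpar_chl(evi)
    eg = light_use_efficiency(eps0, ts, ws)
    return GppResult(gpp=gpp(par, fp, eg), t_scalar=ts, w_scalar=ws, fpar_chl=fp)
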