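"""Hemodynamic preprocessing: MBLL conversion, channel repair, CBSI, standardization.

The fixed pipeline order is ``mbll (optional) -> interpolate -> cbsi ->
standardize``; no filtering or resampling is applied anywhere before VAR
fitting, since such smoothing is known to produce spurious
Granger-causal structure.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .exceptions import ConfigurationError, DataError
from .grid import ChannelGrid
from .signals import HemoglobinTimeSeries, OpticalTimeSeries, OpticsConfig


def mbll_convert(optical: OpticalTimeSeries, optics: OpticsConfig) -> HemoglobinTimeSeries:
    """Convert raw dual-wavelength intensities to hemoglobin concentration changes.

    Optical-density changes are ``dOD(w, t) = -log10(I(t) / I0)`` with
    ``I0`` the temporal mean intensity of the recording; per sample the
    2x2 linear system ``dOD = d * DPF * eps @ [dHbO, dHbR]`` is solved.
    """
    intensities = optical.intensities
    i0 = intensities.mean(axis=2, keepdims=True)
    dod = -np.log10(intensities / i0)  # (2, n_channels, n_samples)
    system = optics.pathlength_matrix  # (2 wavelengths, 2 chromophores)
    try:
        inv = np.linalg.inv(system)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in OpticsConfig
        raise ConfigurationError("singular MBLL system matrix") from exc
    conc = np.einsum("cw,wks->cks", inv, dod)  # (2 chromophores, channels, samples)
    return HemoglobinTimeSeries(
        hbo=conc[0],
        hbr=conc[1],
        channel_ids=list(optical.channel_ids),
        sampling_rate=optical.sampling_rate,
    )


def _spatial_interpolate(
    points_good: np.ndarray, values: np.ndarray, points_bad: np.ndarray
) -> np.ndarray:
    """Sample-wise 2-D interpolation with nearest-neighbor hull fallback.

    ``values`` is (n_good, n_samples); returns (n_bad, n_samples).
    Linear barycentric interpolation has exact linear precision in the
    channel coordinates; outside the convex hull of the good channels the
    nearest good channel is used.
    """
    out = np.empty((len(points_bad), values.shape[1]))
    linear = LinearNDInterpolator(points_good, values)
    nearest = NearestNDInterpolator(points_good, values)
    est = linear(points_bad)
    mask = np.isnan(est).any(axis=1)
    if mask.any():
        est[mask] = nearest(points_bad[mask])
    out[:] = est
    return out


def interpolate_bad_channels(
    ts: HemoglobinTimeSeries, bad: set[str] | list[str], grid: ChannelGrid
) -> HemoglobinTimeSeries:
    """Replace signal-free channels by 2-D spatial interpolation over good ones.

    Each bad channel's HbO and HbR traces are reconstructed sample-wise
    from the good channels' values at the grid coordinates; good
    channels are returned untouched.
    """
    bad = set(bad)
    if not bad:
        return ts.copy()
    unknown = bad - set(grid.channel_ids)
    if unknown:
        raise DataError(f"bad channels not in grid: {sorted(unknown)}")
    unknown = bad - set(ts.channel_ids)
    if unknown:
        raise DataError(f"bad channels not in time series: {sorted(unknown)}")
    good = [c for c in ts.channel_ids if c not in bad]
    if len(good) < 3:
        raise DataError(
            f"need at least 3 good channels for spatial interpolation, have {len(good)}"
        )
    bad_ordered = [c for c in ts.channel_ids if c in bad]
    pts_good = grid.positions(good)
    pts_bad = grid.positions(bad_ordered)
    index = {c: i for i, c in enumerate(ts.channel_ids)}
    rows_good = [index[c] for c in good]
    rows_bad = [index[c] for c in bad_ordered]
    out = ts.copy()
    out.hbo[rows_bad] = _spatial_interpolate(pts_good, ts.hbo[rows_good], pts_bad)
    out.hbr[rows_bad] = _spatial_interpolate(pts_good, ts.hbr[rows_good], pts_bad)
    return out


def cbsi(hbo: np.ndarray, hbr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Array-level correlation-based signal improvement.

    With ``x`` = HbO, ``y`` = HbR and ``alpha = sd(x)/sd(y)`` per channel:
    ``x' = (x - alpha*y) / 2`` and ``y' = -x'/alpha``.  Motion artifacts
    move HbO and HbR in the same direction whereas the hemodynamic
    response moves them in opposite directions, so the construction
    cancels the shared component and returns perfectly anticorrelated
    signals.
    """
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(hbr, dtype=float))
    sx = hbo.std(axis=1, ddof=1)
    sy = hbr.std(axis=1, ddof=1)
    dead = np.flatnonzero((sx == 0) | (sy == 0))
    if dead.size:
        raise DataError(f"zero-variance channel index(es) for CBSI: {dead.tolist()}")
    alpha = (sx / sy)[:, None]
    x_new = (hbo - alpha * hbr) / 2.0
    y_new = -x_new / alpha
    return x_new, y_new


def cbsi_correct(ts: HemoglobinTimeSeries) -> HemoglobinTimeSeries:
    """Correlation-based motion-artifact correction, channel-wise."""
    sx = ts.hbo.std(axis=1, ddof=1)
    sy = ts.hbr.std(axis=1, ddof=1)
    dead = (sx == 0) | (sy == 0)
    if dead.any():
        names = [c for c, d in zip(ts.channel_ids, dead) if d]
        raise DataError(f"zero-variance channel(s) for CBSI: {names}")
    x_new, y_new = cbsi(ts.hbo, ts.hbr)
    return HemoglobinTimeSeries(
        hbo=x_new, hbr=y_new, channel_ids=list(ts.channel_ids), sampling_rate=ts.sampling_rate
    )


def standardize_array(x: np.ndarray) -> np.ndarray:
    """Per-row standardization to mean 0 and (ddof=1) SD 1."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sd = x.std(axis=1, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DataError(f"constant channel index(es), cannot standardize: {dead.tolist()}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def standardize(ts: HemoglobinTimeSeries) -> HemoglobinTimeSeries:
    """Standardize each channel's HbO and HbR trace to zero mean, unit SD."""
    return HemoglobinTimeSeries(
        hbo=standardize_array(ts.hbo),
        hbr=standardize_array(ts.hbr),
        channel_ids=list(ts.channel_ids),
        sampling_rate=ts.sampling_rate,
    )


def preprocess(
    ts: HemoglobinTimeSeries,
    grid: ChannelGrid,
    bad_channels: set[str] | list[str] = (),
    apply_cbsi: bool = True,
) -> HemoglobinTimeSeries:
    """Fixed-order preprocessing: interpolate -> CBSI -> standardize."""
    out = interpolate_bad_channels(ts, bad_channels, grid) if bad_channels else ts
    if apply_cbsi:
        out = cbsi_correct(out)
    return standardize(out)
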