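"""Frequency-domain Granger causality: VAR fit, transfer function, directed coherence.

Each measurement is modelled as a vector autoregressive (VAR) process

    x(t) = sum_{k=1..p} A_k x(t-k) + e(t),      e ~ N(0, Sigma)

fitted by per-equation ordinary least squares.  The spectral transfer
function ``H(f) = [I - sum_k A_k exp(-i 2 pi f k / fs)]^{-1}`` describes
how innovations propagate between channels at frequency ``f``; directed
coherence (DC) from source ``j`` to sink ``i`` is the noise-weighted,
sink-normalized transfer magnitude

    gamma_ij(f) = sigma_j H_ij(f) / sqrt(sum_m sigma_m^2 |H_im(f)|^2)

with ``sigma_m = sqrt(Sigma_mm)``, so that ``sum_j |gamma_ij|^2 = 1``
for every sink and frequency.  The analysis value per ordered channel
pair is the maximum |gamma| inside a low-frequency band (default
0.06-0.12 Hz), where hemodynamic functional coupling is expressed and
physiological noise from respiration and heart beat is avoided.

The default model order 20 at 10 Hz sampling corresponds to a 2 s lag
window and a native (pre-padding) spectral resolution of 0.5 Hz;
coefficients are zero-padded to the length of the fitted series before
the frequency transform to smooth the spectral grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataError, EstimationError
from .grid import ChannelGrid
from .signals import HemoglobinTimeSeries

DEFAULT_BAND = (0.06, 0.12)


@dataclass
class VARModel:
    """Fitted VAR(p): coefficient stack ``coefs[k-1] = A_k`` and noise covariance."""

    coefs: np.ndarray  # (p, k, k)
    sigma: np.ndarray  # (k, k)
    sampling_rate: float
    channel_ids: list[str]
    n_samples_fit: int
    _spectral_radius: float | None = field(default=None, repr=False)

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]

    @property
    def lag_window_s(self) -> float:
        """Temporal depth of the autoregression, ``p / fs`` seconds."""
        return self.order / self.sampling_rate

    @property
    def spectral_radius(self) -> float:
        """Spectral radius of the companion matrix (< 1 means stable)."""
        if self._spectral_radius is None:
            self._spectral_radius = companion_spectral_radius(self.coefs)
        return self._spectral_radius

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass
class SpectralTransfer:
    """Transfer function H(f) on a zero-padded frequency grid."""

    freqs: np.ndarray  # (n_freq,)
    H: np.ndarray  # (n_freq, k, k) complex
    sampling_rate: float
    channel_ids: list[str]
    native_resolution_hz: float  # fs / p, before padding

    @property
    def grid_spacing_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if len(self.freqs) > 1 else np.nan


@dataclass
class DCMatrix:
    """Band-maximum directed coherence per ordered channel pair.

    ``dc[i, j]`` is the influence of source ``j`` on sink ``i`` (both in
    ``channel_ids`` order), in [0, 1].
    """

    dc: np.ndarray  # (k, k)
    band: tuple[float, float]
    channel_ids: list[str]
    freqs: np.ndarray | None = None  # per-frequency spectra, optional
    spectra: np.ndarray | None = None  # (n_freq, k, k) |gamma|

    def value(self, sink: str, source: str) -> float:
        i = self.channel_ids.index(sink)
        j = self.channel_ids.index(source)
        return float(self.dc[i, j])

    def to_frame(self):
        """Tidy (source, sink, dc) table."""
        import pandas as pd

        k = len(self.channel_ids)
        sink, source = np.divmod(np.arange(k * k), k)
        return pd.DataFrame(
            {
                "source": [self.channel_ids[j] for j in source],
                "sink": [self.channel_ids[i] for i in sink],
                "dc": self.dc.ravel(),
            }
        )


def companion_spectral_radius(coefs: np.ndarray) -> float:
    """Spectral radius of the (k*p x k*p) VAR companion matrix (exact)."""
    p, k, _ = coefs.shape
    companion = np.zeros((k * p, k * p))
    companion[:k, :] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        companion[k:, :-k] = np.eye(k * (p - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


def _companion_radius_estimate(coefs: np.ndarray, n_iter: int = 200) -> float:
    """Power-iteration estimate of the companion spectral radius.

    Cheap screening for the instability warning on large fitted models;
    the companion action is applied without materializing the matrix.
    """
    p, k, _ = coefs.shape
    rng = np.random.default_rng(12345)
    v = rng.standard_normal(k * p)
    v /= np.linalg.norm(v)
    growth = 1.0
    for _ in range(n_iter):
        top = sum(coefs[lag] @ v[lag * k : (lag + 1) * k] for lag in range(p))
        w = np.concatenate([top, v[: k * (p - 1)]])
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        growth = norm
        v = w / norm
    return float(growth)


def simulate_var(
    coefs: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    noise_sd: np.ndarray | float = 1.0,
    burn_in: int = 500,
    innovations: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate a VAR process; returns (k, n_samples).

    Used both by the synthetic-data generator and by self-simulation
    oracles in the tests.  ``innovations`` overrides the white-noise
    draw (shape (k, n_samples + burn_in)).
    """
    p, k, _ = coefs.shape
    total = n_samples + burn_in
    if innovations is None:
        sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (k,))
        e = rng.standard_normal((k, total)) * sd[:, None]
    else:
        e = np.asarray(innovations, dtype=float)
        if e.shape != (k, total):
            raise DataError(f"innovations must have shape {(k, total)}, got {e.shape}")
    # keep only lags with nonzero coefficients to speed the recursion
    active = [lag for lag in range(p) if np.any(coefs[lag])]
    x = np.zeros((k, total))
    for t in range(total):
        acc = e[:, t].copy()
        for lag in active:
            if t > lag:
                acc += coefs[lag] @ x[:, t - lag - 1]
        x[:, t] = acc
    return x[:, burn_in:]


def _as_signal_array(ts) -> tuple[np.ndarray, float, list[str]]:
    if isinstance(ts, HemoglobinTimeSeries):
        return ts.hbo, ts.sampling_rate, list(ts.channel_ids)
    x = np.atleast_2d(np.asarray(ts, dtype=float))
    return x, 10.0, [f"ch{i}" for i in range(x.shape[0])]


def fit_var(
    ts,
    order: int = 20,
    sampling_rate: float | None = None,
    channel_ids: list[str] | None = None,
) -> VARModel:
    """Fit a VAR(p) by per-equation ordinary least squares.

    ``ts`` may be a :class:`HemoglobinTimeSeries` (the HbO traces are
    used; after CBSI the HbR traces are proportional and carry identical
    spectral information) or a plain (n_channels, n_samples) array.
    Instability of the fitted model (companion spectral radius >= 1) is
    a warning, not an error: empirical fits on short recordings can be
    borderline.
    """
    x, fs, ids = _as_signal_array(ts)
    if sampling_rate is not None:
        fs = sampling_rate
    if channel_ids is not None:
        ids = list(channel_ids)
    k, n = x.shape
    p = int(order)
    if p < 1:
        raise ConfigurationError("VAR order must be >= 1")
    if n <= p * k + p:
        raise DataError(
            f"need more than p*k + p = {p * k + p} samples to fit VAR({p}) "
            f"on {k} channels, have {n}"
        )
    n_eff = n - p
    # design: row t has [x(t-1), x(t-2), ..., x(t-p)] flattened
    design = np.empty((n_eff, k * p))
    for lag in range(1, p + 1):
        design[:, (lag - 1) * k : lag * k] = x[:, p - lag : n - lag].T
    target = x[:, p:].T  # (n_eff, k)
    gram = design.T @ design
    try:
        coef_flat = np.linalg.solve(gram, design.T @ target)  # (k*p, k)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("rank-deficient VAR regressor matrix") from exc
    resid = target - design @ coef_flat
    dof = max(n_eff - k * p, 1)
    sigma = resid.T @ resid / dof
    coefs = np.empty((p, k, k))
    for lag in range(p):
        # equation i regresses on lagged channels: coefs[lag][i, j]
        coefs[lag] = coef_flat[lag * k : (lag + 1) * k, :].T
    model = VARModel(
        coefs=coefs, sigma=sigma, sampling_rate=fs, channel_ids=ids, n_samples_fit=n
    )
    # instability is a warning, not an error: short empirical fits can be
    # borderline.  Screen with a cheap estimate, confirm exactly only then.
    if _companion_radius_estimate(coefs) > 0.995 and not model.is_stable:
        warnings.warn(
            "fitted VAR is unstable (companion spectral radius "
            f"{model.spectral_radius:.4f} >= 1)",
            RuntimeWarning,
            stacklevel=2,
        )
    return model


def transfer_function(
    var: VARModel,
    pad_to: int | None = None,
    band: tuple[float, float] | None = None,
) -> SpectralTransfer:
    """Spectral transfer function on a zero-padded frequency grid.

    The coefficient sequence ``[I, -A_1, ..., -A_p]`` is zero-padded to
    ``pad_to`` samples (default: the length of the fitted series) before
    the Fourier transform, smoothing the spectral estimate; the grid
    spacing is ``fs / pad_to`` while the native resolution remains
    ``fs / p``.  If ``band`` is given, H is computed (and stored) only at
    grid frequencies inside the band.
    """
    p, k = var.order, var.n_channels
    if pad_to is None:
        pad_to = var.n_samples_fit
    if pad_to < p + 1:
        raise ConfigurationError(f"pad_to must be at least order + 1 = {p + 1}")
    freqs = np.fft.rfftfreq(pad_to, d=1.0 / var.sampling_rate)
    if band is not None:
        lo, hi = band
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ConfigurationError(
                f"frequency grid (spacing {var.sampling_rate / pad_to:.5g} Hz) "
                f"has no point inside band {band}"
            )
        freqs_used = freqs[sel]
        omega = 2.0 * np.pi * freqs_used / var.sampling_rate
        lags = np.arange(1, p + 1)
        phase = np.exp(-1j * np.outer(omega, lags))  # (n_f, p)
        a_f = np.eye(k)[None, :, :] - np.einsum("fp,pij->fij", phase, var.coefs)
    else:
        freqs_used = freqs
        seq = np.zeros((pad_to, k, k))
        seq[0] = np.eye(k)
        seq[1 : p + 1] = -var.coefs
        a_f = np.fft.rfft(seq, axis=0)
    try:
        H = np.linalg.inv(a_f)
        bad = ~np.isfinite(H).all(axis=(1, 2))
    except np.linalg.LinAlgError:
        H = None
        bad = np.array(
            [not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e14
             for m in a_f]
        )
    if bad.any() or H is None:
        f_bad = freqs_used[np.flatnonzero(bad)[0]] if bad.any() else freqs_used[0]
        raise EstimationError(
            f"characteristic matrix I - A(f) is singular at f = {f_bad:.5g} Hz"
        )
    return SpectralTransfer(
        freqs=freqs_used,
        H=H,
        sampling_rate=var.sampling_rate,
        channel_ids=list(var.channel_ids),
        native_resolution_hz=var.sampling_rate / p,
    )


def directed_coherence(
    transfer: SpectralTransfer,
    sigma: np.ndarray,
    noise_weighted: bool = True,
) -> np.ndarray:
    """Per-frequency directed-coherence magnitudes |gamma_ij(f)|.

    With ``noise_weighted=False`` the unweighted (directed transfer
    function) variant is computed, i.e. all innovation SDs are treated
    as equal.  Returns (n_freq, k, k), sink-normalized so that
    ``sum_j |gamma_ij(f)|^2 = 1`` for every sink ``i`` and frequency.
    """
    sigma = np.asarray(sigma, dtype=float)
    d = np.diag(sigma)
    if np.any(d <= 0):
        raise DataError("noise covariance has non-positive diagonal entries")
    w = np.sqrt(d) if noise_weighted else np.ones_like(d)
    num = np.abs(transfer.H) * w[None, None, :]
    denom = np.sqrt((num**2).sum(axis=2, keepdims=True))
    return num / denom


def band_max(
    freqs: np.ndarray,
    spectra: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    channel_ids: list[str] | None = None,
    keep_spectra: bool = False,
) -> DCMatrix:
    """Reduce per-frequency DC spectra to the band maximum per ordered pair.

    Both band edges are inclusive.
    """
    lo, hi = band
    if hi < lo:
        raise ConfigurationError(f"empty band: {band}")
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ConfigurationError(
            f"no frequency grid point inside band [{lo}, {hi}] Hz"
        )
    dc = spectra[sel].max(axis=0)
    k = dc.shape[0]
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(k)]
    return DCMatrix(
        dc=dc,
        band=(lo, hi),
        channel_ids=list(channel_ids),
        freqs=freqs[sel] if keep_spectra else None,
        spectra=spectra[sel] if keep_spectra else None,
    )


class DirectedCoherence:
    """Estimator computing band-maximum directed coherence from multichannel data.

    Follows the scikit-learn estimator protocol (``fit``,
    ``get_params``/``set_params``, fitted attributes with trailing
    underscores) so it composes with sklearn tooling; ``fit`` accepts an
    (n_samples, n_channels) array or a :class:`HemoglobinTimeSeries`.

    Parameters
    ----------
    order : int
        VAR model order (default 20; 2 s at 10 Hz).
    band : (float, float)
        Analysis band in Hz, edges inclusive.
    pad_to : int or None
        Zero-padding length for the spectral grid (default: series length).
    noise_weighted : bool
        Noise-weighted DC (default) vs. the unweighted DTF variant.
    sampling_rate : float or None
        Required for array input; taken from the time series otherwise.

    Attributes
    ----------
    var_ : VARModel
    transfer_ : SpectralTransfer
    dc_ : ndarray, (k, k) band-max DC, sink x source
    dc_matrix_ : DCMatrix
    """

    _param_names = ("order", "band", "pad_to", "noise_weighted", "sampling_rate")

    def __init__(
        self,
        order: int = 20,
        band: tuple[float, float] = DEFAULT_BAND,
        pad_to: int | None = None,
        noise_weighted: bool = True,
        sampling_rate: float | None = None,
    ) -> None:
        self.order = order
        self.band = band
        self.pad_to = pad_to
        self.noise_weighted = noise_weighted
        self.sampling_rate = sampling_rate

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "DirectedCoherence":
        for name, value in params.items():
            if name not in self._param_names:
                raise ValueError(f"unknown parameter {name!r}")
            setattr(self, name, value)
        return self

    def fit(self, X, y=None) -> "DirectedCoherence":
        if isinstance(X, HemoglobinTimeSeries):
            ts = X
        else:
            x = np.asarray(X, dtype=float)
            if x.ndim != 2:
                raise DataError("X must be 2-D (n_samples, n_channels)")
            fs = self.sampling_rate
            if fs is None:
                raise ConfigurationError(
                    "sampling_rate must be set for array input"
                )
            ts = x.T  # fit_var expects channels x samples for arrays
        self.var_ = fit_var(
            ts,
            order=self.order,
            sampling_rate=self.sampling_rate,
        )
        self.transfer_ = transfer_function(self.var_, pad_to=self.pad_to, band=self.band)
        spectra = directed_coherence(
            self.transfer_, self.var_.sigma, noise_weighted=self.noise_weighted
        )
        self.dc_matrix_ = band_max(
            self.transfer_.freqs,
            spectra,
            band=self.band,
            channel_ids=self.var_.channel_ids,
        )
        self.dc_ = self.dc_matrix_.dc
        return self


def estimate_connectivity(
    ts: HemoglobinTimeSeries,
    order: int = 20,
    band: tuple[float, float] = DEFAULT_BAND,
    pad_to: int | None = None,
    noise_weighted: bool = True,
    grid: ChannelGrid | None = None,
    fit_scope: str = "all",
) -> DCMatrix:
    """Full connectivity stage: VAR fit -> transfer -> DC -> band max.

    ``fit_scope='all'`` (default) fits one joint VAR over every channel
    of ``ts``; ``fit_scope='hemisphere'`` fits one VAR per hemisphere
    (requires ``grid``) and assembles a block-diagonal DC matrix with
    NaN for cross-hemisphere pairs, which never enter the stream
    analysis.
    """
    if fit_scope == "all":
        est = DirectedCoherence(
            order=order, band=band, pad_to=pad_to, noise_weighted=noise_weighted
        ).fit(ts)
        return est.dc_matrix_
    if fit_scope != "hemisphere":
        raise ConfigurationError(f"unknown fit_scope {fit_scope!r}")
    if grid is None:
        raise ConfigurationError("fit_scope='hemisphere' requires a channel grid")
    k = ts.n_channels
    dc = np.full((k, k), np.nan)
    index = {c: i for i, c in enumerate(ts.channel_ids)}
    for hemisphere in ("left", "right"):
        sub = grid.analyzed[grid.analyzed["hemisphere"] == hemisphere]
        ids = [c for c in ts.channel_ids if c in set(sub["id"])]
        if not ids:
            continue
        part = estimate_connectivity(
            ts.select(ids),
            order=order,
            band=band,
            pad_to=pad_to,
            noise_weighted=noise_weighted,
        )
        rows = np.array([index[c] for c in ids])
        dc[np.ix_(rows, rows)] = part.dc
    return DCMatrix(dc=dc, band=band, channel_ids=list(ts.channel_ids))
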