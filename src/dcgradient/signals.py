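"""In-memory containers for optical and hemodynamic time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataError

#: Molar extinction coefficients in 1/(mM*cm), rows = wavelength,
#: columns = (HbO, HbR).  Instrument-typical values for 695/830 nm.
DEFAULT_EXTINCTION = np.array(
    [
        [0.35, 2.10],  # 695 nm: HbR dominates
        [1.05, 0.78],  # 830 nm: HbO dominates
    ]
)


@dataclass(frozen=True)
class OpticsConfig:
    """Optical constants of the modified Beer-Lambert conversion.

    Attributes
    ----------
    wavelengths_nm : tuple of float
        The two measurement wavelengths.
    extinction : ndarray, shape (2, 2)
        Molar extinction coefficients in 1/(mM*cm); ``extinction[w, c]``
        for wavelength ``w`` and chromophore ``c`` in (HbO, HbR).
    distance_cm : float
        Source-detector separation.
    dpf : tuple of float
        Differential pathlength factor per wavelength (unitless).
    """

    wavelengths_nm: tuple[float, float] = (695.0, 830.0)
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    distance_cm: float = 3.0
    dpf: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self) -> None:
        eps = np.asarray(self.extinction, dtype=float)
        if eps.shape != (2, 2):
            raise ConfigurationError("extinction matrix must be 2x2")
        if abs(np.linalg.det(eps)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        if self.distance_cm <= 0:
            raise ConfigurationError("source-detector distance must be > 0")
        if any(d <= 0 for d in self.dpf):
            raise ConfigurationError("differential pathlength factors must be > 0")
        object.__setattr__(self, "extinction", eps)

    @property
    def pathlength_matrix(self) -> np.ndarray:
        """Effective 2x2 system matrix ``d * DPF_w * eps[w, c]``."""
        dpf = np.asarray(self.dpf, dtype=float)
        return self.distance_cm * dpf[:, None] * self.extinction


@dataclass
class OpticalTimeSeries:
    """Dual-wavelength raw light intensities, shape (2, n_channels, n_samples)."""

    intensities: np.ndarray
    channel_ids: list[str]
    sampling_rate: float
    wavelengths_nm: tuple[float, float] = (695.0, 830.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or self.intensities.shape[0] != 2:
            raise DataError(
                "intensities must have shape (2, n_channels, n_samples), got "
                f"{self.intensities.shape}"
            )
        if self.intensities.shape[1] != len(self.channel_ids):
            raise DataError("channel_ids length does not match intensity array")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be > 0")
        if not np.all(self.intensities > 0):
            raise DataError("light intensities must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]


@dataclass
class HemoglobinTimeSeries:
    """Per-channel HbO/HbR concentration-change traces at a fixed rate.

    ``hbo`` and ``hbr`` are (n_channels, n_samples) arrays in mM (or
    mM*cm when the pathlength is not resolved); channel order matches
    ``channel_ids``.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    channel_ids: list[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise DataError(
                f"HbO shape {self.hbo.shape} != HbR shape {self.hbr.shape}"
            )
        if self.hbo.shape[0] != len(self.channel_ids):
            raise DataError("channel_ids length does not match signal array")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise DataError("duplicate channel ids in time series")
        if not (np.isfinite(self.hbo).all() and np.isfinite(self.hbr).all()):
            raise DataError("time series contain non-finite samples")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be > 0")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "HemoglobinTimeSeries":
        return HemoglobinTimeSeries(
            hbo=self.hbo.copy(),
            hbr=self.hbr.copy(),
            channel_ids=list(self.channel_ids),
            sampling_rate=self.sampling_rate,
        )

    def select(self, ids: list[str]) -> "HemoglobinTimeSeries":
        """Return a copy restricted to ``ids``, in that order."""
        index = {c: i for i, c in enumerate(self.channel_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise DataError(f"channels absent from time series: {missing}")
        rows = [index[c] for c in ids]
        return HemoglobinTimeSeries(
            hbo=self.hbo[rows].copy(),
            hbr=self.hbr[rows].copy(),
            channel_ids=list(ids),
            sampling_rate=self.sampling_rate,
        )
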