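"""Synthetic cohorts and recordings with known directed coupling.

The generator emulates the cohort and acquisition conditions the
analysis chain is designed for: Parkinson's patients measured in up to three
stimulation states (first ON, steady-state OFF after two hours without
stimulation, and ON2 immediately after switching back on) with dropout
across sessions (24/22/18 retained), 12-minute 10 Hz recordings on the
forehead channel grid, and a rostro-caudally directed coupling
structure expressed in the 0.06-0.12 Hz band.

Signals are generated from a vector autoregressive (VAR) process so
that the analysis model class contains the generator and parameter
recovery is well posed.  Every channel carries a weak AR(2) resonance
centered inside the analysis band (band-limited Gaussian activity,
rather than a pure sinusoid with a degenerate spectrum); neighboring
levels within a stream are coupled by lagged linear terms whose
rostro-caudal gain carries the injected direction, state and covariate
effects.  HbR is the exact negative of HbO until motion artifacts are
injected, which add a *common-sign* component to both chromophores --
the signature the CBSI correction exploits and removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .connectivity import companion_spectral_radius, simulate_var
from .exceptions import ConfigurationError, DataError, EstimationError
from .grid import ChannelGrid, build_channel_grid
from .signals import HemoglobinTimeSeries, OpticalTimeSeries, OpticsConfig

SESSION_STATES = ("ON", "OFF", "ON2")

#: Default cohort covariate distributions: name -> (location, scale),
#: normal truncated at zero.  Units: years for the three time
#: covariates, mg/day for LEDD, mm^3 for the volume of activated tissue.
DEFAULT_COVARIATES = {
    "age_at_onset": (50.0, 9.0),
    "duration_before_implant": (10.0, 4.0),
    "time_since_implant": (4.0, 2.5),
    "ledd": (600.0, 250.0),
    "vat": (200.0, 80.0),
}


@dataclass(frozen=True)
class EffectSizes:
    """Coefficients injected into the rostro-caudal coupling strength.

    All terms are additive on the *normalized* coupling strength kappa,
    expressed in units of the in-band resonance peak gain (the raw VAR
    coupling coefficient is ``kappa / peak``).  On this scale the
    adjacent-pair directed coherence behaves like
    ``kappa / sqrt(1 + kappa^2)``, so kappa around 1 sits on the
    sensitive part of the detection curve, and reciprocal coupling is
    stable when ``kappa_rc * kappa_cr`` stays well below 1 (chain
    resonances tighten the pairwise bound; see the saturation ceiling
    on :class:`CohortSpec`).  Covariates enter as
    z-scores under the cohort-spec distributions, the stimulation state
    as an ON indicator (ON and ON2 = 1, OFF = 0).

    ``state_direction_duration`` is negative by default: switching
    stimulation ON strengthens rostro-caudal coupling in early-implanted
    participants and weakens it in late-implanted ones.
    """

    direction: float = 0.75
    state_direction: float = 0.20
    state_direction_duration: float = -0.35
    vat_direction: float = 0.15
    ledd_direction: float = 0.15

    def null(self) -> "EffectSizes":
        return EffectSizes(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort and its recordings."""

    n_participants: int = 24
    session_plan: tuple[tuple[str, int], ...] = (("ON", 24), ("OFF", 22), ("ON2", 18))
    covariate_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    duration_correlation: float = 0.79
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    coupling_base: float = 0.10
    coupling_max: float = 2.2  # saturation ceiling on any single connection
    coupling_lag: int = 3  # samples
    resonance_hz: float = 0.09
    resonance_radius: float = 0.90
    covariate_zclip: float = 2.0
    random_stream_sd: float = 0.05  # participant x stream gain jitter
    random_level_sd: float = 0.05  # participant x level-pair gain jitter
    duration_s: float = 720.0
    sampling_rate: float = 10.0
    hb_amplitude_mm: float = 5e-4  # target per-channel SD in mM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        retained = [n for _, n in self.session_plan]
        if any(b > a for a, b in zip(retained, retained[1:])):
            raise ConfigurationError(
                f"retained_n must be non-increasing over sessions, got {retained}"
            )
        for state, n in self.session_plan:
            if state not in SESSION_STATES:
                raise ConfigurationError(f"unknown session state {state!r}")
            if not 0 <= n <= self.n_participants:
                raise ConfigurationError(
                    f"retained n={n} outside [0, {self.n_participants}]"
                )
        for name, (loc, scale) in self.covariate_distributions.items():
            if scale < 0:
                raise ConfigurationError(f"negative scale for covariate {name!r}")
        if not 0.0 < self.resonance_radius < 1.0:
            raise ConfigurationError("resonance_radius must be in (0, 1)")
        if self.coupling_lag < 1:
            raise ConfigurationError("coupling_lag must be >= 1 sample")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))


@dataclass
class ParticipantRecord:
    """Per-participant covariates; the three time covariates sum to age."""

    id: str
    side_of_onset: str
    age_at_onset: float
    duration_before_implant: float
    time_since_implant: float
    ledd: float
    vat: float

    @property
    def chronological_age(self) -> float:
        return self.age_at_onset + self.duration_before_implant + self.time_since_implant

    @property
    def overall_disease_duration(self) -> float:
        return self.duration_before_implant + self.time_since_implant


@dataclass
class GroundTruth:
    """What the generator injected, for recovery tests downstream."""

    coupling: np.ndarray  # (k, k) gain of source j on sink i at the coupling lag
    drive_band: tuple[float, float]
    artifact_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    gain_rostro_caudal: float = np.nan
    gain_caudo_rostral: float = np.nan
    spectral_radius: float = np.nan


def _pair_correlation_for_total(sp: float, ss: float, target: float) -> float:
    """Correlation r between pre- and post-implant durations such that
    corr(pre, pre + post) equals ``target``, given their scales."""

    def f(r: float) -> float:
        cov = r * sp * ss
        st = np.sqrt(sp**2 + ss**2 + 2 * cov)
        return (sp**2 + cov) / (sp * st)

    res = minimize_scalar(f, bounds=(-0.999, 0.999), method="bounded")
    r_min, f_min = res.x, res.fun
    if target < f_min - 1e-9 or target > 1.0:
        raise ConfigurationError(
            f"duration correlation {target} unattainable; minimum for these "
            f"scales is {f_min:.3f}"
        )
    if f(0.999) >= target >= f_min:
        return brentq(lambda r: f(r) - target, r_min, 0.999)
    return brentq(lambda r: f(r) - target, -0.999, r_min)


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float, n: int) -> np.ndarray:
    """Normal draws truncated at zero by rejection (degenerate scale allowed)."""
    if scale == 0:
        if loc < 0:
            raise ConfigurationError(f"degenerate covariate with negative location {loc}")
        return np.full(n, loc)
    out = rng.normal(loc, scale, size=n)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(loc, scale, size=int(bad.sum()))
    raise ConfigurationError(
        f"truncation at 0 rejects almost all mass for loc={loc}, scale={scale}"
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[ParticipantRecord]:
    """Draw a cohort of participants with correlated disease-time covariates.

    The correlation between ``duration_before_implant`` and the overall
    disease duration (their sum with ``time_since_implant``) is
    engineered to ``spec.duration_correlation`` in the generating
    distribution; draws are truncated at zero.  Deterministic given the
    spec and seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_participants
    dists = spec.covariate_distributions
    missing = set(DEFAULT_COVARIATES) - set(dists)
    if missing:
        raise ConfigurationError(f"covariate distributions missing: {sorted(missing)}")
    loc_p, sc_p = dists["duration_before_implant"]
    loc_s, sc_s = dists["time_since_implant"]
    if sc_p > 0 and sc_s > 0:
        r = _pair_correlation_for_total(sc_p, sc_s, spec.duration_correlation)
        cov = np.array(
            [[sc_p**2, r * sc_p * sc_s], [r * sc_p * sc_s, sc_s**2]]
        )
        draws = rng.multivariate_normal([loc_p, loc_s], cov, size=n)
        for _ in range(1000):
            bad = (draws < 0).any(axis=1)
            if not bad.any():
                break
            draws[bad] = rng.multivariate_normal([loc_p, loc_s], cov, size=int(bad.sum()))
        else:
            raise ConfigurationError("truncation at 0 rejects almost all duration mass")
        dur_pre, dur_post = draws[:, 0], draws[:, 1]
    else:
        dur_pre = _truncated_normal(rng, loc_p, sc_p, n)
        dur_post = _truncated_normal(rng, loc_s, sc_s, n)
    age = _truncated_normal(rng, *dists["age_at_onset"], n)
    ledd = _truncated_normal(rng, *dists["ledd"], n)
    vat = _truncated_normal(rng, *dists["vat"], n)
    sides = rng.choice(["left", "right"], size=n)
    return [
        ParticipantRecord(
            id=f"P{i + 1:02d}",
            side_of_onset=str(sides[i]),
            age_at_onset=float(age[i]),
            duration_before_implant=float(dur_pre[i]),
            time_since_implant=float(dur_post[i]),
            ledd=float(ledd[i]),
            vat=float(vat[i]),
        )
        for i in range(n)
    ]


def _zscore(value: float, dist: tuple[float, float], clip: float = 2.0) -> float:
    loc, scale = dist
    if scale == 0:
        return 0.0
    return float(np.clip((value - loc) / scale, -clip, clip))


def coupling_gains(
    participant: ParticipantRecord, state: str, spec: CohortSpec
) -> tuple[float, float]:
    """Rostro-caudal and caudo-rostral coupling gains for one measurement."""
    if state not in SESSION_STATES:
        raise ConfigurationError(f"unknown session state {state!r}")
    es = spec.effect_sizes
    on = 1.0 if state in ("ON", "ON2") else 0.0
    clip = spec.covariate_zclip
    zdur = _zscore(
        participant.duration_before_implant,
        spec.covariate_distributions["duration_before_implant"],
        clip,
    )
    zvat = _zscore(participant.vat, spec.covariate_distributions["vat"], clip)
    zledd = _zscore(participant.ledd, spec.covariate_distributions["ledd"], clip)
    g_rc = (
        spec.coupling_base
        + es.direction
        + es.state_direction * on
        + es.state_direction_duration * on * zdur
        + es.vat_direction * zvat
        + es.ledd_direction * zledd
    )
    g_cr = spec.coupling_base
    return g_rc, g_cr


def _resonance_coefs(spec: CohortSpec) -> tuple[float, float]:
    """AR(2) coefficients with poles at radius r and the resonance frequency."""
    omega = 2.0 * np.pi * spec.resonance_hz / spec.sampling_rate
    r = spec.resonance_radius
    return 2.0 * r * np.cos(omega), -(r**2)


def _resonance_peak_gain(spec: CohortSpec) -> float:
    """|H(f0)| of the channel AR(2), used to normalize coupling strengths."""
    a1, a2 = _resonance_coefs(spec)
    z = np.exp(-1j * 2.0 * np.pi * spec.resonance_hz / spec.sampling_rate)
    return float(1.0 / abs(1.0 - a1 * z - a2 * z**2))


def _analyzed_channel_order(grid: ChannelGrid) -> list[str]:
    sub = grid.analyzed.sort_values(["hemisphere", "stream", "level"])
    return list(sub["id"])


def build_generator_coefs(
    participant: ParticipantRecord,
    state: str,
    grid: ChannelGrid,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[str], GroundTruth]:
    """Generative VAR coefficients for one measurement.

    Returns the coefficient stack, the channel order used, and a
    :class:`GroundTruth` holding the injected coupling gains.  The
    participant x stream and participant x level gain jitters (drawn
    from ``rng``) create genuine between-participant variance at the
    grouping structure the mixed models assume.
    """
    ids = _analyzed_channel_order(grid)
    index = {c: i for i, c in enumerate(ids)}
    k = len(ids)
    p_gen = max(2, spec.coupling_lag)
    a1, a2 = _resonance_coefs(spec)
    coefs = np.zeros((p_gen, k, k))
    # every channel carries the same narrowband AR(2) innovation filter
    # (band-limited Gaussian activity inside the analysis band)
    coefs[0] += np.eye(k) * a1
    coefs[1] += np.eye(k) * a2
    g_rc, g_cr = coupling_gains(participant, state, spec)
    if not (np.isfinite(g_rc) and np.isfinite(g_cr)):
        raise ConfigurationError("coupling gains must be finite")
    peak = _resonance_peak_gain(spec)
    analyzed = grid.analyzed
    lag_idx = spec.coupling_lag - 1
    coupling = np.zeros((k, k))
    if rng is None:
        rng = np.random.default_rng(0)
    streams = sorted(analyzed["stream"].unique())
    hemis = sorted(analyzed["hemisphere"].unique())
    stream_jitter = {
        (h, s): rng.normal(0.0, spec.random_stream_sd) for h in hemis for s in streams
    }
    levels = sorted(analyzed["level"].unique())
    level_jitter = {lv: rng.normal(0.0, spec.random_level_sd) for lv in levels[:-1]}
    for h in hemis:
        for s in streams:
            chain = analyzed[(analyzed["hemisphere"] == h) & (analyzed["stream"] == s)]
            chain = chain.sort_values("level")
            cids = list(chain["id"])
            for a, b in zip(cids[:-1], cids[1:]):
                jit = stream_jitter[(h, s)] + level_jitter[
                    int(chain.loc[chain["id"] == a, "level"].iloc[0])
                ]
                # bounded coupling: a saturation ceiling keeps extreme
                # covariate combinations inside the stable region
                k_rc = float(np.clip(g_rc + jit, 0.0, spec.coupling_max))
                k_cr = float(np.clip(g_cr, 0.0, spec.coupling_max))
                coupling[index[b], index[a]] = k_rc / peak
                coupling[index[a], index[b]] = k_cr / peak
    coefs[lag_idx] += coupling
    radius = companion_spectral_radius(coefs)
    if radius >= 1.0:
        raise EstimationError(
            f"implied generative VAR is unstable (companion spectral radius "
            f"{radius:.4f} >= 1); reduce coupling gains or resonance radius"
        )
    gt = GroundTruth(
        coupling=coupling,
        drive_band=(0.06, 0.12),
        gain_rostro_caudal=g_rc,
        gain_caudo_rostral=g_cr,
        spectral_radius=radius,
    )
    return coefs, ids, gt


def simulate_measurement(
    participant: ParticipantRecord,
    state: str,
    grid: ChannelGrid | None = None,
    spec: CohortSpec | None = None,
    seed: int | None = None,
) -> tuple[HemoglobinTimeSeries, GroundTruth]:
    """Simulate one 12-min recording for a participant in a given state.

    HbO is the generative VAR output rescaled to a physiological
    amplitude; HbR is exactly ``-HbO`` (perfect anticorrelation before
    any artifact injection).
    """
    if grid is None:
        grid = build_channel_grid()
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    coefs, ids, gt = build_generator_coefs(participant, state, grid, spec, rng=rng)
    x = simulate_var(coefs, spec.n_samples, rng)
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    hbo = x * (spec.hb_amplitude_mm / sd)[:, None]
    ts = HemoglobinTimeSeries(
        hbo=hbo, hbr=-hbo, channel_ids=ids, sampling_rate=spec.sampling_rate
    )
    return ts, gt


def inject_artifacts(
    ts: HemoglobinTimeSeries,
    rate_per_min: float,
    amplitude_sd: float = 5.0,
    seed: int | None = None,
    ground_truth: GroundTruth | None = None,
    decay_s: float = 1.0,
) -> HemoglobinTimeSeries:
    """Add motion-like spike artifacts with the SAME sign on HbO and HbR.

    Events arrive as a Poisson process at ``rate_per_min``; each adds an
    exponentially decaying transient of ``amplitude_sd`` times the
    channel SD to every channel, with identical sign on both
    chromophores (the motion signature that breaks the physiological
    anticorrelation and that CBSI removes).  Event sample indices are
    recorded on ``ground_truth`` when one is passed.
    """
    if rate_per_min < 0:
        raise DataError("artifact rate must be >= 0")
    out = ts.copy()
    if rate_per_min == 0:
        if ground_truth is not None:
            ground_truth.artifact_times = np.array([], dtype=int)
        return out
    rng = np.random.default_rng(seed)
    duration_min = ts.duration_s / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    times = np.sort(rng.integers(0, ts.n_samples, size=n_events))
    kernel_len = max(1, int(round(5 * decay_s * ts.sampling_rate)))
    kernel = np.exp(-np.arange(kernel_len) / (decay_s * ts.sampling_rate))
    bump = np.zeros(ts.n_samples)
    for t0, sign in zip(times, rng.choice([-1.0, 1.0], size=n_events)):
        seg = min(kernel_len, ts.n_samples - t0)
        bump[t0 : t0 + seg] += sign * kernel[:seg]
    sd_o = ts.hbo.std(axis=1, ddof=1)[:, None]
    sd_r = ts.hbr.std(axis=1, ddof=1)[:, None]
    out.hbo = out.hbo + amplitude_sd * sd_o * bump[None, :]
    out.hbr = out.hbr + amplitude_sd * sd_r * bump[None, :]
    if ground_truth is not None:
        ground_truth.artifact_times = times
    return out


def generate_raw_intensities(
    ts: HemoglobinTimeSeries,
    optics: OpticsConfig | None = None,
    baseline_intensity: float = 1.0,
) -> OpticalTimeSeries:
    """Inverse MBLL: dual-wavelength intensities implying ``ts``.

    ``I(w, t) = I0 * 10**(-dOD(w, t))`` with ``dOD = d * DPF * eps @
    [HbO, HbR]``.  The forward conversion re-references optical density
    to the temporal mean intensity, so a round trip recovers ``ts`` up
    to that baseline convention: exactly, once per-channel means are
    removed (and exactly without demeaning for any ``ts`` that is a
    fixed point of the convention, e.g. the output of a previous
    conversion).
    """
    if optics is None:
        optics = OpticsConfig()
    system = optics.pathlength_matrix  # (2, 2)
    conc = np.stack([ts.hbo, ts.hbr])  # (2, k, n)
    dod = np.einsum("wc,cks->wks", system, conc)
    intensities = baseline_intensity * 10.0 ** (-dod)
    return OpticalTimeSeries(
        intensities=intensities,
        channel_ids=list(ts.channel_ids),
        sampling_rate=ts.sampling_rate,
        wavelengths_nm=optics.wavelengths_nm,
    )


def simulate_connection_table(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    dc_intercept: float = 0.10,
    dc_sensitivity: float = 0.08,
    stream_sd: float = 0.015,
    level_sd: float = 0.02,
    noise_sd: float = 0.06,
) -> "pd.DataFrame":
    """Draw a cohort's connection table directly at the DC level.

    Fast-path generator for Monte-Carlo calibration of the mixed-model
    machinery (type-I error, power, null retention), skipping the
    signal-level pipeline: each connection's DC value is a linearized
    response ``dc_intercept + dc_sensitivity * kappa`` of the coupling
    strength the spec implies for that participant/state/direction, plus
    participant x stream and participant x level random intercepts and
    white residual noise.  Default scales mirror what the full
    signal-level pipeline produces on the default cohort.
    """
    import pandas as pd

    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cohort = {p.id: p for p in generate_cohort(spec, seed=rng.integers(2**31))}
    retained = session_retention(spec, seed=int(rng.integers(2**31)))
    hemis = ("left", "right")
    streams = (1, 2, 3, 4)
    pairs = ("1-2", "2-3", "3-4")
    u_stream = {
        (pid, h, s): rng.normal(0, stream_sd)
        for pid in cohort for h in hemis for s in streams
    }
    u_level = {(pid, lp): rng.normal(0, level_sd) for pid in cohort for lp in pairs}
    rows = []
    for state, _ in spec.session_plan:
        for pid in retained[state]:
            part = cohort[pid]
            g_rc, g_cr = coupling_gains(part, state, spec)
            for h in hemis:
                for s in streams:
                    for lp in pairs:
                        for direction, kappa in (
                            ("rostro-caudal", g_rc),
                            ("caudo-rostral", g_cr),
                        ):
                            dc = (
                                dc_intercept
                                + dc_sensitivity * kappa
                                + u_stream[(pid, h, s)]
                                + u_level[(pid, lp)]
                                + rng.normal(0, noise_sd)
                            )
                            rows.append(
                                (pid, state, h, s, lp, direction, dc,
                                 part.side_of_onset, part.age_at_onset,
                                 part.duration_before_implant,
                                 part.time_since_implant, part.ledd, part.vat)
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "state", "hemisphere", "stream", "level_pair",
            "direction", "dc", "side_of_onset", "age_at_onset",
            "duration_before_implant", "time_since_implant", "ledd", "vat",
        ],
    )


def session_retention(spec: CohortSpec, seed: int | None = None) -> dict[str, list[str]]:
    """Deterministic nested dropout: which participant ids attend each session."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 104729)
    ids = [f"P{i + 1:02d}" for i in range(spec.n_participants)]
    retained: dict[str, list[str]] = {}
    current = list(ids)
    for state, n in spec.session_plan:
        if n > len(current):
            raise ConfigurationError(
                f"cannot retain {n} participants in state {state}: only "
                f"{len(current)} remain"
            )
        keep = sorted(rng.choice(len(current), size=n, replace=False))
        current = [current[i] for i in keep]
        retained[state] = list(current)
    return retained


def simulate_cohort(
    spec: CohortSpec | None = None,
    grid: ChannelGrid | None = None,
    artifact_rate_per_min: float = 0.0,
    artifact_amplitude_sd: float = 5.0,
):
    """Yield ``(participant, state, ts, ground_truth)`` for a full cohort.

    Sessions follow ``spec.session_plan`` with nested dropout; every
    measurement uses an independent child seed derived from
    ``spec.seed``, so the whole cohort is reproducible bit-for-bit.
    """
    if spec is None:
        spec = CohortSpec()
    if grid is None:
        grid = build_channel_grid()
    cohort = {p.id: p for p in generate_cohort(spec)}
    retained = session_retention(spec)
    seq = np.random.SeedSequence(spec.seed)
    children = iter(seq.spawn(sum(len(v) for v in retained.values()) * 2))
    for state, _ in spec.session_plan:
        for pid in retained[state]:
            participant = cohort[pid]
            meas_seed = int(next(children).generate_state(1)[0] % (2**31))
            art_seed = int(next(children).generate_state(1)[0] % (2**31))
            ts, gt = simulate_measurement(participant, state, grid, spec, seed=meas_seed)
            if artifact_rate_per_min > 0:
                ts = inject_artifacts(
                    ts,
                    artifact_rate_per_min,
                    artifact_amplitude_sd,
                    seed=art_seed,
                    ground_truth=gt,
                )
            yield participant, state, ts, gt
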