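"""End-to-end runs: configuration, stage orchestration, manifests."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import estimate_connectivity
from .exceptions import ConfigurationError
from .grid import build_channel_grid
from .io import (
    read_grid,
    sha256_file,
    write_dc_matrix,
    write_grid,
    write_manifest,
    write_table,
    write_timeseries,
)
from .lmm import LMMSpec, prepare_connection_table, reduce_model, type3_tests, vif_check
from .network import extract_stream_connections, label_hemispheres
from .preprocessing import preprocess
from .simulate import CohortSpec, EffectSizes, generate_cohort, simulate_cohort


@dataclass
class RunConfig:
    """Parameters of a reproducible pipeline run (YAML round-trippable)."""

    seed: int = 0
    n_participants: int = 24
    session_plan: list = field(
        default_factory=lambda: [["ON", 24], ["OFF", 22], ["ON2", 18]]
    )
    duration_s: float = 720.0
    sampling_rate: float = 10.0
    effect_sizes: dict = field(default_factory=dict)
    artifact_rate_per_min: float = 0.0
    artifact_amplitude_sd: float = 5.0
    layout_path: str | None = None
    var_order: int = 20
    band: list = field(default_factory=lambda: [0.06, 0.12])
    fit_scope: str = "all"
    model: str = "model2"
    alpha: float = 0.05
    write_signals: bool = False
    verbose: bool = False

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_participants=self.n_participants,
            session_plan=tuple((s, int(n)) for s, n in self.session_plan),
            effect_sizes=EffectSizes(**self.effect_sizes),
            duration_s=self.duration_s,
            sampling_rate=self.sampling_rate,
            seed=self.seed,
        )

    def model_spec(self) -> LMMSpec:
        if self.model == "model1":
            return LMMSpec.model1(alpha=self.alpha)
        if self.model == "model2":
            return LMMSpec.model2(alpha=self.alpha)
        raise ConfigurationError(f"unknown model {self.model!r}")


def cohort_connection_table(
    spec: CohortSpec,
    grid=None,
    var_order: int = 20,
    band: tuple[float, float] = (0.06, 0.12),
    fit_scope: str = "all",
    artifact_rate_per_min: float = 0.0,
) -> pd.DataFrame:
    """Simulate a cohort and run it through preprocessing and connectivity.

    Returns the pooled, covariate-joined, hemisphere-labelled connection
    table ready for mixed-effects modelling.
    """
    from .lmm import prepare_connection_table
    from .network import label_hemispheres
    from .simulate import simulate_cohort

    if grid is None:
        grid = build_channel_grid()
    cohort = generate_cohort(spec)
    tables = []
    for participant, state, ts, _ in simulate_cohort(
        spec, grid, artifact_rate_per_min=artifact_rate_per_min
    ):
        clean = preprocess(ts, grid, apply_cbsi=True)
        dc = estimate_connectivity(
            clean, order=var_order, band=band, grid=grid, fit_scope=fit_scope
        )
        tables.append(
            extract_stream_connections(dc, grid, participant=participant.id, state=state)
        )
    pooled = pd.concat(tables, ignore_index=True)
    pooled = label_hemispheres(pooled, {p.id: p.side_of_onset for p in cohort})
    return prepare_connection_table(pooled, cohort)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute simulate -> preprocess -> connect -> extract -> model.

    All intermediates are persisted under ``outdir``; the returned (and
    written) manifest snapshots the configuration, software version,
    per-file checksums and every warning raised during the run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # resolve configuration fully before any compute
    grid = read_grid(config.layout_path) if config.layout_path else build_channel_grid()
    spec = config.cohort_spec()
    model_spec = config.model_spec()
    band = tuple(config.band)

    captured: list[str] = []
    files: list[Path] = []

    cohort = generate_cohort(spec)
    cohort_table = pd.DataFrame(
        {
            "participant": [p.id for p in cohort],
            "side_of_onset": [p.side_of_onset for p in cohort],
            "age_at_onset": [p.age_at_onset for p in cohort],
            "duration_before_implant": [p.duration_before_implant for p in cohort],
            "time_since_implant": [p.time_since_implant for p in cohort],
            "ledd": [p.ledd for p in cohort],
            "vat": [p.vat for p in cohort],
        }
    )
    files.append(write_table(cohort_table, outdir / "cohort.tsv"))
    files.append(write_grid(grid, outdir / "grid.yaml"))

    tables = []
    truth_rows = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        for participant, state, ts, gt in simulate_cohort(
            spec,
            grid,
            artifact_rate_per_min=config.artifact_rate_per_min,
            artifact_amplitude_sd=config.artifact_amplitude_sd,
        ):
            stem = f"{participant.id}_{state}"
            if config.write_signals:
                files.append(write_timeseries(ts, outdir / "signals" / f"{stem}.tsv"))
            clean = preprocess(ts, grid, apply_cbsi=True)
            dc = estimate_connectivity(
                clean,
                order=config.var_order,
                band=band,
                grid=grid,
                fit_scope=config.fit_scope,
            )
            files.append(write_dc_matrix(dc, outdir / "dc" / f"{stem}.tsv"))
            part = extract_stream_connections(
                dc, grid, participant=participant.id, state=state
            )
            tables.append(part)
            truth_rows.append(
                {
                    "participant": participant.id,
                    "state": state,
                    "gain_rostro_caudal": gt.gain_rostro_caudal,
                    "gain_caudo_rostral": gt.gain_caudo_rostral,
                    "spectral_radius": gt.spectral_radius,
                    "n_artifacts": len(gt.artifact_times),
                }
            )
        pooled = pd.concat(tables, ignore_index=True)
        sides = {p.id: p.side_of_onset for p in cohort}
        pooled = label_hemispheres(pooled, sides)
        pooled = prepare_connection_table(pooled, cohort)
        files.append(write_table(pooled, outdir / "connections.tsv"))
        files.append(write_table(pd.DataFrame(truth_rows), outdir / "ground_truth.tsv"))

        result = reduce_model(pooled, model_spec)
        ftable = type3_tests(result)
        for w in wrec:
            captured.append(str(w.message))

    files.append(write_table(ftable.reset_index(), outdir / "model_ftable.tsv"))
    coef = pd.DataFrame(
        {"coefficient": result.params, "se": np.sqrt(np.diag(result.cov_params))}
    ).reset_index(names="column")
    files.append(write_table(coef, outdir / "model_coefficients.tsv"))
    files.append(
        write_table(
            pd.DataFrame(
                result.reduction_history or [],
                columns=["step", "term", "p_at_removal"],
            ),
            outdir / "model_reduction_log.tsv",
        )
    )
    numeric = [
        c
        for c in (
            "age_at_onset", "duration_before_implant", "time_since_implant",
            "ledd", "vat",
        )
        if c in pooled.columns
    ]
    if len(numeric) >= 2:
        files.append(
            write_table(vif_check(pooled, numeric).reset_index(), outdir / "vif.tsv")
        )

    report = [
        f"dcgradient v{__version__} pipeline run",
        f"participants: {spec.n_participants}; sessions: {list(spec.session_plan)}",
        f"measurements: {len(truth_rows)}; connection rows: {len(pooled)}",
        f"model: {config.model}; terms retained: {len(result.terms)}",
        f"removed terms: {[h['term'] for h in result.reduction_history]}",
        f"variance components: {result.vcomp}; sigma2: {result.sigma2:.6g}",
        "",
        ftable.to_string(),
    ]
    report_path = outdir / "report.txt"
    report_path.write_text("\n".join(report) + "\n")
    files.append(report_path)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "warnings": captured,
        "files": {str(f.relative_to(outdir)): sha256_file(f) for f in files},
    }
    write_manifest(manifest, outdir / "manifest.json")
    return manifest
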