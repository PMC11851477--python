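"""End-to-end orchestration: patient record -> signals -> fit -> report.

``run_pipeline`` ties the library together for one patient cohort.  Per
patient it emits six artifacts into the output directory:

1. ``<id>_profile.csv``    — hemodynamic profile at printed precision,
2. ``<id>_input.csv``      — pulsatile input flow signal,
3. ``<id>_target.csv``     — phase-shifted, ABI-scaled target signal,
4. ``<id>_fit.json``       — fitted R1, R2, L, C, objective breakdown, trace,
5. ``<id>_tf.json``        — transfer-function coefficients (full + 4 s.f.),
6. ``<id>_stability.json`` — poles, Routh column, damping report,

plus a ``manifest.json`` listing every file with its SHA-256 checksum
and the seed used.  All randomness flows from the single configured
seed, so a rerun with the same configuration is byte-identical.

By default the input pulse amplitude is the
normotensive baseline capillary flow and the target amplitude is the
patient's ABI-scaled capillary flow, delayed by a quarter of the
systolic sine period.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hemodynamics as hemo
from .circuit import CircuitParams, assemble_state_space, to_transfer_function
from .exceptions import CapfitError, ConfigurationError
from .fitting import PSOConfig, make_objective, pso_optimize
from .stability import stability_report
from .waveforms import SampledSignal, WaveformSpec, phase_shifted_target, systolic_pulse, write_signal


def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant figures."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{n_sig - 1}e}")


@dataclass
class RunConfig:
    """Top-level configuration for :func:`run_pipeline`."""

    patients_csv: str | None = None
    output_dir: str = "capfit-out"
    seed: int = 0
    waveform: dict = field(default_factory=dict)
    pso: dict = field(default_factory=dict)
    verbosity: int = 0

    def waveform_spec(self, peak_flow: float) -> WaveformSpec:
        try:
            return WaveformSpec(peak_flow=peak_flow, **self.waveform)
        except (TypeError, CapfitError) as exc:
            raise ConfigurationError(f"invalid waveform configuration: {exc}") from exc

    def pso_config(self, seed: int) -> PSOConfig:
        try:
            return PSOConfig(rng_seed=seed, **self.pso)
        except (TypeError, CapfitError) as exc:
            raise ConfigurationError(f"invalid PSO configuration: {exc}") from exc


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — a YAML subset) run configuration file."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot load config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def render_patient_table(
    profiles: dict[str, hemo.HemodynamicProfile], fmt: str = "dataframe"
):
    """Patient hemodynamics table at the conventional printed precision.

    Pressures are rounded to 4 significant figures, flows and
    resistances to 3.  ``fmt`` selects a pandas DataFrame (default),
    ``"csv"`` text, or a ``"markdown"`` table.
    """
    if not profiles:
        raise ConfigurationError("need at least one profile")
    rows = []
    for patient_id, p in profiles.items():
        rows.append(
            {
                "patient": patient_id,
                "arterial_pressure_mmHg": round_sig(p.arterial_pressure_mmhg, 4),
                "capillary_pressure_mmHg": round_sig(p.capillary_pressure_mmhg, 4),
                "arterial_flow_m3_s": round_sig(p.arterial_flow_m3_s, 3),
                "capillary_flow_m3_s": round_sig(p.capillary_flow_m3_s, 3),
                "arterial_resistance_Pa_s_m3": round_sig(p.arterial_resistance, 3),
                "capillary_resistance_Pa_s_m3": round_sig(p.capillary_resistance, 3),
            }
        )
    df = pd.DataFrame(rows)
    if fmt == "dataframe":
        return df
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "markdown":
        header = "| " + " | ".join(df.columns) + " |"
        rule = "|" + "|".join("---" for _ in df.columns) + "|"
        body = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
        return "\n".join([header, rule, *body])
    raise ConfigurationError(f"unknown table format {fmt!r}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-patient pipeline; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = hemo.load_patients(config.patients_csv)
    files: list[Path] = []

    profiles = {p.patient_id: hemo.limb_scaled_profile(p) for p in patients}
    table_path = out / "patient_table.csv"
    table_path.write_text(render_patient_table(profiles, fmt="csv"))
    files.append(table_path)

    for idx, patient in enumerate(patients):
        stage = f"patient {patient.patient_id}"
        try:
            profile_path = out / f"{patient.patient_id}_profile.csv"
            profile_path.write_text(
                render_patient_table({patient.patient_id: profiles[patient.patient_id]}, fmt="csv")
            )

            spec = config.waveform_spec(peak_flow=hemo.baseline_capillary_flow())
            input_signal = systolic_pulse(spec)
            target = phase_shifted_target(
                input_signal, spec, amplitude=hemo.abi_scaled_capillary_flow(patient.ankle_systolic)
            )
            input_path = out / f"{patient.patient_id}_input.csv"
            target_path = out / f"{patient.patient_id}_target.csv"
            write_signal(input_signal, input_path)
            write_signal(target, target_path)

            seed = int(config.seed) + idx
            pso_config = config.pso_config(seed)
            result = pso_optimize(make_objective(input_signal, target), pso_config)
            params = CircuitParams.from_array(result.gbest_position)
            breakdown = make_objective(input_signal, target)(result.gbest_position)
            fit_path = out / f"{patient.patient_id}_fit.json"
            _write_json(
                fit_path,
                {
                    "seed": seed,
                    "params": {"R1": params.r1, "R2": params.r2, "L": params.l, "C": params.c},
                    "objective": {
                        "ise": breakdown.ise,
                        "itse": breakdown.itse,
                        "total": breakdown.total,
                    },
                    "evaluations": result.evaluations,
                    "convergence_trace": result.convergence_trace.tolist(),
                },
            )

            tf = to_transfer_function(assemble_state_space(params))
            tf_path = out / f"{patient.patient_id}_tf.json"
            _write_json(
                tf_path,
                {
                    "seed": seed,
                    "numerator": tf.num.tolist(),
                    "denominator": tf.den.tolist(),
                    "numerator_4sf": [round_sig(v, 4) for v in tf.num],
                    "denominator_4sf": [round_sig(v, 4) for v in tf.den],
                    "dc_gain": tf.dc_gain(),
                },
            )

            report = stability_report(tf)
            stab_path = out / f"{patient.patient_id}_stability.json"
            _write_json(
                stab_path,
                {
                    "seed": seed,
                    "stable": report.stable,
                    "poles": [[p.real, p.imag] for p in report.poles],
                    "routh_first_column": list(report.routh_first_column),
                    "sign_changes": report.sign_changes,
                    "damping_ratio": report.damping_ratio,
                    "natural_frequency": report.natural_frequency,
                    "classification": report.classification,
                },
            )
            files.extend([profile_path, input_path, target_path, fit_path, tf_path, stab_path])
        except CapfitError as exc:
            raise CapfitError(f"pipeline stage failed ({stage}): {exc}") from exc

    manifest = {
        "seed": int(config.seed),
        "files": {f.name: _sha256(f) for f in files},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
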