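"""Scenario generation, persistence and experiment orchestration.

Disturbance time series with the spectral structure the analysis assumes
(single dominant line for sea/air travel, broadband for overland), CSV/JSON
round-tripping of sweep tables and reports, stable per-stage seed
derivation, and a dispatcher that runs the named experiments reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from . import jacobian_ensemble as je
from . import plasticity_switch as ps
from . import posture_adaptation as pa

__all__ = [
    "ExperimentConfig",
    "RunRecord",
    "EXPERIMENTS",
    "make_disturbance",
    "spectral_dominance",
    "derive_seed",
    "read_sweep_csv",
    "write_sweep_csv",
    "run_experiment",
]

logger = logging.getLogger("mdds_loops")

EXPERIMENTS = (
    "sweep_inhibition",
    "sweep_self_inhibition",
    "posture_demo",
    "plasticity_demo",
    "full_chain",
    "classify",
)


def make_disturbance(spec: pa.DisturbanceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sampled disturbance series (t, d) on the aboard grid.

    ``pure_sine``: D sin(2 pi f t); ``sine_plus_noise``: the same plus white
    Gaussian noise; ``broadband``: low-pass filtered Gaussian noise with no
    dominant spectral line, RMS-matched to the sine amplitude.
    """
    return pa._disturbance_series(spec)


def spectral_dominance(series: np.ndarray, dt: float, f: float) -> float:
    """Fraction of total power concentrated at frequency ``f``.

    Hann-windowed periodogram, summed over the window's mainlobe (+/- 2
    bins), so a pure tone scores ~1 regardless of bin alignment.
    """
    freqs, power = periodogram(series - np.mean(series), fs=1.0 / dt, window="hann")
    total = power.sum()
    if total == 0:
        return 0.0
    bin_width = freqs[1] - freqs[0]
    sel = np.abs(freqs - f) <= 2 * bin_width + 1e-12
    return float(power[sel].sum() / total)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable named per-stage seed: SeedSequence keyed on (master, crc32(stage))."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, np.uint32)[0])


# ---------------------------------------------------------------------------
# sweep table persistence

_SWEEP_COLUMNS = list(je.SweepResult.COLUMNS)


def write_sweep_csv(result: je.SweepResult, path) -> None:
    """Write a sweep table; floats at full (round-trip) precision."""
    result.table.to_csv(path, index=False, float_format="%.17g")


def read_sweep_csv(path) -> je.SweepResult:
    """Header-keyed parse of a sweep table (column order is free)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed sweep CSV {path}: {exc}") from exc
    missing = set(_SWEEP_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"sweep CSV {path} missing columns: {sorted(missing)}")
    for line_no, row in enumerate(table.itertuples(index=False), start=2):
        for col, v in zip(table.columns, row):
            if col in _SWEEP_COLUMNS and not np.isfinite(v):
                raise ValueError(f"non-numeric cell in column {col!r} at line {line_no}")
    return je.SweepResult(table)


def read_matrix(path) -> np.ndarray:
    """A 4x4 matrix from CSV (4 rows x 4 values) or a JSON array of arrays."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        data = np.asarray(json.loads(text), dtype=float)
    else:
        data = np.loadtxt(path, delimiter=",", dtype=float)
    if data.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {data.shape}")
    return data


# ---------------------------------------------------------------------------
# experiment configuration and dispatch


@dataclass(frozen=True)
class ExperimentConfig:
    """A named experiment with its parameter blocks and master seed."""

    name: str
    seed: int = 0
    out_dir: str = "."
    blocks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}")
        if not isinstance(self.blocks, dict):
            raise ValueError("blocks must be a mapping")

    def digest(self) -> str:
        payload = json.dumps(
            {"name": self.name, "seed": self.seed, "blocks": self.blocks},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        data = json.loads(Path(path).read_text())
        return cls(name=data["name"], seed=int(data.get("seed", 0)),
                   out_dir=data.get("out_dir", "."), blocks=data.get("blocks", {}))


@dataclass(frozen=True)
class RunRecord:
    """Provenance of one experiment run: config digest, derived seeds and the
    manifest of written files with their content hashes."""

    experiment: str
    config_digest: str
    master_seed: int
    stage_seeds: dict
    manifest: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sweep_experiment(config: ExperimentConfig, out: Path) -> tuple[dict, dict]:
    block = dict(config.blocks.get("sweep", {}))
    n_samples = int(block.get("n_samples", je.DEFAULT_N_SAMPLES))
    step = int(block.get("step", 1))
    seed = derive_seed(config.seed, config.name)
    fn = (je.inhibition_sweep if config.name == "sweep_inhibition"
          else je.self_inhibition_sweep)
    result = fn(n_samples=n_samples, step=step, seed=seed)
    path = out / f"{config.name}.csv"
    write_sweep_csv(result, path)
    return {"sweep_seed": seed}, {path.name: _file_digest(path)}


def _posture_experiment(config: ExperimentConfig, out: Path) -> tuple[dict, dict]:
    pb = dict(config.blocks.get("posture", {}))
    db = dict(config.blocks.get("disturbance", {}))
    db.setdefault("seed", derive_seed(config.seed, "disturbance"))
    params = pa.PostureParams(**pb)
    spec = pa.DisturbanceSpec(**db)
    traj = pa.simulate_posture(params, spec)
    f_ring, tau, regime = pa.post_removal_response(traj)
    frame = pd.DataFrame({
        "t": traj.t,
        "phase": np.where(traj.aboard, "aboard", "ashore"),
        "theta": traj.theta, "theta_dot": traj.theta_dot,
        "u_C": traj.u_C, "u_A": traj.u_A, "d": traj.d,
    })
    csv_path = out / "posture_trajectory.csv"
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "params": dataclasses.asdict(params),
        "disturbance": dataclasses.asdict(spec),
        "ringing_frequency_hz": f_ring,
        "tau_s": None if np.isinf(tau) else tau,
        "regime": regime,
    }
    meta_path = out / "posture_report.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return ({"disturbance_seed": db["seed"]},
            {csv_path.name: _file_digest(csv_path), meta_path.name: _file_digest(meta_path)})


def _plasticity_experiment(config: ExperimentConfig, out: Path) -> tuple[dict, dict]:
    block = dict(config.blocks.get("plasticity", {}))
    params = ps.PlasticityParams(**block)
    scan = ps.bifurcation_scan(params)
    table = pd.DataFrame(scan.branches, columns=["B", "L_low", "L_unstable", "L_high"])
    csv_path = out / "bifurcation_diagram.csv"
    table.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "params": dataclasses.asdict(params),
        "regime": scan.regime,
        "B_on": scan.B_on,
        "B_off": scan.B_off,
        "equilibria_at_zero": [list(e) for e in scan.equilibria_at_zero],
    }
    meta_path = out / "plasticity_report.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {}, {csv_path.name: _file_digest(csv_path), meta_path.name: _file_digest(meta_path)}


def _chain_experiment(config: ExperimentConfig, out: Path) -> tuple[dict, dict]:
    block = dict(config.blocks.get("chain", {}))
    block.setdefault("seed", derive_seed(config.seed, "chain"))
    cfg = ps.ChainConfig(**block)
    report = ps.full_chain(cfg)
    path = out / "chain_report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"chain_seed": cfg.seed}, {path.name: _file_digest(path)}


def _classify_experiment(config: ExperimentConfig, out: Path) -> tuple[dict, dict]:
    block = config.blocks.get("classify", {})
    if "matrix_file" not in block:
        raise ValueError("classify experiment requires blocks.classify.matrix_file")
    J = read_matrix(block["matrix_file"])
    result = je.classify_spectrum(J)
    meta = {
        "eigenvalues": [[z.real, z.imag] for z in result.eigenvalues],
        "oscillatory": result.oscillatory,
        "category": result.category,
    }
    path = out / "classification.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {}, {path.name: _file_digest(path)}


_DISPATCH = {
    "sweep_inhibition": _sweep_experiment,
    "sweep_self_inhibition": _sweep_experiment,
    "posture_demo": _posture_experiment,
    "plasticity_demo": _plasticity_experiment,
    "full_chain": _chain_experiment,
    "classify": _classify_experiment,
}


def run_experiment(config: ExperimentConfig) -> RunRecord:
    """Dispatch the named experiment, write its outputs and a RunRecord.

    Identical (config, seed) produce identical output manifests.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("running experiment %s (seed %d) -> %s", config.name, config.seed, out)
    stage_seeds, manifest = _DISPATCH[config.name](config, out)
    record = RunRecord(
        experiment=config.name,
        config_digest=config.digest(),
        master_seed=config.seed,
        stage_seeds=stage_seeds,
        manifest=manifest,
    )
    record.write(out / f"{config.name}_run_record.json")
    return record
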