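"""File formats, pipeline configuration, and the end-to-end per-subject run.

Recordings travel as EDF (read via mne) or as plain CSV channel matrices:
channels as rows, the electrode label in the first column, with a mandatory
YAML side-car (``<name>.meta.yaml``) carrying the sampling rate and units —
a CSV matrix without its side-car is rejected rather than guessed at.
Band-power tables, z-maps, ROI powers and test results are CSV; stimulation
plans are JSON; configs are YAML.  Every pipeline output directory carries a
run-metadata stamp (config hash + seed) so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import targeting, trial_stats
from .spectral import DEFAULT_BANDS, Recording, band_power_pipeline

logger = logging.getLogger("tailored_tacs")

__all__ = [
    "read_recording",
    "write_recording",
    "PipelineConfig",
    "run_pipeline",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml").with_name(
        path.stem + ".meta.yaml"
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a CSV channel matrix plus YAML side-car."""
    path = Path(path)
    df = pd.DataFrame(rec.data, index=pd.Index(rec.labels, name="channel"))
    df.to_csv(path)
    meta = {
        "fs_hz": float(rec.fs),
        "units": "uV",
        "reference": rec.reference,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
    }
    side = _sidecar_path(path)
    side.write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read an EDF or CSV recording.

    ``fmt`` defaults from the file extension.  CSV requires the YAML
    side-car written by :func:`write_recording` (sampling rate is never
    guessed).  EDF is read with mne; unknown or non-10/10 labels pass
    through with a warning.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads volts; store microvolts
        return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                         reference="EDF")
    if fmt == "csv":
        side = _sidecar_path(path)
        if not side.exists():
            raise FileNotFoundError(
                f"missing side-car {side.name}: sampling rate unknown for {path}"
            )
        meta = yaml.safe_load(side.read_text())
        df = pd.read_csv(path, index_col=0)
        from .synthetic_data import DEFAULT_MONTAGE

        known = {x.lower() for x in DEFAULT_MONTAGE} | {"m1", "m2"}
        odd = [c for c in df.index if str(c).lower() not in known]
        if odd:
            logger.warning("labels not in the standard 10/10 montage: %s", odd)
        return Recording(
            df.to_numpy(dtype=float),
            float(meta["fs_hz"]),
            [str(c) for c in df.index],
            reference=str(meta.get("reference", "file")),
        )
    raise ValueError(f"unsupported recording format {fmt!r}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    control_paths : recordings of the healthy normative cohort
    subject_paths : patient recordings to map and plan for
    outcomes_path : optional long-format outcome CSV for the crossover stats
    """

    control_paths: list[str] = field(default_factory=list)
    subject_paths: list[str] = field(default_factory=list)
    outcomes_path: str | None = None
    out_dir: str = "tacs_out"
    z_threshold: float = targeting.Z_THRESHOLD
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow: spectra -> normative model -> z-maps ->
    stimulation plans -> ROI powers, plus crossover statistics when an
    outcome table is provided.

    Writes, per subject: band-power CSV, z-map CSV, plan JSON (or an explicit
    no-target plan), ROI power CSV; and cohort-level results CSV.  Returns a
    manifest of written artifacts.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.digest(), "seed": cfg.seed, "artifacts": []}

    def _emit(path: Path) -> None:
        manifest["artifacts"].append(str(path))

    try:
        logger.info("stage: control spectra (%d recordings)", len(cfg.control_paths))
        controls = [
            band_power_pipeline(read_recording(p), DEFAULT_BANDS)
            for p in cfg.control_paths
        ]
        model = targeting.fit_normative(controls) if controls else None

        logger.info("stage: subject mapping (%d subjects)", len(cfg.subject_paths))
        for spath in cfg.subject_paths:
            stem = Path(spath).stem
            table = band_power_pipeline(read_recording(spath), DEFAULT_BANDS)
            bp_csv = out / f"{stem}_bandpower.csv"
            table.to_csv(bp_csv)
            _emit(bp_csv)

            roi = trial_stats.roi_band_power(table)
            roi_csv = out / f"{stem}_roi_power.csv"
            roi.to_csv(roi_csv)
            _emit(roi_csv)

            if model is None:
                continue
            zmap = targeting.compute_zmap(table, model)
            zmap.threshold = cfg.z_threshold
            z_csv = out / f"{stem}_zmap.csv"
            zmap.to_csv(z_csv)
            _emit(z_csv)

            prev = targeting.prevailing_rhythm(zmap)
            plan_path = out / f"{stem}_plan.json"
            if prev is None:
                plan_path.write_text(json.dumps({"outcome": "no target"}, indent=2))
            else:
                targeting.plan_stimulation(prev).to_json(plan_path)
            _emit(plan_path)

        if cfg.outcomes_path:
            logger.info("stage: crossover statistics")
            outcomes = pd.read_csv(cfg.outcomes_path)
            results = trial_stats.crossover_analysis(outcomes)
            res_csv = out / "test_results.csv"
            trial_stats.results_to_frame(results).to_csv(res_csv, index=False)
            _emit(res_csv)
    except Exception:
        logger.exception("pipeline aborted")
        raise

    stamp = out / "run_metadata.json"
    stamp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
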