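"""Dataset layout: per-trial files, JSON sidecars, and the cohort manifest.

Layout under a dataset root::

    manifest.json                   # trial table, config hash, seed
    ground_truth.json               # injected bursts / coupling / effects
    kinematics/<trial_id>.tsv       # columns t_s, x_cm, y_cm
    lfp/<trial_id>.f32              # little-endian float32 microvolts
    lfp/<trial_id>.json             # sidecar: fs_hz, t0_s, units, intervals...

Kinematic files are plain TSV; LFP is raw float32 plus a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from spiralbeta.kinematics import KinematicTrial
from spiralbeta.lfp import LfpEpoch
from spiralbeta.synthetic import CohortDataset, SimulationConfig

VALID_DRAWING = ("free", "template")
VALID_STIM = ("off", "on")


@dataclass
class ManifestEntry:
    trial_id: str
    subject: str
    drawing: str
    stim: str
    kinematic_file: str
    lfp_file: str
    draw_duration: float
    tremor_subject: bool = False
    rotation: str = "cw"


@dataclass
class DatasetManifest:
    root: Path
    seed: int
    config_hash: str
    entries: list

    @property
    def subjects(self) -> list:
        return sorted({e.subject for e in self.entries})

    def validate(self) -> None:
        for e in self.entries:
            if e.drawing not in VALID_DRAWING or e.stim not in VALID_STIM:
                raise ValueError(f"trial {e.trial_id}: bad condition labels")
            for f in (e.kinematic_file, e.lfp_file):
                if not (self.root / f).exists():
                    raise FileNotFoundError(f"trial {e.trial_id}: missing {f}")
            sidecar = (self.root / e.lfp_file).with_suffix(".json")
            if not sidecar.exists():
                raise FileNotFoundError(f"trial {e.trial_id}: missing LFP sidecar {sidecar.name}")


def config_hash(config: SimulationConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def write_kinematic_tsv(trial: KinematicTrial, path: Path) -> None:
    df = pd.DataFrame({"t_s": trial.t, "x_cm": trial.x, "y_cm": trial.y})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_kinematic_tsv(path: Path, **meta) -> KinematicTrial:
    df = pd.read_csv(path, sep="\t")
    missing = {"t_s", "x_cm", "y_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(df[["t_s", "x_cm", "y_cm"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-finite values at line {bad[0] + 2}")
    return KinematicTrial(
        t=df["t_s"].to_numpy(), x=df["x_cm"].to_numpy(), y=df["y_cm"].to_numpy(), **meta
    )


def write_lfp(epoch: LfpEpoch, path: Path) -> None:
    """float32 binary + JSON sidecar next to it."""
    path = Path(path)
    epoch.signal.astype("<f4").tofile(path)
    sidecar = {
        "fs_hz": epoch.fs,
        "t0_s": epoch.t0,
        "units": "uV",
        "intervals": {k: list(v) for k, v in epoch.intervals.items()},
        "subject": epoch.subject,
        "drawing": epoch.drawing,
        "stim": epoch.stim,
        "n_samples": int(epoch.signal.size),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_lfp(path: Path) -> LfpEpoch:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing LFP sidecar for {path.name}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("units") != "uV":
        raise ValueError(f"{path.name}: expected microvolt units, got {meta.get('units')!r}")
    signal = np.fromfile(path, dtype="<f4").astype(float)
    if "n_samples" in meta and signal.size != meta["n_samples"]:
        raise ValueError(f"{path.name}: sample count mismatch with sidecar")
    return LfpEpoch(
        signal=signal,
        fs=float(meta["fs_hz"]),
        t0=float(meta["t0_s"]),
        intervals={k: tuple(v) for k, v in meta["intervals"].items()},
        subject=meta.get("subject", ""),
        drawing=meta.get("drawing", "free"),
        stim=meta.get("stim", "off"),
    )


def write_dataset(cohort: CohortDataset, root: Path) -> DatasetManifest:
    root = Path(root)
    (root / "kinematics").mkdir(parents=True, exist_ok=True)
    (root / "lfp").mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in cohort.trials:
        kin_file = f"kinematics/{tr.trial_id}.tsv"
        lfp_file = f"lfp/{tr.trial_id}.f32"
        write_kinematic_tsv(tr.kinematic, root / kin_file)
        write_lfp(tr.lfp, root / lfp_file)
        entries.append(
            ManifestEntry(
                trial_id=tr.trial_id,
                subject=tr.subject,
                drawing=tr.drawing,
                stim=tr.stim,
                kinematic_file=kin_file,
                lfp_file=lfp_file,
                draw_duration=tr.draw_duration,
                tremor_subject=tr.kinematic.tremor_subject,
            )
        )
    manifest = DatasetManifest(
        root=root,
        seed=cohort.config.seed,
        config_hash=config_hash(cohort.config),
        entries=entries,
    )
    (root / "manifest.json").write_text(
        json.dumps(
            {
                "seed": manifest.seed,
                "config_hash": manifest.config_hash,
                "entries": [vars(e) for e in entries],
            },
            indent=2,
            sort_keys=True,
        )
    )
    (root / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    (root / "config.json").write_text(cohort.config.to_json())
    return manifest


def read_manifest(root: Path) -> DatasetManifest:
    root = Path(root)
    data = json.loads((root / "manifest.json").read_text())
    manifest = DatasetManifest(
        root=root,
        seed=data["seed"],
        config_hash=data["config_hash"],
        entries=[ManifestEntry(**e) for e in data["entries"]],
    )
    manifest.validate()
    return manifest


def load_trial(manifest: DatasetManifest, entry: ManifestEntry) -> tuple[KinematicTrial, LfpEpoch]:
    kin = read_kinematic_tsv(
        manifest.root / entry.kinematic_file,
        subject=entry.subject,
        drawing=entry.drawing,
        stim=entry.stim,
        rotation=entry.rotation,
        tremor_subject=entry.tremor_subject,
    )
    lfp = read_lfp(manifest.root / entry.lfp_file)
    return kin, lfp


def read_dataset(root: Path) -> list[tuple[ManifestEntry, KinematicTrial, LfpEpoch]]:
    """Eagerly load every trial of a dataset (small cohorts only)."""
    manifest = read_manifest(root)
    return [(e, *load_trial(manifest, e)) for e in manifest.entries]
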