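"""End-to-end pipeline driver: configuration, seeding, artifacts, fixtures.

Every stochastic stage consumes a child seed derived from one master seed and
the stage name, so a run is reproducible bit-for-bit from its config.  Each
run writes a manifest recording the effective config, a config hash,
per-stage record counts and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ErrorConfig, build_augmented_training_set
from .features import FEATURE_NAMES, extract_feature_table
from .forward import (
    LabeledDataset,
    MU_A_RANGE,
    MU_S_RANGE,
    default_standard,
    generate_grid_dataset,
    render_image,
)
from .models import WIRRegressor, kfold_cv
from .rgb import to_fractions, wavelength_to_rgb
from .spectra import ProbeGeometry, default_grid, write_spectra_csv

__all__ = [
    "RunConfig",
    "child_seed",
    "run_pipeline",
    "make_fixtures",
    "write_dataset",
    "read_dataset",
]


def child_seed(master_seed: int, stage: str) -> int:
    """Stage-name -> child seed derivation (stable, below 2^31)."""
    mix = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    n_mu_a: int = 40
    n_mu_s: int = 38
    mu_a_range: tuple[float, float] = MU_A_RANGE
    mu_s_range: tuple[float, float] = MU_S_RANGE
    n_columns: int = 585
    probe_id: int = 1
    snr_linear: float = 35.0
    snr_linear_all_errors: float = 45.0
    shift_nm: float = -4.8
    compress_nm_per_tail: float = 1.0
    rotate_max_frac: float = 0.05
    scale_max_frac: float = 0.05
    n_estimators: int = 200
    max_depth: int = 5
    min_samples_leaf: int = 3
    cv_folds: int = 5
    run_evaluation: bool = True
    seed: int = 0

    def error_config(self, stage: str = "corrupt") -> ErrorConfig:
        return ErrorConfig(
            snr_linear=self.snr_linear,
            snr_linear_all_errors=self.snr_linear_all_errors,
            shift_nm=self.shift_nm,
            compress_nm_per_tail=self.compress_nm_per_tail,
            rotate_max_frac=self.rotate_max_frac,
            scale_max_frac=self.scale_max_frac,
            seed=child_seed(self.seed, stage),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mu_a_range", "mu_s_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _file_sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate -> standardise -> split -> corrupt -> extract -> train -> evaluate.

    Returns the artifact directory; a ``manifest.json`` records the effective
    config, per-stage record counts and checksums of every written file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "simulate"
    try:
        base = generate_grid_dataset(
            config.n_mu_a,
            config.n_mu_s,
            ranges=(config.mu_a_range, config.mu_s_range),
            probe=ProbeGeometry(config.probe_id),
            grid=default_grid(config.n_columns),
        )
        counts["simulate"] = len(base)
        extract_feature_table(base).to_csv(out / "base_features.csv", index=False)

        stage = "corrupt"
        train = build_augmented_training_set(base, config.error_config("corrupt"))
        counts["corrupt"] = len(train)

        stage = "extract"
        table = extract_feature_table(train)
        table.to_csv(out / "training_features.csv", index=False)
        counts["extract"] = len(table)

        stage = "train"
        model = WIRRegressor(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=child_seed(config.seed, "train"),
        )
        model.fit(table[list(FEATURE_NAMES)], table[["mu_a", "mu_s_prime"]])
        save_model(model, out / "model")

        if config.run_evaluation:
            stage = "evaluate"
            report = kfold_cv(
                train,
                k=config.cv_folds,
                model_spec=model.__class__(
                    n_estimators=config.n_estimators,
                    max_depth=config.max_depth,
                    min_samples_leaf=config.min_samples_leaf,
                    random_state=child_seed(config.seed, "train"),
                ),
                seed=child_seed(config.seed, "evaluate"),
            )
            report.to_csv(out / "cv_report.csv")
            counts["evaluate"] = len(report.rmse)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.digest(),
        "config": asdict(config),
        "record_counts": counts,
        "checksums": {str(p.relative_to(out)): _file_sha(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(model: WIRRegressor, path: str | Path) -> None:
    """Persist a fitted model with a feature-order manifest."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path / "model.joblib")
    (path / "manifest.json").write_text(
        json.dumps({"format_version": 1, "feature_names": list(FEATURE_NAMES)})
    )


def load_model(path: str | Path) -> WIRRegressor:
    """Load a persisted model, refusing a mismatched feature layout."""
    import joblib

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("feature_names") != list(FEATURE_NAMES):
        raise ValueError("persisted model has a different feature layout")
    return joblib.load(path / "model.joblib")


# ---------------------------------------------------------------------------
# dataset directory I/O (CLI interchange format)
# ---------------------------------------------------------------------------


def write_dataset(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """One CSV per spectrum set plus a manifest CSV of labels/groups/tags."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        spectra, props, group, tag = dataset.record(i)
        name = f"spec_{i:05d}.csv"
        write_spectra_csv(out / name, spectra)
        rows.append(
            {
                "file": name,
                "mu_a": props.mu_a,
                "mu_s_prime": props.mu_s_prime,
                "group_id": group,
                "error_tag": tag,
                "probe_id": dataset.probe_id,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def read_dataset(in_dir: str | Path) -> LabeledDataset:
    from .spectra import read_spectra_csv

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    reds, greens, blues = [], [], []
    grid = None
    for name in manifest["file"]:
        chans = read_spectra_csv(in_dir / name)
        grid = chans["R"].grid
        reds.append(chans["R"].intensity)
        greens.append(chans["G"].intensity)
        blues.append(chans["B"].intensity)
    red, green, blue = np.array(reds), np.array(greens), np.array(blues)
    return LabeledDataset(
        grid=grid,
        red=red,
        green=green,
        blue=blue,
        gray=red + green + blue,
        mu_a=manifest["mu_a"].to_numpy(),
        mu_s_prime=manifest["mu_s_prime"].to_numpy(),
        group_id=manifest["group_id"].to_numpy(dtype=object),
        error_tag=manifest["error_tag"].to_numpy(dtype=object),
        probe_id=int(manifest["probe_id"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(seed: int = 0, out_dir: str | Path = "fixtures") -> Path:
    """Small deterministic test assets: mini-grid, rendered images, standard.

    Writes a 5x5-label mini dataset, three rendered 8-bit images with sidecar
    metadata, the default lamp/standard curve as CSV, and the worked RGB
    channel-fraction example record.  Byte-identical across runs for a seed.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = default_grid()
    mini = generate_grid_dataset(5, 5, grid=grid)
    write_dataset(mini, out / "mini_grid")

    std = default_standard(grid)
    write_spectra_csv(out / "standard.csv", std.spectrum)

    rng = np.random.default_rng(child_seed(seed, "fixtures"))
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for i, rec in enumerate(rng.choice(len(mini), size=3, replace=False)):
        spectra, props, group, _ = mini.record(int(rec))
        img = render_image(spectra, m_rows=8, exposure_time_s=0.5, iso_speed=200.0)
        iio.imwrite(img_dir / f"img_{i}.png", img.pixels.astype(np.uint8))
        (img_dir / f"img_{i}.json").write_text(
            json.dumps(
                {
                    "exposure_time_s": img.exposure_time_s,
                    "iso_speed": img.iso_speed,
                    "probe_id": img.probe_id,
                    "mu_a": props.mu_a,
                    "mu_s_prime": props.mu_s_prime,
                    "group_id": group,
                },
                sort_keys=True,
            )
        )

    triple = (0, 255, 146)
    fr = to_fractions(triple)
    (out / "rgb_example.json").write_text(
        json.dumps(
            {
                "wavelength_nm": 500.0,
                "rgb_triple": list(triple),
                "fractions": [round(fr.f_red, 2), round(fr.f_green, 2), round(fr.f_blue, 2)],
                "map_triple_at_500nm": list(wavelength_to_rgb(500.0)),
            },
            sort_keys=True,
        )
    )
    return out
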