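"""Manifests, pipeline configuration and on-disk artifacts.

A dataset is described by a manifest CSV (sample_id, path, label, subset);
features are stored as a binary columnar matrix (``features.npy``) with a
JSON sidecar listing per-column provenance records {space, pair, bin} — the
column order is normative.  Every artifact embeds the hash of the pipeline
configuration that produced it, and downstream stages refuse artifacts whose
hash disagrees with the active configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .color_spaces import COLOR_SPACES, ColorImage, ColorSpaceSet
from .lbp import BinProvenance, FeatureMatrix, LBPParams
from .selection import STRATEGIES

SUBSET_NAMES = ("train", "validation", "test")


class ManifestError(ValueError):
    """Raised when a dataset manifest fails validation."""


class ArtifactError(ValueError):
    """Raised when an upstream artifact is missing or inconsistent."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on; hashed into every artifact."""

    spaces: tuple[str, ...] = COLOR_SPACES
    P: int = 8
    R: int = 1
    histogram_score: str = "spasl"
    bin_score: str = "sparsity"
    strategy: str = "MCSHBS"
    lam: float = 0.1
    stride: int = 1
    validation_equals_test: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        ColorSpaceSet(tuple(self.spaces))  # validates identifiers
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.histogram_score != "spasl":
            raise ValueError(f"unknown histogram score {self.histogram_score!r}")
        if self.bin_score != "sparsity":
            raise ValueError(f"unknown bin score {self.bin_score!r}")
        LBPParams(self.P, self.R)  # validates the neighborhood

    @property
    def lbp_params(self) -> LBPParams:
        return LBPParams(self.P, self.R)

    @property
    def space_set(self) -> ColorSpaceSet:
        return ColorSpaceSet(tuple(self.spaces))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spaces"] = list(self.spaces)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "spaces" in d:
            d["spaces"] = tuple(d["spaces"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a dataset manifest CSV.

    Subset strings are normalized to lower case; duplicate sample ids,
    unknown subsets and missing image files raise a ManifestError naming
    the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "path", "label", "subset"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    df["subset"] = df["subset"].str.strip().str.lower()
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if not dupes.empty:
        raise ManifestError(f"duplicate sample_id: {dupes.iloc[0]!r}")
    bad = df.loc[~df["subset"].isin(SUBSET_NAMES)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ManifestError(
            f"unknown subset {row['subset']!r} for sample {row['sample_id']!r}"
        )
    base = path.parent
    for _, row in df.iterrows():
        if not (base / row["path"]).exists():
            raise ManifestError(
                f"image missing for sample {row['sample_id']!r}: {row['path']}"
            )
    if "train" not in set(df["subset"]):
        raise ManifestError("manifest has no training rows")
    if "test" not in set(df["subset"]):
        raise ManifestError("manifest has no test rows")
    return df


def load_images(manifest: pd.DataFrame, base_dir: str | Path) -> list[ColorImage]:
    """Load every manifest image as an RGB ColorImage, in manifest order."""
    from PIL import Image

    base = Path(base_dir)
    images = []
    for _, row in manifest.iterrows():
        with Image.open(base / row["path"]) as im:
            images.append(ColorImage(np.asarray(im.convert("RGB")), "RGB"))
    return images


def save_features(
    out_dir: str | Path,
    features: FeatureMatrix,
    subsets: np.ndarray,
    config: PipelineConfig,
) -> Path:
    """Persist a FeatureMatrix: features.npy + features.json sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / "features.npy", features.values)
    sidecar = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "sample_ids": features.sample_ids,
        "labels": np.asarray(features.labels).tolist(),
        "subsets": np.asarray(subsets).tolist(),
        "provenance": [
            {"space": p.space, "pair": list(p.pair), "bin": p.bin}
            for p in features.provenance
        ],
    }
    with open(out_dir / "features.json", "w") as fh:
        json.dump(sidecar, fh)
    return out_dir / "features.npy"


def load_features(
    store_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[FeatureMatrix, np.ndarray]:
    """Load a persisted feature store; returns (FeatureMatrix, subsets)."""
    store_dir = Path(store_dir)
    npy = store_dir / "features.npy"
    meta = store_dir / "features.json"
    for p in (npy, meta):
        if not p.exists():
            raise ArtifactError(f"missing upstream artifact: {p}")
    with open(meta) as fh:
        sidecar = json.load(fh)
    if config is not None and sidecar.get("config_hash") != config.config_hash():
        raise ArtifactError(
            f"feature store {store_dir} was built with config hash "
            f"{sidecar.get('config_hash')!r}, expected {config.config_hash()!r}"
        )
    provenance = [
        BinProvenance(p["space"], tuple(p["pair"]), p["bin"])
        for p in sidecar["provenance"]
    ]
    fm = FeatureMatrix(
        np.load(npy),
        np.asarray(sidecar["labels"]),
        provenance,
        list(sidecar["sample_ids"]),
    )
    return fm, np.asarray(sidecar["subsets"])


def write_json_artifact(path: str | Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"config_hash": config.config_hash(), **payload}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json_artifact(path: str | Path, config: PipelineConfig | None = None) -> dict:
    path = Path(path)
    if not path.exists():
        raise ArtifactError(f"missing upstream artifact: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    if config is not None and payload.get("config_hash") != config.config_hash():
        raise ArtifactError(
            f"artifact {path} carries config hash {payload.get('config_hash')!r}, "
            f"expected {config.config_hash()!r}"
        )
    return payload
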