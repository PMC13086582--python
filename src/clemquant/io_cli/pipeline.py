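"""End-to-end quantification: contour model + channel images + transform
-> per-endosome density results and a summary CSV.

The configuration is a flat key/value YAML file::

    endosome_id: endo-01
    model: model.json
    model_dialect: json
    mode: area3d              # or length2d
    transform: transform.json # or landmarks: landmarks.csv
    channel_lipid: lipid.tif
    channel_Tf: tf.tif
    channel_LDL: ldl.tif
    pixel_size_nm: 65.0
    mask_sigma_px: 30.0
    mask_threshold_fraction: 0.1
    kde_bandwidth: 1.0        # or silverman
    fallback: equal_split
    background: percentile
    background_percentile: 5.0
    cap_bm: true
    out_dir: results/
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clemquant.density_metrics import DensityResult, compute_densities
from clemquant.errors import ClemQuantError, ValidationError
from clemquant.intensity_assignment import AssignConfig, ChannelImage, assign_intensities
from clemquant.io_cli.registration import RegistrationTransform, fit_landmark_affine
from clemquant.mask_builder import MaskConfig, build_class_masks, partition_masks
from clemquant.model_geometry import (
    ContourModel,
    compute_domain_measure,
    project_outlines,
    read_contour_model,
)

logger = logging.getLogger(__name__)


@dataclass
class QuantifyConfig:
    model: str
    channels: dict[str, str]
    endosome_id: str = ""
    model_dialect: str = "json"
    mode: str = "area3d"
    transform: str | None = None
    landmarks: str | None = None
    pixel_size_nm: float = 65.0
    mask_sigma_px: float = 30.0
    mask_threshold_fraction: float = 0.1
    kde_bandwidth: float | str = 1.0
    fallback: str = "equal_split"
    background: str = "percentile"
    background_percentile: float = 5.0
    cap_bm: bool = True
    out_dir: str = "."
    extras: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuantifyConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValidationError(f"{path}: config must be a flat mapping")
        channels = {
            key[len("channel_"):]: str(value)
            for key, value in payload.items()
            if key.startswith("channel_")
        }
        if not channels:
            raise ValidationError(f"{path}: no channel_<name> entries in config")
        known = {f.name for f in cls.__dataclass_fields__.values()} - {"channels", "extras"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        extras = {
            k: v for k, v in payload.items()
            if k not in known and not k.startswith("channel_")
        }
        base = Path(path).parent
        cfg = cls(channels=channels, extras=extras, **kwargs)
        cfg.model = str(base / cfg.model)
        cfg.channels = {k: str(base / v) for k, v in cfg.channels.items()}
        if cfg.transform:
            cfg.transform = str(base / cfg.transform)
        if cfg.landmarks:
            cfg.landmarks = str(base / cfg.landmarks)
        return cfg

    def mask_config(self) -> MaskConfig:
        return MaskConfig(
            sigma_px=self.mask_sigma_px, threshold_fraction=self.mask_threshold_fraction
        )

    def assign_config(self) -> AssignConfig:
        return AssignConfig(
            kde_bandwidth=self.kde_bandwidth,
            fallback=self.fallback,
            background=self.background,
            background_percentile=self.background_percentile,
        )


def quantify_endosome(
    model: ContourModel,
    images: dict[str, ChannelImage],
    transform: RegistrationTransform | np.ndarray,
    mask_cfg: MaskConfig | None = None,
    assign_cfg: AssignConfig | None = None,
    mode: str = "area3d",
    cap_bm: bool = True,
) -> DensityResult:
    """Run the full in-memory pipeline for a single endosome."""
    model.validate(require_all_classes=True)
    shape = next(iter(images.values())).pixels.shape
    measures = compute_domain_measure(model, mode=mode, cap_bm=cap_bm)
    outlines = project_outlines(model, transform, shape)
    masks = build_class_masks(outlines, mask_cfg)
    partition = partition_masks(masks)
    table = assign_intensities(images, partition, assign_cfg)
    table.endosome_id = model.endosome_id
    return compute_densities(table, measures)


def _load_transform(cfg: QuantifyConfig) -> RegistrationTransform:
    if cfg.transform:
        payload_path = Path(cfg.transform)
        if payload_path.suffix == ".json":
            import json

            payload = json.loads(payload_path.read_text())
            if "matrix" in payload:
                return RegistrationTransform(
                    matrix=np.asarray(payload["matrix"], dtype=float),
                    ttype=payload.get("type", "affine"),
                )
        raise ValidationError(f"cannot read transform from {cfg.transform}")
    if cfg.landmarks:
        table = pd.read_csv(cfg.landmarks)
        required = {"src_x", "src_y", "dst_x", "dst_y"}
        if not required <= set(table.columns):
            raise ValidationError(
                f"landmark CSV needs columns {sorted(required)}, has {list(table.columns)}"
            )
        return fit_landmark_affine(
            table[["src_x", "src_y"]].to_numpy(), table[["dst_x", "dst_y"]].to_numpy()
        )
    raise ValidationError("config must provide either a transform or a landmarks file")


def run_quantify(cfg: QuantifyConfig) -> list[DensityResult]:
    """Execute the pipeline from files and write per-endosome CSVs plus a
    combined summary CSV into ``cfg.out_dir``."""
    import tifffile

    stage = "read model"
    try:
        model = read_contour_model(cfg.model, dialect=cfg.model_dialect)
        if cfg.endosome_id:
            model.endosome_id = cfg.endosome_id

        stage = "read channels"
        images = {}
        for channel, path in cfg.channels.items():
            if not Path(path).exists():
                raise ValidationError(f"channel {channel!r}: no such image {path}")
            images[channel] = ChannelImage(
                pixels=np.asarray(tifffile.imread(path), dtype=float),
                channel=channel,
                pixel_size_nm=cfg.pixel_size_nm,
            )

        stage = "registration"
        transform = _load_transform(cfg)

        stage = "quantify"
        result = quantify_endosome(
            model,
            images,
            transform,
            mask_cfg=cfg.mask_config(),
            assign_cfg=cfg.assign_config(),
            mode=cfg.mode,
            cap_bm=cfg.cap_bm,
        )
    except ClemQuantError as exc:
        raise ClemQuantError(
            f"stage '{stage}' failed for endosome "
            f"{cfg.endosome_id or cfg.model}: {exc}"
        ) from exc

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = result.to_frame()
    frame.to_csv(out_dir / f"{result.endosome_id}_densities.csv", index=False)
    frame.to_csv(out_dir / "summary.csv", index=False)
    logger.info(
        "quantified endosome %s: classes=%s channels=%s",
        result.endosome_id,
        [c.value for c in result.classes],
        result.channels,
    )
    return [result]
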