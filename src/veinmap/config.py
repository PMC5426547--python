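"""Pipeline configuration: one nested, strictly-validated YAML document.

Unknown keys are rejected so typos cannot silently fall back to defaults;
the document round-trips through serialization unchanged.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

CONFIG_VERSION = "1"


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OtsuConfig(_Section):
    bins: int | None = None
    invert: bool = False


class MaskConfig(_Section):
    widths: tuple[int, int] = (10, 15)


class ClaheConfig(_Section):
    tiles: tuple[int, int] = (8, 8)
    clip: float = 0.01


class AdjustConfig(_Section):
    saturation: float = 0.01


class MaxCurvConfig(_Section):
    sigma: float = 3.0
    bin_rule: str = "otsu"  # "otsu" or "median", over positive connected scores
    threshold: float | None = None  # explicit override of the derived threshold
    min_score: float = 0.02  # floor on the derived threshold (normalized scale)


class KMeansConfig(_Section):
    k: int = 3
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 300
    n_init: int = 10


class ExtractConfig(_Section):
    method: str = "kmeans"  # "kmeans" or "max_curvature"


class RansacConfig(_Section):
    epsilon: float = 2.0
    iterations: int = 2000
    seed: int = 0


class FusionConfig(_Section):
    fill_radius: float = 4.0
    amplitude_floor: float = 0.0


class PipelineConfig(_Section):
    version: str = CONFIG_VERSION
    otsu: OtsuConfig = OtsuConfig()
    mask: MaskConfig = MaskConfig()
    clahe: ClaheConfig = ClaheConfig()
    adjust: AdjustConfig = AdjustConfig()
    extract: ExtractConfig = ExtractConfig()
    maxcurv: MaxCurvConfig = MaxCurvConfig()
    kmeans: KMeansConfig = KMeansConfig()
    ransac: RansacConfig = RansacConfig()
    fusion: FusionConfig = FusionConfig()

    def detect_kwargs(self) -> dict:
        """Keyword arguments for :func:`veinmap.extract.detect_veins`."""
        return dict(
            method=self.extract.method,
            seed=self.kmeans.seed,
            mask_widths=self.mask.widths,
            invert_threshold=self.otsu.invert,
            clahe_clip=self.clahe.clip,
            clahe_tiles=self.clahe.tiles,
            saturation=self.adjust.saturation,
            maxcurv_sigma=self.maxcurv.sigma,
            maxcurv_threshold=self.maxcurv.threshold,
            maxcurv_rule=self.maxcurv.bin_rule,
            maxcurv_min_score=self.maxcurv.min_score,
            kmeans_k=self.kmeans.k,
            kmeans_tol=self.kmeans.tol,
            kmeans_max_iter=self.kmeans.max_iter,
            kmeans_n_init=self.kmeans.n_init,
        )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
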