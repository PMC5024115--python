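"""Reflectance arithmetic: Rayleigh-corrected reflectance, sunglint
rescaling, the turbidity index, and true-color compositing."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .series import SceneObservation, SceneSeries


@dataclass(frozen=True)
class RadiometricInputs:
    """Inputs for Rayleigh-corrected reflectance.

    ``lt_star`` is at-sensor total radiance already adjusted for ozone
    and gaseous absorption (W m⁻² µm⁻¹ sr⁻¹); ``f0`` the extraterrestrial
    solar irradiance (W m⁻² µm⁻¹), with any Earth–sun distance correction
    folded in by the caller; ``theta0`` the solar zenith angle (degrees);
    ``rr`` the Rayleigh reflectance (dimensionless).
    """

    lt_star: np.ndarray | float
    f0: float
    theta0: float
    rr: np.ndarray | float

    def validate(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0.0 <= self.theta0 < 90.0:
            raise ValueError("theta0 must be in [0, 90) degrees (sun above horizon)")


@dataclass(frozen=True)
class GlintConfig:
    """Sunglint rescaling: where the 859-nm reflectance exceeds
    ``trigger``, bands 469 and 645 are reduced by their scaled 859-nm
    signal, R(λ) − C_λ·R(859). The 859-nm band itself is never modified."""

    trigger: float = 0.01
    c: Mapping[int, float] = field(default_factory=lambda: {469: 0.67, 645: 0.94})

    def __post_init__(self) -> None:
        if self.trigger <= 0:
            raise ValueError("trigger must be positive")
        for wl, coef in self.c.items():
            if not 0.0 < coef < 2.0:
                raise ValueError(f"scaling coefficient for band {wl} must be in (0, 2)")


def compute_rrc(inputs: RadiometricInputs) -> np.ndarray:
    """Rayleigh-corrected reflectance: π·Lt*/(F0·cos θ0) − Rr, element-wise."""
    inputs.validate()
    mu0 = np.cos(np.deg2rad(inputs.theta0))
    return np.asarray(np.pi * np.asarray(inputs.lt_star) / (inputs.f0 * mu0) - inputs.rr)


def deglint_bands(
    b469: np.ndarray, b645: np.ndarray, b859: np.ndarray, cfg: GlintConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level glint rescaling; returns corrected (469, 645) bands."""
    cfg = cfg or GlintConfig()
    hit = np.asarray(b859) > cfg.trigger
    out469 = np.where(hit, b469 - cfg.c[469] * b859, b469)
    out645 = np.where(hit, b645 - cfg.c[645] * b859, b645)
    return out469, out645


def correct_glint(scene, cfg: GlintConfig | None = None):
    """Apply the sunglint rescaling to a scene or series.

    Returns a new object of the same type with bands 469 and 645
    replaced where R(859) exceeds the trigger; all other bands (and the
    859-nm band in particular) are carried through untouched, which
    makes the operation exactly idempotent.
    """
    cfg = cfg or GlintConfig()
    if not isinstance(scene, (SceneObservation, SceneSeries)):
        raise TypeError("correct_glint expects a SceneObservation or SceneSeries")
    if 859 not in scene.bands:
        raise ValueError("scene is missing the 859-nm band required for glint correction")
    for wl in (469, 645):
        if wl not in scene.bands:
            raise ValueError(f"scene is missing band {wl}")
    out469, out645 = deglint_bands(
        scene.bands[469], scene.bands[645], scene.bands[859], cfg
    )
    new_bands = dict(scene.bands)
    new_bands[469] = out469.astype(scene.bands[469].dtype, copy=False)
    new_bands[645] = out645.astype(scene.bands[645].dtype, copy=False)
    return replace(scene, bands=new_bands)


def compute_ti(scene) -> np.ndarray:
    """Turbidity index: R(469) − R(645), with NaN under the cloud mask.

    Accepts a SceneObservation or SceneSeries (glint correction, if
    wanted, is applied upstream via :func:`correct_glint`).
    """
    for wl in (469, 645):
        if wl not in scene.bands:
            raise ValueError(f"scene is missing band {wl}")
    ti = np.asarray(scene.bands[469], dtype=float) - np.asarray(scene.bands[645], dtype=float)
    if scene.cloud is not None:
        ti = np.where(scene.cloud, np.nan, ti)
    return ti


# reflectance value mapped to channel 255, per sensor
RGB_SCALE = {"modis": 0.15, "oli": 0.5}


def quantize_channel(reflectance: np.ndarray, scale: float) -> np.ndarray:
    """Scale reflectance to [0, 1] by ``scale``, clip, and quantize to
    uint8 with round-half-away-from-zero (0.5 → up, since values are
    non-negative after clipping)."""
    v = np.clip(np.asarray(reflectance, dtype=float) / scale, 0.0, 1.0)
    return np.floor(v * 255.0 + 0.5).astype(np.uint8)


def compose_rgb(red: np.ndarray, green: np.ndarray, blue: np.ndarray, sensor: str = "modis") -> np.ndarray:
    """8-bit true-color composite from red/green/blue reflectance grids.

    MODIS composites scale 0–0.15 per channel; OLI composites 0–0.5.
    """
    try:
        scale = RGB_SCALE[sensor]
    except KeyError:
        raise ValueError(f"unknown sensor {sensor!r}; expected 'modis' or 'oli'") from None
    return np.stack([quantize_channel(c, scale) for c in (red, green, blue)], axis=-1)


def scene_rgb(scene, sensor: str = "modis") -> np.ndarray:
    """Convenience composite from a scene's (645, 555, 469) bands."""
    scene_bands = (645, 555, 469) if sensor == "modis" else (655, 561, 483)
    for wl in scene_bands:
        if wl not in scene.bands:
            raise ValueError(f"scene is missing band {wl}")
    r, g, b = (scene.bands[wl] for wl in scene_bands)
    return compose_rgb(r, g, b, sensor)


def ratio_sharpen(
    red_fine: np.ndarray, green_coarse: np.ndarray, blue_coarse: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sharpen half-resolution green/blue toward the full-resolution red.

    The coarse inputs (shape exactly half of ``red_fine`` along both
    axes) are replicated to full resolution and multiplied by the ratio
    of the fine red band to its 2×2 block mean, i.e. the red/green and
    red/blue ratio structure transfers the red band's spatial detail.
    """
    red_fine = np.asarray(red_fine, dtype=float)
    ny, nx = red_fine.shape
    if ny % 2 or nx % 2:
        raise ValueError("red band dimensions must be even for 2x ratio sharpening")
    for name, arr in (("green", green_coarse), ("blue", blue_coarse)):
        if arr.shape != (ny // 2, nx // 2):
            raise ValueError(f"{name} band must be exactly half the red band resolution")
    red_block = red_fine.reshape(ny // 2, 2, nx // 2, 2).mean(axis=(1, 3))
    up = lambda a: np.kron(np.asarray(a, dtype=float), np.ones((2, 2)))
    up_block = up(red_block)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(up_block > 0, red_fine / up_block, 1.0)
    return up(green_coarse) * ratio, up(blue_coarse) * ratio
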