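"""Analysis configuration.

Every tunable of the pipeline lives in one flat, YAML-serializable
configuration object so that a batch run is a pure function of
(input images, config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PhansalkarParams:
    """Parameters of Phansalkar local adaptive thresholding.

    The threshold at each pixel is ``t = m * (1 + p*exp(-q*m) + k*(s/r - 1))``
    with ``m``, ``s`` the local mean and standard deviation in a disk of
    ``radius_px``.  Defaults are the widely used defaults of the original
    algorithm for images normalized to [0, 1]; the radius should scale with
    magnification (15 px suits ~0.5 um/px).
    """

    radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


@dataclass
class ReferenceStats:
    """Reference distribution of endomysial septum widths.

    ``enhanced`` separation is defined as a septum wider than
    ``mu_ref_um + 2 * sd_ref_um``.  The reference is meant to come from the
    healthiest available cohort (e.g. patients without AF or heart failure);
    it can be estimated from a designated reference image set with
    :func:`cardiohist.septa.estimate_reference` or supplied here directly for
    cross-study comparability.
    """

    mu_ref_um: float = 2.9
    sd_ref_um: float = 0.5
    source_note: str = "config default (healthy atrial myocardium)"

    def __post_init__(self) -> None:
        if self.mu_ref_um <= 0:
            raise ValueError("mu_ref_um must be > 0")
        if self.sd_ref_um < 0:
            raise ValueError("sd_ref_um must be >= 0")
        if self.threshold_um <= 0:
            raise ValueError("enhancement threshold must be > 0")

    @property
    def threshold_um(self) -> float:
        return self.mu_ref_um + 2.0 * self.sd_ref_um


@dataclass
class HsbRange:
    """Hue-Saturation-Brightness gate for a fluorescence color channel.

    Hue is in degrees on the color circle ([0, 360), circular interval);
    saturation and brightness are fractions of full scale.
    """

    hue_min_deg: float = 80.0
    hue_max_deg: float = 160.0
    sat_min: float = 0.15
    bright_min: float = 0.15


@dataclass
class AnalysisConfig:
    """All tunables of the analysis pipeline, with defaults.

    Length scales are in pixels where they track image resolution concerns
    (blur, annulus) and in micrometers where they are anatomical gates.
    """

    # WGA thresholding / myocyte detection
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    blur_sigma_px: float = 2.0
    contrast_scale: float = 0.5          # prominence = scale * (mean fg - mean bg)
    reject_inner_px: float = 2.0         # annulus for "red surround" rejection
    reject_outer_px: float = 6.0
    reject_fraction: float = 0.6
    min_cell_area_um2: float = 20.0      # size gate for myocyte size statistics

    # Septum profiles / CDI.  The default measures the profile width at half
    # maximum on the raw intensity line profile (unbiased against the
    # rendering level); set profile_on_intensity=False to measure the
    # stained run on the thresholded mask instead.
    profile_step_px: float = 0.25
    profile_on_intensity: bool = True
    reference: ReferenceStats = field(default_factory=ReferenceStats)

    # Clustering statistic
    n_permutations: int = 1000

    # Capillaries (endothelial channel) and fibroblasts (vimentin channel)
    capillary_hsb: HsbRange = field(default_factory=HsbRange)
    fibroblast_hsb: HsbRange = field(
        default_factory=lambda: HsbRange(hue_min_deg=200.0, hue_max_deg=280.0)
    )
    hsb_blur_sigma_px: float = 1.0
    capillary_min_area_um2: float = 1.5
    capillary_circularity_gate: float = 0.35
    fibroblast_min_area_um2: float = 1.5

    seed: int = 0

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kwargs = dict(raw)
        if "phansalkar" in kwargs:
            kwargs["phansalkar"] = PhansalkarParams(**kwargs["phansalkar"])
        if "reference" in kwargs:
            kwargs["reference"] = ReferenceStats(**kwargs["reference"])
        for key in ("capillary_hsb", "fibroblast_hsb"):
            if key in kwargs:
                kwargs[key] = HsbRange(**kwargs[key])
        return cls(**kwargs)
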