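"""Generator configuration.

The defaults encode the study conditions of the axolotl tail-bud dataset the
generator emulates: per-stage labelled mesodermal/neural cell counts from
transverse-section counting, per-region aspect-ratio moments and
orientation-class probabilities, per-region cohesion (median in-section
pairwise distance) and nearest-neighbour scales, filopodia count/length
distributions, per-stage AP-oriented spindle fractions, and the strand
geometry (arc length, cross-section radius, somite spacing) per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

ORIENTATION_CLASSES = ("AP", "ML", "DV", "unclassified")


@dataclass(frozen=True)
class RegionShape:
    """Per-region cell shape/orientation/filopodia parameters."""

    aspect_mean: float
    aspect_sd: float
    #: probabilities over (AP, ML, DV, unclassified); must sum to 1
    orientation_probs: tuple[float, float, float, float]
    cohesion_um: float  # target in-section median pairwise distance
    nn_um: float  # target median nearest-neighbour distance (sphere groups)
    filopodia_mean_count: float  # Poisson mean filopodia per cell
    filopodia_mean_um: float  # mean filopodium length (gamma, shape 2)
    mean_volume_um3: float  # mean single-cell volume
    volume_cv: float = 0.25  # lognormal CV of cell volume

    def validate(self, name: str) -> None:
        if self.aspect_mean < 1 or self.aspect_sd < 0:
            raise ConfigurationError(f"{name}: invalid aspect-ratio moments")
        p = np.asarray(self.orientation_probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{name}: orientation-class probabilities must be >= 0 and sum to 1"
            )
        if self.cohesion_um <= 0 or self.nn_um <= 0:
            raise ConfigurationError(f"{name}: cohesion/NN scales must be positive")
        if self.filopodia_mean_count < 0 or self.filopodia_mean_um <= 0:
            raise ConfigurationError(f"{name}: invalid filopodia parameters")
        if self.mean_volume_um3 <= 0:
            raise ConfigurationError(f"{name}: mean cell volume must be positive")


@dataclass(frozen=True)
class StageGeometry:
    """Strand geometry at one stage: arc length budget along the stream."""

    arc_length_um: float  # total labelled strand arc length
    pz_length_um: float  # posterior-zone span from the tail tip
    n_somites: int  # somite pairs already segmented
    tissue_volume_um3: float  # configured labelled-tissue envelope volume
    anterior_offset_um: float = 300.0  # AP position of strand anterior end


# --- study-condition defaults -------------------------------------------------

# volume halving: PZ cells at the early tail-bud stage are twice the volume of
# all later PSM/somite cells.
_V_PZ22 = 8000.0
_V_LATE = _V_PZ22 / 2

_DEFAULT_SHAPES: dict[str, RegionShape] = {
    "PZ": RegionShape(2.33, 0.70, (0.28, 0.48, 0.24, 0.0), 14.9, 30.0, 0.9, 6.0, _V_PZ22),
    "posterior_PSM": RegionShape(2.78, 0.67, (0.36, 0.36, 0.28, 0.0), 14.3, 30.0, 2.0, 6.0, _V_LATE),
    "medial_PSM": RegionShape(2.26, 0.68, (0.44, 0.28, 0.28, 0.0), 57.9, 30.0, 2.0, 6.0, _V_LATE),
    "anterior_PSM": RegionShape(2.37, 0.71, (0.30, 0.32, 0.30, 0.08), 10.6, 30.0, 3.5, 4.0, _V_LATE),
    "somite": RegionShape(3.03, 1.31, (0.33, 0.21, 0.46, 0.0), 10.2, 25.0, 0.9, 4.0, _V_LATE),
    # neural-tube cells (Sox2+) are counted but not morphometrically profiled
    "NT": RegionShape(2.0, 0.5, (0.25, 0.25, 0.25, 0.25), 15.0, 15.0, 0.2, 4.0, _V_LATE),
}

# per-stage labelled cell counts on transverse sections (mesodermal, neural)
_DEFAULT_COUNTS: dict[int, tuple[int, int]] = {
    19: (527, 0),
    22: (1095, 27),
    28: (1232, 78),
    30: (1989, 1),
}

# fraction of mesodermal cells per active region at each stage
_DEFAULT_REGION_FRACTIONS: dict[int, dict[str, float]] = {
    19: {"PZ": 1.0},
    22: {"PZ": 1.0},
    28: {"PZ": 0.20, "posterior_PSM": 0.27, "medial_PSM": 0.27, "anterior_PSM": 0.26},
    30: {
        "PZ": 0.08,
        "posterior_PSM": 0.15,
        "medial_PSM": 0.15,
        "anterior_PSM": 0.20,
        "somite": 0.42,
    },
}

# AP-oriented mitotic spindle fraction per stage (percent / 100)
_DEFAULT_SPINDLE_AP = {19: 0.059, 22: 0.014, 28: 0.121, 30: 0.044}

# strand geometry per stage.  Arc lengths follow the measured 500 -> 1200 µm
# elongation; the cross-section radius follows from the tissue-volume
# schedule (constant between the two early tail-bud stages, doubling across
# the last interval), which with these numbers gives a stage-30 strand height
# of ~140 µm.
_V0 = 9.2e6
_DEFAULT_GEOMETRY: dict[int, StageGeometry] = {
    19: StageGeometry(350.0, 350.0, 0, 0.75 * _V0),
    22: StageGeometry(500.0, 500.0, 0, _V0),
    28: StageGeometry(950.0, 120.0, 0, _V0),
    30: StageGeometry(1200.0, 120.0, 4, 2 * _V0),
}

# ventral body contour length per stage (µm); 9.3 mm at the pre-hatching
# larval stage anchors the scale.
_DEFAULT_BODY_LENGTH = {
    14: 2100.0,
    19: 2300.0,
    22: 2500.0,
    28: 3000.0,
    30: 3400.0,
    35: 5500.0,
    40: 9300.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the synthetic tail-bud generator needs.

    ``cohesion_group_size`` controls the size of the small clump of
    focally-labelled cells placed per region for the cohesion analysis
    (0 disables the clumps).
    """

    shapes: dict[str, RegionShape] = field(default_factory=lambda: dict(_DEFAULT_SHAPES))
    counts: dict[int, tuple[int, int]] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    region_fractions: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_REGION_FRACTIONS.items()}
    )
    spindle_ap_fraction: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPINDLE_AP)
    )
    geometry: dict[int, StageGeometry] = field(default_factory=lambda: dict(_DEFAULT_GEOMETRY))
    body_length_um: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_BODY_LENGTH))
    somite_spacing_um: float = 70.0
    midline_gap_um: float = 5.0  # gap between midline and the stream's medial edge
    graft_cell_count: int = 60  # labelled cells per focal-graft snapshot
    n_divisions: int = 150  # mitotic events per snapshot
    cone_half_angle_deg: float = 30.0  # AP cone used when sampling spindles
    aspect_lower_bound: float = 1.0  # lower truncation of the aspect-ratio draw
    min_ar: float = 1.3  # classifier threshold mirrored by the generator
    cohesion_group_size: int = 0  # total focally-labelled cells per region group
    cohesion_subclumps: int = 4  # substream sub-clumps (one section apart) per group
    graft_origin: str = "left_half"
    epidermis_intact: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name, shape in self.shapes.items():
            shape.validate(name)
        for stage, (n_meso, n_neural) in self.counts.items():
            if n_meso < 0 or n_neural < 0:
                raise ConfigurationError(f"stage {stage}: counts must be >= 0")
            if n_meso > 0 and stage not in self.region_fractions:
                raise ConfigurationError(f"stage {stage}: no region fractions configured")
        for stage, fr in self.region_fractions.items():
            tot = sum(fr.values())
            if fr and abs(tot - 1.0) > 1e-9:
                raise ConfigurationError(f"stage {stage}: region fractions sum to {tot}")
            for region, f in fr.items():
                if f < 0:
                    raise ConfigurationError(f"stage {stage}: negative fraction for {region}")
                key = "somite" if region == "somite" else region
                if key not in self.shapes:
                    raise ConfigurationError(f"stage {stage}: no shape params for {region}")
                probs = self.shapes[key].orientation_probs
                if f > 0 and sum(probs[:3]) == 0 and probs[3] < 1:
                    raise ConfigurationError(
                        f"{region}: all orientation vector classes have zero probability"
                    )
        for stage, p in self.spindle_ap_fraction.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"stage {stage}: spindle AP fraction outside [0,1]")
        if self.graft_origin not in ("median", "paramedian", "lateral", "left_half", "entire"):
            raise ConfigurationError(f"unknown graft origin {self.graft_origin!r}")
        if self.aspect_lower_bound < 1:
            raise ConfigurationError("aspect-ratio lower bound must be >= 1")
        if self.cohesion_group_size < 0:
            raise ConfigurationError("cohesion group size must be >= 0")
        if self.cohesion_subclumps < 1:
            raise ConfigurationError("cohesion_subclumps must be >= 1")
        if self.cohesion_group_size % max(self.cohesion_subclumps, 1):
            raise ConfigurationError(
                "cohesion_group_size must be divisible by cohesion_subclumps"
            )

    def stages(self) -> list[int]:
        return sorted(self.counts)

    def shape_for(self, region: str) -> RegionShape:
        key = "somite" if region.startswith("somite") else region
        try:
            return self.shapes[key]
        except KeyError:
            raise ConfigurationError(f"no shape parameters for region {region!r}") from None

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# --- serialization ------------------------------------------------------------

def _shape_to_dict(s: RegionShape) -> dict:
    return {
        "aspect_mean": s.aspect_mean,
        "aspect_sd": s.aspect_sd,
        "orientation_probs": list(s.orientation_probs),
        "cohesion_um": s.cohesion_um,
        "nn_um": s.nn_um,
        "filopodia_mean_count": s.filopodia_mean_count,
        "filopodia_mean_um": s.filopodia_mean_um,
        "mean_volume_um3": s.mean_volume_um3,
        "volume_cv": s.volume_cv,
    }


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return {
        "shapes": {k: _shape_to_dict(v) for k, v in cfg.shapes.items()},
        "counts": {str(k): list(v) for k, v in cfg.counts.items()},
        "region_fractions": {str(k): v for k, v in cfg.region_fractions.items()},
        "spindle_ap_fraction": {str(k): v for k, v in cfg.spindle_ap_fraction.items()},
        "geometry": {
            str(k): {
                "arc_length_um": g.arc_length_um,
                "pz_length_um": g.pz_length_um,
                "n_somites": g.n_somites,
                "tissue_volume_um3": g.tissue_volume_um3,
                "anterior_offset_um": g.anterior_offset_um,
            }
            for k, g in cfg.geometry.items()
        },
        "body_length_um": {str(k): v for k, v in cfg.body_length_um.items()},
        "somite_spacing_um": cfg.somite_spacing_um,
        "midline_gap_um": cfg.midline_gap_um,
        "graft_cell_count": cfg.graft_cell_count,
        "n_divisions": cfg.n_divisions,
        "cone_half_angle_deg": cfg.cone_half_angle_deg,
        "aspect_lower_bound": cfg.aspect_lower_bound,
        "min_ar": cfg.min_ar,
        "cohesion_group_size": cfg.cohesion_group_size,
        "cohesion_subclumps": cfg.cohesion_subclumps,
        "graft_origin": cfg.graft_origin,
        "epidermis_intact": cfg.epidermis_intact,
        "seed": cfg.seed,
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    base = default_config()
    kw: dict = {}
    if "shapes" in d:
        kw["shapes"] = {k: RegionShape(**{**_shape_to_dict(base.shapes.get(k, base.shapes["PZ"])), **v,
                                          "orientation_probs": tuple(v.get("orientation_probs",
                                              base.shapes.get(k, base.shapes["PZ"]).orientation_probs))})
                        for k, v in d["shapes"].items()}
        # keep defaults for regions not overridden
        for k, v in base.shapes.items():
            kw["shapes"].setdefault(k, v)
    if "counts" in d:
        kw["counts"] = {int(k): tuple(v) for k, v in d["counts"].items()}
    if "region_fractions" in d:
        kw["region_fractions"] = {int(k): dict(v) for k, v in d["region_fractions"].items()}
    if "spindle_ap_fraction" in d:
        kw["spindle_ap_fraction"] = {int(k): float(v) for k, v in d["spindle_ap_fraction"].items()}
    if "geometry" in d:
        kw["geometry"] = {int(k): StageGeometry(**v) for k, v in d["geometry"].items()}
    if "body_length_um" in d:
        kw["body_length_um"] = {int(k): float(v) for k, v in d["body_length_um"].items()}
    for key in (
        "somite_spacing_um",
        "midline_gap_um",
        "graft_cell_count",
        "n_divisions",
        "cone_half_angle_deg",
        "aspect_lower_bound",
        "min_ar",
        "cohesion_group_size",
        "cohesion_subclumps",
        "graft_origin",
        "epidermis_intact",
        "seed",
    ):
        if key in d:
            kw[key] = d[key]
    cfg = replace(base, **kw)
    cfg.validate()
    return cfg


def load_config(path) -> GeneratorConfig:
    """Read a YAML or JSON generator config; omitted keys keep defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data or {})


def save_config(cfg: GeneratorConfig, path) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
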