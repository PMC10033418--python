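"""Pipeline configuration: one YAML document covering every stage.

Every field is optional with a documented default, so an empty config is
valid; unknown keys are rejected with the offending path named.  The config
round-trips: parse -> serialize -> parse is a fixed point.  All randomness
in the pipeline flows from the seeds recorded here.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import synthetic
from .compartments import ContactParams
from .nn import NetConfig, TrainConfig

__all__ = ["PipelineConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NucleusSection(_Strict):
    semi_axes_nm: tuple[float, float, float] = (1100.0, 1150.0, 1150.0)
    center_nm: tuple[float, float, float] = (1600.0, 1250.0, 1250.0)
    euler_zyx_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)


class SceneSection(_Strict):
    grid_shape: tuple[int, int, int] = (64, 500, 500)
    voxel_size_nm: tuple[float, float, float] = (50.0, 5.0, 5.0)
    nucleus: NucleusSection = NucleusSection()
    n_mitochondria: int = 25
    mito_radius_nm: float = 100.0
    mito_length_mean_um: float | None = None  # None: set by fragmentation_mode
    mito_length_sd_um: float | None = None
    fragmentation_mode: str = "elongated"
    placement_mode: str = "dispersed"
    perinuclear_shell_nm: float = 1000.0
    n_lipid_droplets: int = 5
    ld_radius_mean_nm: float = 300.0
    ld_radius_sd_nm: float = 50.0
    noise_sd: float = 0.05
    seed: int = 0

    def to_scene_spec(self) -> synthetic.SceneSpec:
        shape = None
        if self.mito_length_mean_um is not None:
            shape = synthetic.MitoShapeParams(
                radius_nm=self.mito_radius_nm,
                length_mean_um=self.mito_length_mean_um,
                length_sd_um=self.mito_length_sd_um or 0.0,
            )
        return synthetic.SceneSpec(
            grid_shape=tuple(self.grid_shape),
            voxel_size=tuple(self.voxel_size_nm),
            nucleus=synthetic.NucleusSpec(
                semi_axes=tuple(self.nucleus.semi_axes_nm),
                center=tuple(self.nucleus.center_nm),
                euler_zyx=tuple(self.nucleus.euler_zyx_rad),
            ),
            n_mitochondria=self.n_mitochondria,
            mito_shape=shape,
            fragmentation_mode=self.fragmentation_mode,
            placement_mode=self.placement_mode,
            perinuclear_shell_nm=self.perinuclear_shell_nm,
            n_lipid_droplets=self.n_lipid_droplets,
            ld_radius_mean_nm=self.ld_radius_mean_nm,
            ld_radius_sd_nm=self.ld_radius_sd_nm,
            intensity=synthetic.IntensityModel(noise_sd=self.noise_sd),
            seed=self.seed,
        )


class NetSection(_Strict):
    encoder_filters: tuple[int, ...] = (32, 64, 128, 256, 256)
    max_downsampling_factor: int = 8
    aspp_rates: tuple[int, ...] = (6, 12, 18, 24)
    n_classes: int = 3
    leaky_slope: float = 0.01
    input_size: int = 768
    seed: int = 0

    def to_net_config(self) -> NetConfig:
        return NetConfig(**self.model_dump())


class TrainSection(_Strict):
    epochs: int = 200
    batch_size: int = 8
    lr_initial: float = 1e-4
    lr_late: float = 1e-5
    lr_switch_epoch: int = 150
    augment: bool = True
    seed: int = 0

    def to_train_config(self) -> TrainConfig:
        return TrainConfig(**self.model_dump())


class InstanceSection(_Strict):
    median_size: int = 3
    threshold: float | None = None  # None: Otsu
    bright_objects: bool = False  # EM organelles are dark
    separate_touching: bool = True
    connectivity: int = 26


class DistanceSection(_Strict):
    mode: str = "surface"  # or "centroid"


class MotilitySection(_Strict):
    dt_s: float = 20.0
    n_frames: int = 10
    velocity_px_per_frame: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    background_radius: float | None = None
    seed: int = 0


class ContactsSection(_Strict):
    ld_contact_max_nm: float = 50.0
    pnm_distance_max_nm: float = 1000.0

    def to_contact_params(self) -> ContactParams:
        return ContactParams(self.ld_contact_max_nm, self.pnm_distance_max_nm)


class PipelineConfig(_Strict):
    scene: SceneSection = SceneSection()
    net: NetSection = NetSection()
    train: TrainSection = TrainSection()
    instances: InstanceSection = InstanceSection()
    distance: DistanceSection = DistanceSection()
    motility: MotilitySection = MotilitySection()
    contacts: ContactsSection = ContactsSection()


def load_config(source) -> PipelineConfig:
    """Parse a YAML path, YAML string, or mapping into a validated config."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and len(source) < 4096
        and Path(source).exists()
    ):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, str):
        raw = yaml.safe_load(source) or {}
    elif isinstance(source, dict):
        raw = source
    elif source is None:
        raw = {}
    else:
        raise ConfigError(f"cannot load config from {type(source).__name__}")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as e:
        paths = "; ".join(".".join(str(p) for p in err["loc"]) for err in e.errors())
        raise ConfigError(f"invalid config (offending keys: {paths})") from e


def dump_config(config: PipelineConfig) -> str:
    """Serialize to YAML; load_config(dump_config(c)) == c."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
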