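"""Run configuration: a YAML-serializable bundle of all stage parameters."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mp2rageme import AcquisitionParams
from .phantom import EffectConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    ``tier`` selects between the full voxel-level phantom chain
    (``"voxel"``) and the fast profile-level simulation (``"profile"``).
    The config is serialized verbatim into every results directory so two
    runs from identical configs (and seed) produce identical outputs.
    """

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    effects: EffectConfig = field(default_factory=EffectConfig)
    n_mdd: int = 48
    n_hc: int = 10
    tier: str = "profile"
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)
    ribbon_thickness_mm: float = 8.4
    undulation_amp_mm: float = 0.7
    undulation_period_mm: float = 22.4
    dilation: int = 2
    n_depths: int = 10
    min_voxels: int = 10
    alpha: float = 0.05
    bootstrap_reps: int = 2000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.tier not in ("profile", "voxel"):
            raise ValueError("tier must be 'profile' or 'voxel'")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "acquisition": dict(
                TI1=self.acquisition.TI1,
                TI2=self.acquisition.TI2,
                TR_seq=self.acquisition.TR_seq,
                TR_gre1=self.acquisition.TR_gre1,
                TR_gre2=self.acquisition.TR_gre2,
                FA1=self.acquisition.FA1,
                FA2=self.acquisition.FA2,
                TEs=list(self.acquisition.TEs),
                n_exc=self.acquisition.n_exc,
                inv_eff=self.acquisition.inv_eff,
            ),
            "phantom": dict(
                tier=self.tier,
                grid_shape=list(self.grid_shape),
                voxel_size=list(self.voxel_size),
                ribbon_thickness_mm=self.ribbon_thickness_mm,
                undulation_amp_mm=self.undulation_amp_mm,
                undulation_period_mm=self.undulation_period_mm,
            ),
            "cohort": dict(
                n_mdd=self.n_mdd,
                n_hc=self.n_hc,
                **dataclasses.asdict(self.effects),
            ),
            "laminar": dict(
                dilation=self.dilation,
                n_depths=self.n_depths,
                min_voxels=self.min_voxels,
            ),
            "stats": dict(alpha=self.alpha, bootstrap_reps=self.bootstrap_reps),
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = d or {}
        acq = AcquisitionParams(**{
            k: (tuple(v) if k == "TEs" else v)
            for k, v in (d.get("acquisition") or {}).items()
        })
        cohort = dict(d.get("cohort") or {})
        n_mdd = cohort.pop("n_mdd", 48)
        n_hc = cohort.pop("n_hc", 10)
        effects = EffectConfig(**cohort)
        ph = dict(d.get("phantom") or {})
        lam = dict(d.get("laminar") or {})
        st = dict(d.get("stats") or {})
        return cls(
            acquisition=acq,
            effects=effects,
            n_mdd=n_mdd,
            n_hc=n_hc,
            tier=ph.get("tier", "profile"),
            grid_shape=tuple(ph.get("grid_shape", (64, 64, 32))),
            voxel_size=tuple(ph.get("voxel_size", (0.7, 0.7, 0.7))),
            ribbon_thickness_mm=ph.get("ribbon_thickness_mm", 8.4),
            undulation_amp_mm=ph.get("undulation_amp_mm", 0.7),
            undulation_period_mm=ph.get("undulation_period_mm", 22.4),
            dilation=lam.get("dilation", 2),
            n_depths=lam.get("n_depths", 10),
            min_voxels=lam.get("min_voxels", 10),
            alpha=st.get("alpha", 0.05),
            bootstrap_reps=st.get("bootstrap_reps", 2000),
            master_seed=d.get("master_seed", 0),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
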