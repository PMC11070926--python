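"""Run configuration: one YAML file drives a reproducible pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .. import reference

__all__ = ["RunConfig"]


def _default_truth() -> dict:
    """Generating parameters per LET, seeded from the published summary."""
    return {
        str(let): {
            "ed50_total_dose": reference.ION_ED50[(let, 1)].value,
            "logistic_slope": 1.2,
            "alpha_beta": reference.ION_ALPHA_BETA[let].value,
            "censor_hazard": 0.0002,
        }
        for let in reference.LET_POSITIONS
    }


def _default_photon() -> dict:
    return {
        "ed50_1fx": reference.PHOTON_ED50[1].value,
        "se_1fx": reference.PHOTON_ED50[1].se,
        "ed50_2fx": reference.PHOTON_ED50[2].value,
        "se_2fx": reference.PHOTON_ED50[2].se,
        "bed50": reference.PHOTON_BED50.value,
        "bed50_se": reference.PHOTON_BED50.se,
        "alpha_beta": reference.PHOTON_ALPHA_BETA.value,
    }


@dataclass
class RunConfig:
    seed: int = 0
    level: float = 0.90
    out_dir: str = "cordrbe_run"
    animal_table: str | None = None  # simulate when absent
    truth: dict = field(default_factory=_default_truth)
    photon: dict = field(default_factory=_default_photon)
    lem: dict = field(default_factory=lambda: {
        "alpha_x": 0.1, "beta_x": 0.05, "d_t": 30.0,
        "r_min": 0.3, "track_coeff": 0.05, "track_exp": 1.7,
        "nucleus_radius": 5.0,
    })
    mkm: dict = field(default_factory=lambda: {
        "domain_radius": 0.3, "nucleus_radius": 3.6,
        "alpha_0": 0.003, "beta_m": 0.0015, "y_0": 150.0,
    })

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.animal_table is not None and not Path(self.animal_table).exists():
            raise FileNotFoundError(self.animal_table)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
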