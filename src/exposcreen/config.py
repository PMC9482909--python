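"""Run configuration: one flat, auditable home for every threshold.

Defaults are the workflow's published operating points: QC RSD < 50%,
p < 0.1, FC > 2 / < 0.5, VIP > 1, library score bands 0.9/0.7/0.4, dot
product bands 70/50, fragment presence 50, isotope score 0.5/0.9,
annotation similarity 0.7, candidate gaps 0.2, mass tolerance 5 ppm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # input paths (a dataset directory as produced by the generator)
    dataset_dir: str = "."
    out_dir: str = "run"

    # qc
    qc_rsd_max_pct: float = 50.0

    # mass matching
    ms1_tol_ppm: float = 5.0
    ms2_tol_mz: float = 0.01
    ms2_rel_int_floor: float = 0.01
    adduct_set: list[str] = field(
        default_factory=lambda: ["[M+H]+", "[M+Na]+", "[M+NH4]+", "[M]+", "[M-H]-", "[M+HCOO]-"]
    )

    # formula annotation (panel is CHNO; widen for halogenated suspects)
    element_bounds: dict[str, int] = field(
        default_factory=lambda: {"C": 30, "H": 60, "N": 6, "O": 12}
    )

    # statistics
    stats_p_max: float = 0.1
    stats_fc_up: float = 2.0
    stats_fc_down: float = 0.5
    stats_vip_min: float = 1.0
    stats_orthogonal: bool = True  # one orthogonal component before the predictive one
    stats_fdr: bool = False

    # confidence engine
    schemes: list[str] = field(
        default_factory=lambda: ["suspect_patroon", "nt_patroon", "nt_msdial"]
    )

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
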