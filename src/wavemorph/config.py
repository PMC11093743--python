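"""Pipeline configuration: every analysis constant in one place.

Defaults are the study constants: inshore depth 1 m, g = 9.81 m/s2,
500 m circle radius, 1000 m transect, Jan-Mar winter / Jun-Aug summer
windows, >= 6 sampling years per site, DBC > 2 mm, legal minimum DBC
15 mm and optimum capture size 18.01 mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .morphometry import PARADA_DEFAULT, ParadaParams
from .simulate import WorldConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    g: float = 9.81
    d_i: float = 1.0  # inshore depth, m
    circle_radius: float = 500.0  # m
    transect_length: float = 1000.0  # m
    transect_step: float = 50.0  # m
    winter_months: tuple = (1, 2, 3)
    summer_months: tuple = (6, 7, 8)
    min_years: int = 6  # distinct sampling years per retained site
    dbc_min: float = 2.0  # mm, strict lower measurement cutoff
    parada: ParadaParams = PARADA_DEFAULT
    legal_min_dbc: float = 15.0  # mm
    optimum_dbc: float = 18.01  # mm
    intersection_domain: tuple = (2.0, 50.0)  # mm
    knots_trend: int = 15
    knots_seasonal: int = 12
    world: WorldConfig = field(default_factory=WorldConfig)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, world=dataclasses.replace(self.world, seed=seed)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
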