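"""YAML round-trip for species trait/parameter configuration."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .behaviour import ConsumptionModel, PerchModel, SpeciesTraits
from .movement import MovementParams

__all__ = ["assemblage_to_dict", "assemblage_from_dict", "save_assemblage", "load_assemblage"]


def assemblage_to_dict(assemblage: list[SpeciesTraits]) -> dict:
    return {
        "species": [
            {
                "name": t.name,
                "body_mass_g": t.body_mass_g,
                "relative_abundance": t.relative_abundance,
                "perch_shape": t.perch.shape,
                "perch_scale": t.perch.scale,
                "zip_pi": t.consumption.pi_zero,
                "zip_lambda": t.consumption.lam,
                "gpt_shape": t.gpt_shape,
                "gpt_scale": t.gpt_scale,
                "seeds_per_fruit": dict(t.seeds_per_fruit_by_plant),
                "movement": {k: v for k, v in asdict(t.movement).items() if v is not None},
            }
            for t in assemblage
        ]
    }


def assemblage_from_dict(d: dict) -> list[SpeciesTraits]:
    out = []
    for s in d["species"]:
        out.append(
            SpeciesTraits(
                name=s["name"],
                body_mass_g=float(s["body_mass_g"]),
                relative_abundance=float(s["relative_abundance"]),
                perch=PerchModel(float(s["perch_shape"]), float(s["perch_scale"])),
                consumption=ConsumptionModel(float(s["zip_pi"]), float(s["zip_lambda"])),
                movement=MovementParams(**s["movement"]),
                gpt_shape=float(s["gpt_shape"]),
                gpt_scale=float(s["gpt_scale"]),
                seeds_per_fruit_by_plant={k: int(v) for k, v in s.get("seeds_per_fruit", {}).items()},
            )
        )
    return out


def save_assemblage(assemblage: list[SpeciesTraits], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(assemblage_to_dict(assemblage), fh, sort_keys=False)


def load_assemblage(path) -> list[SpeciesTraits]:
    with open(path) as fh:
        return assemblage_from_dict(yaml.safe_load(fh))
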