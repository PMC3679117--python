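"""Default study system: a six-species thrush assemblage on three fleshy-
fruited trees.

The assemblage mirrors the Cantabrian secondary-growth system this package
emulates: Turdus iliacus, T. philomelos, T. merula, T. pilaris, T. torquatus
and T. viscivorus dispersing Ilex aquifolium (holly), Crataegus monogyna
(hawthorn) and Taxus baccata (yew). Quantitative parameter tables for that
system are not published with the study, so the values below are plausible
defaults chosen once from the qualitative record: feeding in roughly half of
perches with 4-8 fruits per bout (ZIP pi ~ 0.5, lambda ~ 6), Gamma perch
times of a few minutes with heavy right tails, mean gut passage rising with
body mass over 61-118 g, and per-species factor combinations in which
T. pilaris ignores fruit abundance and T. torquatus ignores cover. All of it
is config-overridable; see the YAML round-trip in :mod:`seedscape.configio`.
"""

from __future__ import annotations

from .behaviour import ConsumptionModel, GutModel, PerchModel, SpeciesTraits, gpt_scale_from_mass
from .movement import MovementParams
from .synth import CropSpec, SyntheticLandscapeSpec

__all__ = [
    "PLANT_SPECIES",
    "SEEDS_PER_FRUIT",
    "GPT_SHAPE",
    "GPT_REGRESSION",
    "default_assemblage",
    "default_landscape_spec",
]

PLANT_SPECIES = ["Crataegus_monogyna", "Ilex_aquifolium", "Taxus_baccata"]

# fruits contain 1-4 seeds depending on the plant; holly carries ~4
SEEDS_PER_FRUIT = {"Crataegus_monogyna": 1, "Ilex_aquifolium": 4, "Taxus_baccata": 1}

GPT_SHAPE = 2.0
GPT_REGRESSION = (8.0, 0.18)  # mean GPT (min) = 8.0 + 0.18 * mass (g)

# name, mass (g), relative abundance, perch (shape, scale min),
# ZIP (pi, lambda), movement params
_SPECIES_TABLE = [
    ("Turdus_iliacus", 61.0, 0.30, (0.9, 2.2), (0.50, 6.0),
     dict(a_o=-2.2, b_o=0.030, eps_d=35.0, eta_d=1.2,
          eps_c=0.45, eta_c=1.2, eps_f=5.0, eta_f=1.1, combo="DCF")),
    ("Turdus_philomelos", 70.0, 0.28, (0.9, 2.6), (0.52, 5.5),
     dict(a_o=-2.3, b_o=0.028, eps_d=40.0, eta_d=1.3,
          eps_c=0.50, eta_c=1.3, eps_f=5.5, eta_f=1.2, combo="DCF")),
    ("Turdus_merula", 103.0, 0.17, (0.8, 3.5), (0.48, 6.5),
     dict(a_o=-2.4, b_o=0.025, eps_d=45.0, eta_d=1.2,
          eps_c=0.20, eta_c=2.5, eps_f=3.0, eta_f=1.5, combo="DCF")),
    ("Turdus_pilaris", 106.0, 0.06, (0.8, 3.8), (0.55, 7.0),
     dict(a_o=-2.0, b_o=0.020, eps_d=60.0, eta_d=1.1,
          eps_c=0.25, eta_c=2.0, combo="DC")),  # no fruit response
    ("Turdus_torquatus", 109.0, 0.06, (0.8, 4.0), (0.50, 6.0),
     dict(a_o=-2.1, b_o=0.022, eps_d=45.0, eta_d=1.2,
          eps_f=1.0, eta_f=3.0, combo="DF")),  # no cover response
    ("Turdus_viscivorus", 118.0, 0.13, (0.7, 5.0), (0.55, 6.5),
     dict(a_o=-1.8, b_o=0.015, eps_d=65.0, eta_d=1.0,
          eps_c=0.15, eta_c=3.0, eps_f=1.5, eta_f=3.0, combo="DCF")),
]


def default_assemblage() -> list[SpeciesTraits]:
    out = []
    for name, mass, ab, (p_sh, p_sc), (pi, lam), mv in _SPECIES_TABLE:
        scale = gpt_scale_from_mass(mass, *GPT_REGRESSION, GPT_SHAPE)
        out.append(
            SpeciesTraits(
                name=name,
                body_mass_g=mass,
                relative_abundance=ab,
                perch=PerchModel(p_sh, p_sc),
                consumption=ConsumptionModel(pi, lam),
                movement=MovementParams(**mv),
                gpt_shape=GPT_SHAPE,
                gpt_scale=scale,
                seeds_per_fruit_by_plant=dict(SEEDS_PER_FRUIT),
            )
        )
    return out


def default_gut_model() -> GutModel:
    return GutModel(
        shape=GPT_SHAPE,
        scale_by_species={
            name: gpt_scale_from_mass(mass, *GPT_REGRESSION, GPT_SHAPE)
            for name, mass, *_ in _SPECIES_TABLE
        },
        gpt_regression=GPT_REGRESSION,
    )


def default_landscape_spec() -> SyntheticLandscapeSpec:
    """The emulated study plot: 440 cells of 20 m with clumped fruit crops."""
    return SyntheticLandscapeSpec(
        rows=22,
        cols=20,
        cell_size=20.0,
        cover_mean=0.45,
        cover_sd=0.35,
        cover_corr_cells=2.0,
        crops=[
            CropSpec("Crataegus_monogyna", n_trees=150, clustering=4, cluster_sd_m=30.0,
                     fai_probs=(0.05, 0.20, 0.35, 0.25, 0.12, 0.03)),
            CropSpec("Ilex_aquifolium", n_trees=300, clustering=8, cluster_sd_m=25.0,
                     fai_probs=(0.05, 0.10, 0.25, 0.35, 0.20, 0.05)),
            CropSpec("Taxus_baccata", n_trees=60, clustering=3, cluster_sd_m=40.0,
                     fai_probs=(0.10, 0.20, 0.30, 0.25, 0.12, 0.03)),
        ],
    )
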