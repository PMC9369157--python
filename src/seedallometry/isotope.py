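"""Hydrogen-isotope mass balance for bulk seed δ²H.

Seed organic hydrogen carries the signature of leaf water (where source
metabolites are made, depleted by the fractionation of NADPH-mediated
reduction), partially overwritten by exchange with pod water during
import and metabolism, and shifted by compound-class fractionations.
Bulk seed δ²H then mixes a lipid pool and a non-lipid pool (mean of
protein and starch) in proportion to the lipid hydrogen mole fraction x:

    δ_source     = δ_wl (1 + ε_A) + ε_A
    δ_metabolite = (1 − f) δ_source + f (δ_wp (1 + ε_H) + ε_H) − Δ
    δ_seed       = (1 − x) δ_other + x δ_lipids

All δ and ε are dimensionless isotope-ratio deviations; the public API
speaks per mil (‰) and converts internally, since the equations mix δ
and ε multiplicatively and are only consistent in fractional form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class IsotopeDomainError(ValueError):
    """Raised for physically impossible isotope inputs."""


def permil_to_fraction(value_permil: float) -> float:
    """Convert a δ or ε value from ‰ to its dimensionless fraction."""
    return value_permil / 1000.0


def fraction_to_permil(value: float) -> float:
    """Convert a dimensionless δ or ε to ‰."""
    return value * 1000.0


def ratio_to_delta(r_sample: float, r_standard: float) -> float:
    """δ in ‰ of a sample isotope ratio against a standard ratio.

    δ = R_sample / R_standard − 1, reported in ‰.  Both ratios must be
    strictly positive.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise IsotopeDomainError("isotope ratios must be strictly positive")
    return fraction_to_permil(r_sample / r_standard - 1.0)


@dataclass(frozen=True)
class FractionationConstants:
    """Fractionation factors and exchangeable-H fractions (values in ‰ / [0,1]).

    eps_a: fractionation in NADPH reduction (product ²H-depleted).
    eps_h: equilibrium fractionation of H exchange with water.
    delta_cap_*: metabolic fractionation Δ of protein synthesis from amino
        acids, lipid synthesis from precursors, and starch synthesis
        (glycosidic linkage only, hence 0).
    f_*: fraction of each compound class's H atoms that exchange with
        local water — one third of sugar H (OH groups), 0.14 for proteins,
        0.75 for lipids (water-derived H in triose-to-acetyl-CoA
        conversion and fatty-acid synthesis).
    """

    eps_a: float = -171.0
    eps_h: float = +158.0
    delta_cap_protein: float = 80.0
    delta_cap_lipid: float = 70.0
    delta_cap_starch: float = 0.0
    f_starch: float = 0.33
    f_protein: float = 0.14
    f_lipid: float = 0.75

    def __post_init__(self) -> None:
        for name in ("f_starch", "f_protein", "f_lipid"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise IsotopeDomainError(f"{name}={f} outside [0, 1]")


@dataclass(frozen=True)
class IsotopeScenario:
    """Leaf and pod water δ²H under a named enrichment hypothesis.

    Plant water is ²H-enriched relative to source (rain/tap) water by
    transpiration.  The named scenarios bracket the unknown leaf/pod
    water difference:

    - ``a``: moderate difference — leaf +60‰, pod +30‰ over source;
    - ``b``: large difference — leaf +75‰, pod at source water;
    - ``c``: no difference — both waters at 0‰ absolute.

    Scenario ``a`` is the default for generation and reporting.
    """

    name: str = "a"
    source_water_delta: float = -33.0
    leaf_enrichment: float = 60.0
    pod_enrichment: float = 30.0

    @property
    def delta_wl(self) -> float:
        """Leaf water δ²H in ‰."""
        return self.source_water_delta + self.leaf_enrichment

    @property
    def delta_wp(self) -> float:
        """Pod water δ²H in ‰."""
        return self.source_water_delta + self.pod_enrichment

    @classmethod
    def named(cls, name: str, source_water_delta: float = -33.0) -> "IsotopeScenario":
        if name == "a":
            return cls("a", source_water_delta, 60.0, 30.0)
        if name == "b":
            return cls("b", source_water_delta, 75.0, 0.0)
        if name == "c":
            # both waters pinned at 0 permil absolute
            return cls("c", source_water_delta,
                       -source_water_delta, -source_water_delta)
        raise IsotopeDomainError(f"unknown scenario {name!r}; use a, b, c or build a custom one")


def delta_source(delta_wl: float, constants: FractionationConstants = FractionationConstants()) -> float:
    """δ²H (‰) of source metabolites made in the leaf.

    Photosynthates inherit leaf water corrected for the reduction
    fractionation: δ_source = δ_wl (1 + ε_A) + ε_A.
    """
    d = permil_to_fraction(delta_wl)
    e = permil_to_fraction(constants.eps_a)
    return fraction_to_permil(d * (1.0 + e) + e)


def delta_metabolite(
    delta_src: float,
    delta_wp: float,
    f: float,
    delta_cap: float,
    constants: FractionationConstants = FractionationConstants(),
) -> float:
    """δ²H (‰) of a compound class after exchange and metabolic fractionation.

    A fraction ``f`` of the class's H atoms equilibrates with pod water
    (with exchange fractionation ε_H); synthesis imposes an additional
    offset Δ: δ = (1 − f) δ_source + f (δ_wp (1 + ε_H) + ε_H) − Δ.
    """
    if not 0.0 <= f <= 1.0:
        raise IsotopeDomainError(f"exchangeable fraction f={f} outside [0, 1]")
    ds = permil_to_fraction(delta_src)
    dw = permil_to_fraction(delta_wp)
    eh = permil_to_fraction(constants.eps_h)
    dc = permil_to_fraction(delta_cap)
    return fraction_to_permil((1.0 - f) * ds + f * (dw * (1.0 + eh) + eh) - dc)


def delta_seed(x: float, delta_other: float, delta_lipids: float) -> float:
    """Bulk seed δ²H (‰) as a lipid / non-lipid two-pool mixture.

    ``x`` is the lipid hydrogen mole fraction; the non-lipid pool is the
    protein/starch average.  Linear in x by construction.
    """
    if not 0.0 <= x <= 1.0:
        raise IsotopeDomainError(f"lipid H mole fraction x={x} outside [0, 1]")
    return (1.0 - x) * delta_other + x * delta_lipids


def class_deltas(
    scenario: IsotopeScenario,
    constants: FractionationConstants = FractionationConstants(),
) -> dict[str, float]:
    """δ²H (‰) of starch, protein, lipid and the non-lipid average."""
    src = delta_source(scenario.delta_wl, constants)
    starch = delta_metabolite(src, scenario.delta_wp, constants.f_starch,
                              constants.delta_cap_starch, constants)
    protein = delta_metabolite(src, scenario.delta_wp, constants.f_protein,
                               constants.delta_cap_protein, constants)
    lipid = delta_metabolite(src, scenario.delta_wp, constants.f_lipid,
                             constants.delta_cap_lipid, constants)
    return {
        "source": src,
        "starch": starch,
        "protein": protein,
        "lipid": lipid,
        # unweighted mean, as the model defines the non-lipid pool
        "other": 0.5 * (starch + protein),
    }


def predict_seed_delta2h(
    x: float,
    scenario: IsotopeScenario = IsotopeScenario(),
    constants: FractionationConstants = FractionationConstants(),
    weighted_other: tuple[float, float] | None = None,
) -> float:
    """Predicted bulk seed δ²H (‰) for lipid H mole fraction ``x``.

    Composes the source, exchange and mixing equations.  By default the
    non-lipid pool is the unweighted protein/starch mean; passing
    ``weighted_other=(w_protein, w_starch)`` switches to a weighted mean.
    """
    d = class_deltas(scenario, constants)
    if weighted_other is None:
        other = d["other"]
    else:
        wp, ws = weighted_other
        if wp < 0 or ws < 0 or wp + ws == 0:
            raise IsotopeDomainError("weights for the non-lipid pool must be nonnegative, not both zero")
        other = (wp * d["protein"] + ws * d["starch"]) / (wp + ws)
    return delta_seed(x, other, d["lipid"])


def scenario_line(
    scenario: IsotopeScenario,
    x_grid: Sequence[float] | Iterable[float],
    constants: FractionationConstants = FractionationConstants(),
) -> pd.DataFrame:
    """Predicted δ²H along a grid of lipid H mole fractions.

    Returns a two-column table (x, delta_permil) ready for TSV export;
    the model line of the observed-δ²H-versus-x plot.
    """
    xs = np.asarray(list(x_grid), dtype=float)
    if xs.size and (xs.min() < 0 or xs.max() > 1):
        raise IsotopeDomainError("x grid must lie within [0, 1]")
    d = class_deltas(scenario, constants)
    ys = (1.0 - xs) * d["other"] + xs * d["lipid"]
    return pd.DataFrame({"x": xs, "delta_permil": ys})
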