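"""Synthetic seed-cohort generator.

Emulates the statistical structure of a multi-accession seed dataset:
eight accessions with realistic natural weight ranges, linear elemental
allometry (N content rising, H content falling with seed weight), bulk
δ²H generated from the hydrogen-isotope mass-balance forward model plus
calibrated noise, and a 244-analyte metabolome containing positively and
negatively weight-correlated metabolite classes plus paired amino-acid /
degradation-product columns with opposite trends.

Two generation modes:

- ``elemental``: percent N and H are drawn linearly in weight with the
  target slopes and noise calibrated to a target R²; C and S fluctuate
  around constant means.  The latent biochemical composition is obtained
  by inverting the generated elemental data.
- ``biochemical``: latent component fractions are drawn first (lipid
  decaying exponentially with weight, carbohydrate and albumin constant)
  and the elemental data follow exactly from the forward mixing model,
  guaranteeing exact inversion recovery.

Every draw flows from a single ``numpy`` Generator so identical configs
and seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .elemental import (
    BiochemicalComposition,
    ComponentReferenceMatrix,
    CorrectionPolicy,
    ElementalComposition,
    correct_composition,
    forward_composition,
    invert_composition,
    lipid_h_mole_fraction,
)
from .isotope import FractionationConstants, IsotopeScenario, class_deltas


class GeneratorError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class AccessionSpec:
    """One accession with its natural seed-weight range in mg."""

    name: str
    accession_no: int
    weight_min: float
    weight_max: float

    def __post_init__(self) -> None:
        if not 0 < self.weight_min < self.weight_max:
            raise GeneratorError(f"invalid weight range for {self.name}")


#: The eight barrel-medic core-collection accessions with their natural
#: seed weight ranges (mg).
DEFAULT_ACCESSIONS: tuple[AccessionSpec, ...] = (
    AccessionSpec("Jemalong A17", 738, 1.1, 6.3),
    AccessionSpec("DZA045-6", 736, 1.8, 6.4),
    AccessionSpec("DZA315-16", 734, 1.9, 6.1),
    AccessionSpec("ESP105-L", 544, 2.3, 8.6),
    AccessionSpec("F83005-5", 530, 2.0, 6.7),
    AccessionSpec("DZA012-J", 368, 1.0, 5.1),
    AccessionSpec("SA028064", 174, 2.0, 7.2),
    AccessionSpec("SA022322", 163, 2.0, 6.2),
)

METABOLITE_CLASSES = (
    "hexose", "disaccharide", "amino_acid", "degradation_product",
    "fatty_acid", "organic_acid", "nucleoside", "null",
)

POSITIVE_CLASSES = ("hexose", "amino_acid", "nucleoside")
NEGATIVE_CLASSES = ("disaccharide", "fatty_acid", "organic_acid")


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator (defaults are the study conditions).

    Elemental-mode slopes are the observed allometry (+0.17 %N per mg,
    −0.14 %H per mg); intercepts put %N near 6 and %H near 7 at 1 mg.
    Gaussian noise on the linear responses is calibrated so the expected
    regression R² matches the targets (0.36 for %N on weight, 0.38 for
    δ²H on the lipid H mole fraction).  Biochemical-mode lipid content
    decays exponentially from ``lipid_max`` toward ``lipid_min`` as
    weight grows, with carbohydrate and albumin held at 37% and 13%.
    """

    n_seeds_per_accession: int = 20
    rng_seed: int = 0
    mode: str = "elemental"  # or "biochemical"
    accessions: tuple[AccessionSpec, ...] = DEFAULT_ACCESSIONS

    # elemental mode
    slope_n: float = +0.17     # % N per mg
    slope_h: float = -0.14     # % H per mg
    intercept_n: float = 5.83  # %N ~ 6 at 1 mg
    intercept_h: float = 7.14  # %H ~ 7 at 1 mg
    mean_c: float = 45.0       # % C, constant mean
    mean_s: float = 0.33       # % S, constant mean
    sd_c: float = 0.8
    sd_s: float = 0.04
    target_r2_n: float = 0.36
    target_r2_h: float = 0.36
    s_small_seed_bump: float = 0.0   # extra %S added below 2 mg (off by default)

    # biochemical mode
    w_carb: float = 0.37
    w_alb: float = 0.13
    lipid_max: float = 0.20   # lipid fraction at 1 mg
    lipid_min: float = 0.08   # asymptote in large seeds
    lipid_decay: float = 0.35  # per mg

    # isotopes
    scenario: str = "a"
    target_r2_d2h: float = 0.38
    mean_d13c: float = -27.0
    sd_d13c: float = 1.0
    mean_d15n: float = 0.5
    sd_d15n: float = 1.2
    mean_d34s: float = 5.0
    sd_d34s: float = 1.0

    # metabolome
    n_analytes: int = 244
    prop_positive: float = 0.30
    prop_negative: float = 0.20
    prop_paired: float = 0.10
    prop_null: float = 0.40
    effect_size: float = 0.08        # per mg, log-intensity scale
    log_noise_sd: float = 0.5
    accession_sd: float = 0.0        # near-zero: accessions share one trend
    baseline_sd: float = 1.0

    correction: CorrectionPolicy = field(default_factory=CorrectionPolicy)

    def __post_init__(self) -> None:
        if self.mode not in ("elemental", "biochemical"):
            raise GeneratorError(f"unknown mode {self.mode!r}")
        for name in ("target_r2_n", "target_r2_h", "target_r2_d2h"):
            r2 = getattr(self, name)
            if not 0.0 < r2 < 1.0:
                raise GeneratorError(f"{name}={r2} must be in (0, 1)")
        props = (self.prop_positive, self.prop_negative, self.prop_paired, self.prop_null)
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise GeneratorError("metabolite class proportions must be nonnegative and sum to 1")
        if not (0 <= self.lipid_min <= self.lipid_max <= 1):
            raise GeneratorError("lipid fractions must satisfy 0 <= lipid_min <= lipid_max <= 1")
        if self.lipid_decay < 0:
            raise GeneratorError("lipid_decay must be >= 0")
        if self.w_carb + self.w_alb + self.lipid_max > 1:
            raise GeneratorError("biochemical fractions exceed 1 at minimum weight")


@dataclass(frozen=True)
class SeedRecord:
    """A single generated seed with its latent truths."""

    seed_id: str
    accession: str
    weight_mg: float
    elemental: ElementalComposition
    d13c: float
    d15n: float
    d34s: float
    d2h: float
    true_biochemical: BiochemicalComposition | None
    true_lipid_h_mole_fraction: float


def sample_weights(spec: AccessionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` seed weights from a Beta(2,2) scaled to the accession range.

    Beta(2,2) gives mild central tendency within the natural range,
    avoiding pile-up at the extremes.
    """
    if n < 0:
        raise GeneratorError("n must be >= 0")
    u = rng.beta(2.0, 2.0, size=n)
    return spec.weight_min + u * (spec.weight_max - spec.weight_min)


def _noise_sd_for_target_r2(slope: float, var_x: float, target_r2: float) -> float:
    """SD of additive noise so a linear response hits a target regression R².

    For y = a + b x + e,  R² = b² Var(x) / (b² Var(x) + σ²), hence
    σ² = b² Var(x) (1 − R²) / R².
    """
    return float(np.sqrt(slope**2 * var_x * (1.0 - target_r2) / target_r2))


def simulate_elemental(
    weights: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Percent C/N/S/H per seed with linear N and H allometry.

    Noise on %N and %H is calibrated to the configured target R² using
    the empirical weight variance of this cohort.
    """
    w = np.asarray(weights, dtype=float)
    var_w = float(np.var(w)) if w.size > 1 else 0.0
    sd_n = _noise_sd_for_target_r2(config.slope_n, var_w, config.target_r2_n)
    sd_h = _noise_sd_for_target_r2(config.slope_h, var_w, config.target_r2_h)
    pct_n = config.intercept_n + config.slope_n * w + rng.normal(0, sd_n, w.size)
    pct_h = config.intercept_h + config.slope_h * w + rng.normal(0, sd_h, w.size)
    pct_c = config.mean_c + rng.normal(0, config.sd_c, w.size)
    pct_s = config.mean_s + rng.normal(0, config.sd_s, w.size)
    if config.s_small_seed_bump:
        pct_s = pct_s + np.where(w < 2.0, config.s_small_seed_bump, 0.0)
    return pd.DataFrame(
        {"pct_C": pct_c.clip(0), "pct_N": pct_n.clip(0),
         "pct_S": pct_s.clip(0), "pct_H": pct_h.clip(0)}
    )


def simulate_biochemical(
    weights: np.ndarray, config: GeneratorConfig, rng: np.random.Generator,
    ref: ComponentReferenceMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent component fractions plus the exact elemental data they imply.

    Lipid fraction decays exponentially with weight,
    ``w_lip(w) = lipid_min + (lipid_max − lipid_min) exp(−k (w − 1))``;
    carbohydrate and albumin stay constant and S-poor protein takes the
    remainder.  Elemental percentages follow from the forward mixing
    model (then rescaled back to whole-seed basis), so inversion recovers
    the latent fractions exactly.
    """
    ref = ref or ComponentReferenceMatrix()
    w = np.asarray(weights, dtype=float)
    w_lip = config.lipid_min + (config.lipid_max - config.lipid_min) * np.exp(
        -config.lipid_decay * (w - 1.0)
    )
    w_carb = np.full_like(w, config.w_carb)
    w_alb = np.full_like(w, config.w_alb)
    w_spp = 1.0 - w_carb - w_alb - w_lip
    if np.any(w_spp < 0) or np.any(w_lip > 1):
        raise GeneratorError("component fractions left [0, 1]; adjust lipid/carb/albumin settings")
    biochem = pd.DataFrame(
        {"w_carb": w_carb, "w_alb": w_alb, "w_spp": w_spp, "w_lip": w_lip}
    )
    corrected = biochem.to_numpy() @ ref.matrix  # organic-matter basis
    raw = corrected * config.correction.divisor * 100.0  # whole-seed percent
    elemental = pd.DataFrame(raw, columns=["pct_C", "pct_N", "pct_S", "pct_H"])
    return biochem, elemental


def simulate_isotopes(
    weights: np.ndarray,
    x: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    constants: FractionationConstants | None = None,
) -> pd.DataFrame:
    """Per-seed isotope deltas (‰).

    δ²H is the mass-balance forward prediction at each seed's lipid H
    mole fraction plus Gaussian noise calibrated so the regression of
    δ²H on x has the target R².  δ¹³C, δ¹⁵N and δ³⁴S are drawn
    weight-independent around their configured means.
    """
    constants = constants or FractionationConstants()
    scenario = IsotopeScenario.named(config.scenario)
    d = class_deltas(scenario, constants)
    xv = np.asarray(x, dtype=float)
    pred = (1.0 - xv) * d["other"] + xv * d["lipid"]
    var_pred = float(np.var(pred)) if pred.size > 1 else 0.0
    sd = _noise_sd_for_target_r2(1.0, var_pred, config.target_r2_d2h)
    n = len(weights)
    return pd.DataFrame(
        {
            "d13C": rng.normal(config.mean_d13c, config.sd_d13c, n),
            "d15N": rng.normal(config.mean_d15n, config.sd_d15n, n),
            "d34S": rng.normal(config.mean_d34s, config.sd_d34s, n),
            "d2H": pred + rng.normal(0, sd, n),
            "d2H_predicted": pred,
        }
    )


def _analyte_annotations(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic class layout of the metabolome columns.

    Paired amino-acid / degradation-product columns share a ``pair_id``
    and get opposite weight-trend signs; the null class has no trend.
    """
    m = config.n_analytes
    n_paired = 2 * int(round(config.prop_paired * m / 2.0))
    n_pos = int(round(config.prop_positive * m))
    n_neg = int(round(config.prop_negative * m))
    n_null = m - n_pos - n_neg - n_paired
    if n_null < 0:
        raise GeneratorError("class proportions leave no room for the null class")
    rows = []
    k = 0
    for i in range(n_pos):
        rows.append((f"m{k:03d}", POSITIVE_CLASSES[i % len(POSITIVE_CLASSES)], +1, -1)); k += 1
    for i in range(n_neg):
        rows.append((f"m{k:03d}", NEGATIVE_CLASSES[i % len(NEGATIVE_CLASSES)], -1, -1)); k += 1
    for pair in range(n_paired // 2):
        rows.append((f"m{k:03d}", "amino_acid", +1, pair)); k += 1
        rows.append((f"m{k:03d}", "degradation_product", -1, pair)); k += 1
    for _ in range(n_null):
        rows.append((f"m{k:03d}", "null", 0, -1)); k += 1
    return pd.DataFrame(rows, columns=["analyte", "class", "sign", "pair_id"])


def simulate_metabolome(
    weights: np.ndarray,
    accessions: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeds × analytes nonnegative intensity matrix plus annotations.

    Log-intensity of analyte j in seed i is
    ``baseline_j + sign_j * effect * (w_i − mean w) + accession offset +
    noise``, exponentiated to an intensity.  Intensities emulate values
    already normalised to the internal standard and seed weight.
    """
    ann = _analyte_annotations(config)
    w = np.asarray(weights, dtype=float)
    n, m = len(w), config.n_analytes
    baseline = rng.normal(0.0, config.baseline_sd, m)
    signs = ann["sign"].to_numpy(dtype=float)
    centred = w - w.mean()
    logi = baseline[None, :] + np.outer(centred, signs * config.effect_size)
    if config.accession_sd > 0:
        levels = pd.unique(accessions)
        offsets = rng.normal(0.0, config.accession_sd, (len(levels), m))
        idx = pd.Index(levels).get_indexer(accessions)
        logi = logi + offsets[idx]
    logi = logi + rng.normal(0.0, config.log_noise_sd, (n, m))
    matrix = pd.DataFrame(np.exp(logi), columns=ann["analyte"].tolist())
    return matrix, ann


def simulate_cohort(
    config: GeneratorConfig | None = None,
    ref: ComponentReferenceMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: seed table, metabolome matrix, annotations.

    The seed table carries measured quantities (weight, percent
    elements, isotope deltas) plus the latent truths used to generate
    them (component fractions, lipid H mole fraction, noise-free δ²H)
    for recovery testing.  Fully reproducible from ``config.rng_seed``.
    """
    config = config or GeneratorConfig()
    ref = ref or ComponentReferenceMatrix()
    rng = np.random.default_rng(config.rng_seed)

    # weights first, across all accessions, so elemental noise is
    # calibrated against the pooled weight variance — the target R²
    # describes the all-accessions-together regression
    acc_names, weight_blocks = [], []
    for spec in config.accessions:
        w = sample_weights(spec, config.n_seeds_per_accession, rng)
        weight_blocks.append(w)
        acc_names.extend([spec.name] * len(w))
    w_all = np.concatenate(weight_blocks) if weight_blocks else np.empty(0)

    if config.mode == "elemental":
        elem = simulate_elemental(w_all, config, rng)
        latent = []
        for row in elem.itertuples(index=False):
            raw = ElementalComposition.from_percent(row.pct_C, row.pct_N, row.pct_S, row.pct_H)
            corrected = correct_composition(raw, config.correction)
            # noisy linear elemental data need not sum near 1 after
            # inversion; the warning band is informative here, not an error
            biochem = invert_composition(corrected, ref, warn_total_outside=(0.0, np.inf))
            latent.append(biochem)
    else:
        biochem_df, elem = simulate_biochemical(w_all, config, rng, ref)
        latent = [BiochemicalComposition.from_array(r) for r in biochem_df.to_numpy()]
    x = np.array([lipid_h_mole_fraction(b, ref) for b in latent])

    seeds = elem.copy()
    seeds.insert(0, "accession", acc_names)
    seeds.insert(1, "weight_mg", w_all)
    for col, i in (("true_w_carb", 0), ("true_w_alb", 1), ("true_w_spp", 2), ("true_w_lip", 3)):
        seeds[col] = [b.as_array()[i] for b in latent]
    seeds["true_x"] = x
    iso = simulate_isotopes(seeds["weight_mg"].to_numpy(), seeds["true_x"].to_numpy(), config, rng)
    seeds = pd.concat([seeds, iso.rename(columns={"d2H_predicted": "true_d2H"})], axis=1)
    seeds.insert(0, "seed_id", [f"s{i:04d}" for i in range(len(seeds))])

    matrix, ann = simulate_metabolome(
        seeds["weight_mg"].to_numpy(), seeds["accession"].to_numpy(), config, rng
    )
    matrix.insert(0, "seed_id", seeds["seed_id"])
    return seeds, matrix, ann


def write_cohort(
    outdir: str | Path,
    seeds: pd.DataFrame,
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
) -> dict[str, Path]:
    """Write the standard file layout: seeds.csv, metabolome.tsv, annotations.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "seeds": outdir / "seeds.csv",
        "metabolome": outdir / "metabolome.tsv",
        "annotations": outdir / "annotations.tsv",
    }
    seeds.to_csv(paths["seeds"], index=False)
    matrix.to_csv(paths["metabolome"], sep="\t", index=False)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    return paths
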