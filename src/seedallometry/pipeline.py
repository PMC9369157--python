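"""Pipeline configuration and stage runners.

Pure functions tying the stages together — simulate, compose (elemental
to biochemical), isotope prediction, metabolome statistics — plus YAML
configuration with schema validation and run manifests.  The command
line in :mod:`seedallometry.cli` is a thin wrapper over these.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .elemental import (
    ComponentReferenceMatrix,
    CorrectionPolicy,
    compose_table,
    read_seed_table,
)
from .isotope import FractionationConstants, IsotopeScenario, scenario_line
from .multivariate import cluster_scores, opls_fit, opls_predict, uv_scale
from .stats import (
    best_subset,
    fit_linear,
    prefilter_top_univariate,
    subsets_to_frame,
    univariate_screen,
    volcano_table,
)
from .synthetic import GeneratorConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Raised for invalid pipeline configuration (exit code 2 at the CLI)."""


class PipelineDataError(ValueError):
    """Raised for inconsistent input data (exit code 1 at the CLI)."""


@dataclass
class StatsSettings:
    alpha: float = 0.05
    nvmax: int = 5
    nbest: int = 100
    top_k: int = 20
    folds: int = 7
    n_ortho: int = 1
    n_clusters: int = 3  # small / medium / large weight classes

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise PipelineConfigError(f"alpha={self.alpha} outside (0, 1)")
        for name in ("nvmax", "nbest", "top_k", "n_ortho", "n_clusters"):
            if getattr(self, name) < (0 if name == "n_ortho" else 1):
                raise PipelineConfigError(f"{name} must be positive")
        if self.folds < 2:
            raise PipelineConfigError("folds must be >= 2")


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``load_config`` for the YAML form)."""

    rng_seed: int = 0
    output_dir: Path = Path("out")
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    correction: CorrectionPolicy = field(default_factory=CorrectionPolicy)
    reference_matrix_path: Path | None = None
    scenario: str = "a"
    constants: FractionationConstants = field(default_factory=FractionationConstants)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def reference_matrix(self) -> ComponentReferenceMatrix:
        if self.reference_matrix_path is None:
            return ComponentReferenceMatrix()
        return ComponentReferenceMatrix.from_csv(self.reference_matrix_path)


_KNOWN_SECTIONS = {"rng_seed", "output_dir", "generator", "correction",
                   "reference_matrix", "isotope", "stats"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown top-level keys and unknown keys inside any section are
    configuration errors, so typos never pass silently.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw = {**raw, **overrides}
    if not isinstance(raw, dict):
        raise PipelineConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")

    def build(cls, section: dict, name: str):
        if not isinstance(section, dict):
            raise PipelineConfigError(f"section {name!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise PipelineConfigError(f"unknown keys in {name!r}: {sorted(bad)}")
        try:
            return cls(**section)
        except (TypeError, ValueError) as exc:
            raise PipelineConfigError(f"invalid {name!r} section: {exc}") from exc

    rng_seed = int(raw.get("rng_seed", 0))
    gen_section = dict(raw.get("generator", {}))
    gen_section.setdefault("rng_seed", rng_seed)
    iso = raw.get("isotope", {})
    if not isinstance(iso, dict):
        raise PipelineConfigError("section 'isotope' must be a mapping")
    bad = set(iso) - {"scenario", "constants"}
    if bad:
        raise PipelineConfigError(f"unknown keys in 'isotope': {sorted(bad)}")
    cfg = PipelineConfig(
        rng_seed=rng_seed,
        output_dir=Path(raw.get("output_dir", "out")),
        generator=build(GeneratorConfig, gen_section, "generator"),
        correction=build(CorrectionPolicy, raw.get("correction", {}), "correction"),
        reference_matrix_path=Path(raw["reference_matrix"]) if raw.get("reference_matrix") else None,
        scenario=iso.get("scenario", "a"),
        constants=build(FractionationConstants, iso.get("constants", {}), "isotope.constants"),
        stats=build(StatsSettings, raw.get("stats", {}), "stats"),
    )
    if cfg.reference_matrix_path is not None and not cfg.reference_matrix_path.exists():
        raise PipelineConfigError(f"reference matrix not found: {cfg.reference_matrix_path}")
    IsotopeScenario.named(cfg.scenario)  # validates the name
    return cfg


def write_manifest(outdir: Path, config_echo: dict, paths: dict[str, Path]) -> Path:
    """Write a manifest with the config echo and sha256 checksums."""
    manifest = {
        "config": config_echo,
        "outputs": {
            name: {"path": str(p), "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
            for name, p in sorted(paths.items())
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    echo["output_dir"] = str(cfg.output_dir)
    return echo


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig, outdir: Path | None = None) -> dict[str, Path]:
    """Generate a cohort and write seeds.csv / metabolome.tsv / annotations.tsv."""
    outdir = Path(outdir or cfg.output_dir)
    seeds, matrix, ann = simulate_cohort(cfg.generator, cfg.reference_matrix())
    paths = write_cohort(outdir, seeds, matrix, ann)
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(_config_echo(cfg), sort_keys=False))
    paths["config"] = cfg_path
    write_manifest(outdir, _config_echo(cfg), paths)
    logger.info("simulated %d seeds x %d analytes into %s", len(seeds), matrix.shape[1] - 1, outdir)
    return paths


def run_compose(seeds_path: Path, cfg: PipelineConfig, out_path: Path) -> pd.DataFrame:
    """Correct, invert and derive lipid H mole fraction per seed; write CSV."""
    try:
        seeds = read_seed_table(seeds_path)
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineDataError(f"cannot read seed table {seeds_path}: {exc}") from exc
    table = compose_table(seeds, cfg.correction, cfg.reference_matrix())
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    return table


def run_isotope(
    seeds_path: Path,
    biochem_path: Path,
    cfg: PipelineConfig,
    outdir: Path,
    x_grid_points: int = 101,
) -> dict[str, Path]:
    """Observed vs predicted δ²H table plus the three scenario lines.

    Emits ``isotope_observed.tsv`` (x, observed, predicted under
    scenarios a/b/c) and ``scenario_lines.tsv``, and a regression
    summary of observed δ²H on x.
    """
    seeds = pd.read_csv(seeds_path)
    if "d2H" not in seeds.columns:
        raise PipelineDataError(f"{seeds_path} lacks a d2H column")
    biochem = pd.read_csv(biochem_path)
    if "lipid_h_mole_fraction" not in biochem.columns:
        raise PipelineDataError(f"{biochem_path} lacks lipid_h_mole_fraction")
    merged = seeds.merge(biochem[["seed_id", "lipid_h_mole_fraction"]], on="seed_id")
    if len(merged) != len(seeds):
        raise PipelineDataError("seed tables do not share the same seed_id set")

    x = merged["lipid_h_mole_fraction"].to_numpy()
    obs = merged["d2H"].to_numpy()
    out = pd.DataFrame({"seed_id": merged["seed_id"], "x": x, "observed_d2H": obs})
    for name in ("a", "b", "c"):
        line = scenario_line(IsotopeScenario.named(name), x, cfg.constants)
        out[f"predicted_{name}"] = line["delta_permil"].to_numpy()

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"observed": outdir / "isotope_observed.tsv",
             "lines": outdir / "scenario_lines.tsv",
             "regression": outdir / "isotope_regression.json"}
    out.to_csv(paths["observed"], sep="\t", index=False)

    grid = np.linspace(0.0, 1.0, x_grid_points)
    lines = pd.concat(
        [scenario_line(IsotopeScenario.named(n), grid, cfg.constants).assign(scenario=n)
         for n in ("a", "b", "c")],
        ignore_index=True,
    )
    lines.to_csv(paths["lines"], sep="\t", index=False)

    reg = fit_linear(x, obs)
    paths["regression"].write_text(json.dumps({
        "slope_permil_per_x": reg.slope, "intercept_permil": reg.intercept,
        "r_squared": reg.r_squared, "p_value": reg.p_value, "n": reg.n,
    }, indent=2) + "\n")
    return paths


def run_stats(
    metabolome_path: Path,
    seeds_path: Path,
    cfg: PipelineConfig,
    outdir: Path,
) -> dict[str, Path]:
    """Univariate screen, OPLS, volcano, best subsets and score clustering."""
    matrix = pd.read_csv(metabolome_path, sep="\t")
    seeds = pd.read_csv(seeds_path)
    if "seed_id" in matrix.columns:
        if not matrix["seed_id"].equals(seeds["seed_id"]):
            raise PipelineDataError("metabolome and seed table rows do not match by seed_id")
        matrix = matrix.drop(columns="seed_id")
    elif len(matrix) != len(seeds):
        raise PipelineDataError(
            f"metabolome has {len(matrix)} rows but seed table has {len(seeds)}"
        )
    weights = seeds["weight_mg"].to_numpy(dtype=float)
    st = cfg.stats

    screen = univariate_screen(matrix, weights)
    scaled, scaling = uv_scale(matrix)
    model = opls_fit(scaled, weights, n_ortho=st.n_ortho, folds=st.folds, cv_seed=cfg.rng_seed)
    volcano = volcano_table(screen, model.loadings_frame(), alpha=st.alpha, m=None)

    candidates = prefilter_top_univariate(matrix, weights, k=min(st.top_k, matrix.shape[1]))
    models, per_var = best_subset(matrix[candidates], weights,
                                  nvmax=min(st.nvmax, len(candidates)), nbest=st.nbest)

    score_matrix = np.column_stack([model.scores_pred, model.ortho_scores])
    labels = cluster_scores(score_matrix, k=min(st.n_clusters, len(seeds)))
    predicted = opls_predict(model, scaled)

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volcano": outdir / "volcano.tsv",
        "subsets": outdir / "subsets.tsv",
        "subset_variables": outdir / "subset_variables.tsv",
        "scores": outdir / "scores.tsv",
        "loadings": outdir / "loadings.tsv",
        "clusters": outdir / "clusters.tsv",
        "predicted": outdir / "predicted_weight.tsv",
        "summary": outdir / "model_summary.json",
    }
    volcano.to_csv(paths["volcano"], sep="\t", index=False)
    subsets_to_frame(models).to_csv(paths["subsets"], sep="\t", index=False)
    per_var.to_csv(paths["subset_variables"], sep="\t", index=False)
    scores = pd.DataFrame({"seed_id": seeds["seed_id"], "t_pred": model.scores_pred})
    for j in range(model.n_ortho):
        scores[f"t_ortho{j + 1}"] = model.ortho_scores[:, j]
    scores.to_csv(paths["scores"], sep="\t", index=False)
    model.loadings_frame().to_csv(paths["loadings"], sep="\t", index=False)
    pd.DataFrame({"seed_id": seeds["seed_id"], "cluster": labels}).to_csv(
        paths["clusters"], sep="\t", index=False)
    pd.DataFrame({"seed_id": seeds["seed_id"], "observed_weight_mg": weights,
                  "predicted_weight_mg": predicted}).to_csv(
        paths["predicted"], sep="\t", index=False)

    obs_vs_pred = fit_linear(predicted, weights)
    paths["summary"].write_text(json.dumps({
        "n_seeds": len(seeds),
        "n_analytes": int(matrix.shape[1]),
        "n_dropped_constant": len(scaling.dropped),
        "r2y": model.r_squared,
        "q2": model.q_squared,
        "p_cv_anova": model.p_cv_anova,
        "n_ortho": model.n_ortho,
        "folds": model.folds,
        "observed_vs_predicted_r2": obs_vs_pred.r_squared,
        "n_bonferroni_hits": int(volcano["passes_bonferroni"].sum()),
        "rng_seed": cfg.rng_seed,
    }, indent=2) + "\n")
    return paths


def run_all(cfg: PipelineConfig, outdir: Path | None = None) -> dict[str, Path]:
    """simulate → compose → isotope → stats in one deterministic pass."""
    outdir = Path(outdir or cfg.output_dir)
    paths = run_simulate(cfg, outdir)
    run_compose(paths["seeds"], cfg, outdir / "biochem.csv")
    paths["biochem"] = outdir / "biochem.csv"
    paths.update(run_isotope(paths["seeds"], paths["biochem"], cfg, outdir))
    paths.update(run_stats(paths["metabolome"], paths["seeds"], cfg, outdir))
    write_manifest(outdir, _config_echo(cfg), {k: v for k, v in paths.items() if v.is_file()})
    return paths
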