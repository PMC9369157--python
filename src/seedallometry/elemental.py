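"""Elemental-to-biochemical composition mass balance.

Whole-seed CHNS elemental analysis gives mass fractions of carbon,
nitrogen, sulfur and hydrogen.  After correcting for residual
non-extractable water and minerals, these four observations are inverted
against reference elemental compositions of four seed components
(carbohydrate, sulfur-rich albumin-type protein, sulfur-poor protein and
other nitrogenous compounds, lipid) by nonnegative least squares.  The
resulting component fractions feed the hydrogen-isotope mass balance via
the lipid hydrogen mole fraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

#: Canonical element order used throughout.
ELEMENTS = ("C", "N", "S", "H")

#: Canonical component order used throughout.
COMPONENTS = ("carbohydrate", "albumin", "s_poor_protein_other", "lipid")


class CompositionError(ValueError):
    """Raised when a composition violates mass-balance constraints."""


class ConfigurationError(ValueError):
    """Raised when a policy or reference matrix is invalid."""


@dataclass(frozen=True)
class ElementalComposition:
    """Mass fractions of C, N, S and H (dimensionless, on [0, 1]).

    File I/O uses percent by weight; conversion happens at the boundary
    (:func:`read_seed_table` / :func:`write_seed_table`).  Oxygen and any
    other elements are the unmeasured remainder, so the four fractions
    need not sum to one — but they may not exceed it.
    """

    c: float
    n: float
    s: float
    h: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < 0):
            raise CompositionError(f"negative elemental fraction in {self}")
        if vec.sum() > 1.0 + 1e-9:
            raise CompositionError(
                f"elemental fractions sum to {vec.sum():.4f} > 1 in {self}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.n, self.s, self.h], dtype=float)

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ElementalComposition":
        return cls(*(float(v) for v in vec))

    @classmethod
    def from_percent(cls, c: float, n: float, s: float, h: float) -> "ElementalComposition":
        return cls(c / 100.0, n / 100.0, s / 100.0, h / 100.0)


@dataclass(frozen=True)
class CorrectionPolicy:
    """Correction for residual non-extractable seed water and minerals.

    Raw elemental fractions refer to whole dry-seed weight, which still
    contains bound water (default 11%) and minerals (default 4%) that are
    not part of the four organic components.  Dividing by
    ``1 - water_fraction - mineral_fraction`` (default 0.85) rescales the
    fractions onto the organic matter only.
    """

    water_fraction: float = 0.11
    mineral_fraction: float = 0.04

    def __post_init__(self) -> None:
        if self.water_fraction < 0 or self.mineral_fraction < 0:
            raise ConfigurationError("water/mineral fractions must be >= 0")
        if self.water_fraction + self.mineral_fraction >= 1.0:
            raise ConfigurationError(
                f"water_fraction + mineral_fraction = "
                f"{self.water_fraction + self.mineral_fraction} leaves no organic matter"
            )

    @property
    def divisor(self) -> float:
        return 1.0 - self.water_fraction - self.mineral_fraction


class ComponentReferenceMatrix:
    """Reference elemental weight fractions of the four seed components.

    Rows are components (carbohydrate, albumin, s_poor_protein_other,
    lipid), columns are elements (C, N, S, H).  Defaults correspond to
    starch, a sulfur-rich albumin, sulfur-poor storage proteins
    (vicilin/legumin type) and fatty acids.
    """

    DEFAULT = np.array(
        [
            # C      N      S      H
            [0.400, 0.000, 0.000, 0.066],  # carbohydrate (starch)
            [0.505, 0.187, 0.027, 0.069],  # albumin (S-rich protein)
            [0.519, 0.194, 0.001, 0.068],  # S-poor proteins + other N compounds
            [0.760, 0.000, 0.000, 0.120],  # lipid (fatty acids)
        ]
    )

    def __init__(self, matrix: np.ndarray | None = None):
        m = self.DEFAULT.copy() if matrix is None else np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ConfigurationError(f"reference matrix must be 4x4, got {m.shape}")
        if np.any(m < 0) or np.any(m > 1):
            raise ConfigurationError("reference entries must be mass fractions in [0, 1]")
        if np.linalg.matrix_rank(m) < 4:
            raise ConfigurationError("reference matrix is rank-deficient")
        self.matrix = m

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComponentReferenceMatrix":
        """Load from a CSV with columns component, C, N, S, H."""
        df = pd.read_csv(path)
        missing = {"component", *ELEMENTS} - set(df.columns)
        if missing:
            raise ConfigurationError(f"reference CSV missing columns: {sorted(missing)}")
        df = df.set_index("component")
        try:
            df = df.loc[list(COMPONENTS)]
        except KeyError as exc:
            raise ConfigurationError(f"reference CSV missing component row: {exc}") from exc
        return cls(df[list(ELEMENTS)].to_numpy())

    @classmethod
    def default_csv_path(cls) -> Path:
        """Path of the packaged default reference CSV."""
        return Path(resources.files("seedallometry") / "data" / "component_reference.csv")

    def h_column(self) -> np.ndarray:
        return self.matrix[:, ELEMENTS.index("H")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(COMPONENTS), columns=list(ELEMENTS))


@dataclass(frozen=True)
class BiochemicalComposition:
    """Component mass fractions with per-element fitting residuals.

    ``total`` is reported, never forced: the four observations determine
    four unknowns, and constraining the sum would over-determine the
    system.  A total far from 1 flags data inconsistent with the mixing
    model.
    """

    w_carb: float
    w_alb: float
    w_spp: float
    w_lip: float
    residual: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        if min(self.w_carb, self.w_alb, self.w_spp, self.w_lip) < 0:
            raise CompositionError(f"negative component fraction in {self}")
        if np.any(np.asarray(self.residual) < -1e-12):
            raise CompositionError("residuals must be nonnegative magnitudes")

    @property
    def total(self) -> float:
        return self.w_carb + self.w_alb + self.w_spp + self.w_lip

    def as_array(self) -> np.ndarray:
        return np.array([self.w_carb, self.w_alb, self.w_spp, self.w_lip], dtype=float)

    @classmethod
    def from_array(cls, vec: np.ndarray, residual: np.ndarray | None = None) -> "BiochemicalComposition":
        res = np.zeros(4) if residual is None else np.asarray(residual, dtype=float)
        return cls(*(float(v) for v in vec), residual=res)


def correct_composition(
    raw: ElementalComposition,
    policy: CorrectionPolicy = CorrectionPolicy(),
    seed_id: str | None = None,
) -> ElementalComposition:
    """Rescale raw elemental fractions onto the organic-matter basis.

    Divides each element by ``policy.divisor`` (default 0.85).  Raises a
    :class:`CompositionError` naming ``seed_id`` if the corrected
    fractions exceed a total of one, which indicates measurements
    inconsistent with the assumed water/mineral content.
    """
    corrected = raw.as_array() / policy.divisor
    if corrected.sum() > 1.0 + 1e-9:
        who = f" (seed {seed_id})" if seed_id else ""
        raise CompositionError(
            f"corrected elemental fractions sum to {corrected.sum():.4f} > 1{who}"
        )
    return ElementalComposition.from_array(corrected)


def forward_composition(
    biochem: BiochemicalComposition | np.ndarray,
    ref: ComponentReferenceMatrix | None = None,
) -> ElementalComposition:
    """Linear mixing model: component fractions -> elemental fractions.

    Each element is the component-fraction-weighted sum of the reference
    elemental weight fractions.  This is the forward counterpart of
    :func:`invert_composition`, used by the cohort generator and for
    round-trip validation.
    """
    ref = ref or ComponentReferenceMatrix()
    w = biochem.as_array() if isinstance(biochem, BiochemicalComposition) else np.asarray(biochem, dtype=float)
    if np.any(w < 0):
        raise CompositionError("component fractions must be nonnegative")
    return ElementalComposition.from_array(w @ ref.matrix)


def invert_composition(
    corrected: ElementalComposition,
    ref: ComponentReferenceMatrix | None = None,
    warn_total_outside: tuple[float, float] = (0.90, 1.10),
) -> BiochemicalComposition:
    """Recover component fractions from corrected elemental fractions.

    Solves ``min || M' w - e ||^2`` subject to ``w >= 0`` where ``M`` is
    the component reference matrix and ``e`` the observed (corrected)
    elemental vector, using an exact active-set nonnegative least-squares
    solve — deterministic, with no random initialisation.  The per-element
    residual magnitudes are reported alongside the fractions.  The sum of
    fractions is not constrained; a warning is emitted when the total
    falls outside ``warn_total_outside``.
    """
    ref = ref or ComponentReferenceMatrix()
    e = corrected.as_array()
    # nnls solves A x = b with A = M^T (elements x components)
    w, _ = nnls(ref.matrix.T, e)
    residual = np.abs(w @ ref.matrix - e)
    result = BiochemicalComposition.from_array(w, residual)
    lo, hi = warn_total_outside
    if not lo <= result.total <= hi and e.sum() > 0:
        warnings.warn(
            f"component fractions sum to {result.total:.3f}, outside [{lo}, {hi}]; "
            "elemental data may be inconsistent with the mixing model",
            stacklevel=2,
        )
    return result


def lipid_h_mole_fraction(
    biochem: BiochemicalComposition,
    ref: ComponentReferenceMatrix | None = None,
) -> float:
    """Share of the seed's hydrogen contributed by the lipid component.

    Hydrogen mass is proportional to hydrogen moles, so the mole fraction
    equals ``w_lip * H_lip / sum_k w_k * H_k`` with the H column of the
    reference matrix.  Undefined (raises) when all fractions are zero.
    """
    ref = ref or ComponentReferenceMatrix()
    w = biochem.as_array()
    h = ref.h_column()
    denom = float(w @ h)
    if denom <= 0:
        raise CompositionError("lipid H mole fraction undefined: no hydrogen-bearing mass")
    x = float(w[COMPONENTS.index("lipid")] * h[COMPONENTS.index("lipid")]) / denom
    return x


# ---------------------------------------------------------------------------
# Per-seed table I/O (percent units in files, fractions in memory)
# ---------------------------------------------------------------------------

SEED_TABLE_COLUMNS = [
    "seed_id", "accession", "weight_mg", "pct_C", "pct_N", "pct_S", "pct_H",
]


def read_seed_table(path: str | Path) -> pd.DataFrame:
    """Read a per-seed elemental CSV (named columns, percent units)."""
    df = pd.read_csv(path)
    missing = set(SEED_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise CompositionError(f"seed table {path} missing columns: {sorted(missing)}")
    return df


def compose_table(
    seeds: pd.DataFrame,
    policy: CorrectionPolicy = CorrectionPolicy(),
    ref: ComponentReferenceMatrix | None = None,
) -> pd.DataFrame:
    """Run correct -> invert -> lipid H mole fraction over a seed table.

    Returns one row per seed with component mass fractions, the summed
    fraction total, per-element residuals and the lipid H mole fraction.
    """
    ref = ref or ComponentReferenceMatrix()
    rows = []
    for rec in seeds.itertuples(index=False):
        raw = ElementalComposition.from_percent(rec.pct_C, rec.pct_N, rec.pct_S, rec.pct_H)
        corrected = correct_composition(raw, policy, seed_id=str(rec.seed_id))
        biochem = invert_composition(corrected, ref)
        rows.append(
            {
                "seed_id": rec.seed_id,
                "accession": rec.accession,
                "weight_mg": rec.weight_mg,
                "w_carb": biochem.w_carb,
                "w_alb": biochem.w_alb,
                "w_spp": biochem.w_spp,
                "w_lip": biochem.w_lip,
                "total": biochem.total,
                "resid_C": biochem.residual[0],
                "resid_N": biochem.residual[1],
                "resid_S": biochem.residual[2],
                "resid_H": biochem.residual[3],
                "lipid_h_mole_fraction": lipid_h_mole_fraction(biochem, ref),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seed_id", "accession", "weight_mg", "w_carb", "w_alb", "w_spp",
            "w_lip", "total", "resid_C", "resid_N", "resid_S", "resid_H",
            "lipid_h_mole_fraction",
        ],
    )
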