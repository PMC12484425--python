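"""Model design matrix: standardized covariates with quadratic terms.

Column layout (20 columns):
  intercept (1)
  habitat block (10): four class proportions, each linear + quadratic,
      plus clumpiness and entropy as linear-only terms
  climate block (8): four climate covariates, each linear + quadratic
  effort (1): log trap-days, linear

Quadratic columns are squares of the standardized linear columns.
Standardization statistics are estimated on the training (sampled) units
and frozen; prediction-grid matrices reuse them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariates receiving a quadratic term.
QUADRATIC = (
    "hab_prop_broadleaf",
    "hab_prop_conifer",
    "hab_prop_mixed",
    "hab_prop_seminatural",
    "clim_gdd",
    "clim_cdd",
    "clim_snow",
    "clim_precip",
)
#: Linear-only covariates (no optimum is biologically plausible for
#: fragmentation/diversity; effort is an offset-like adjustment).
LINEAR_ONLY = ("hab_clumpiness", "hab_entropy", "effort_logdays")

FEATURE_COLUMNS = (
    "hab_prop_broadleaf",
    "hab_prop_conifer",
    "hab_prop_mixed",
    "hab_prop_seminatural",
    "hab_clumpiness",
    "hab_entropy",
    "clim_gdd",
    "clim_cdd",
    "clim_snow",
    "clim_precip",
    "effort_logdays",
)


def _column_layout() -> tuple[list[str], dict[str, list[int]]]:
    names = ["intercept"]
    blocks: dict[str, list[int]] = {
        "intercept": [0],
        "habitat": [],
        "climate": [],
        "effort": [],
    }
    for feat in FEATURE_COLUMNS:
        block = (
            "habitat"
            if feat.startswith("hab_")
            else "climate" if feat.startswith("clim_") else "effort"
        )
        blocks[block].append(len(names))
        names.append(feat)
        if feat in QUADRATIC:
            blocks[block].append(len(names))
            names.append(feat + "_sq")
    return names, blocks


COLUMN_NAMES, BLOCKS = _column_layout()
N_COLUMNS = len(COLUMN_NAMES)  # 20


@dataclass
class DesignMatrix:
    """Standardized design matrix with block structure.

    Attributes
    ----------
    X : (n_units, 20) float array
    colnames : column names in order
    blocks : mapping block name -> column indices
    stats : per-feature (mean, sd) used for standardization
    units : identifier frame aligned with rows (e.g. site/cell, year)
    """

    X: np.ndarray
    colnames: list[str] = field(default_factory=lambda: list(COLUMN_NAMES))
    blocks: dict[str, list[int]] = field(
        default_factory=lambda: {k: list(v) for k, v in BLOCKS.items()}
    )
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    units: pd.DataFrame | None = None

    @property
    def n_units(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.colnames.index(name)]


def build_design_matrix(
    features: pd.DataFrame,
    standardization_stats: dict[str, tuple[float, float]] | None = None,
    unit_columns: tuple[str, ...] = (),
) -> DesignMatrix:
    """Build the 20-column design matrix from a per-unit feature table.

    ``features`` must contain every name in :data:`FEATURE_COLUMNS`.
    Missing values (e.g. undefined clumpiness) are excluded from the
    standardization statistics with a warning and propagate as NaN rows.
    When ``standardization_stats`` is given (a prediction set), it is used
    unchanged, making construction idempotent given frozen stats.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    n = len(features)
    if n == 0:
        raise ValueError("empty feature table")

    if standardization_stats is None:
        stats = {}
        for c in FEATURE_COLUMNS:
            vals = features[c].to_numpy(dtype=float)
            if np.isnan(vals).any():
                warnings.warn(
                    f"{int(np.isnan(vals).sum())} units with undefined {c} "
                    "excluded from standardization",
                    stacklevel=2,
                )
            mu = float(np.nanmean(vals))
            sd = float(np.nanstd(vals))
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(f"zero-variance covariate: {c}")
            stats[c] = (mu, sd)
    else:
        stats = dict(standardization_stats)

    X = np.empty((n, N_COLUMNS))
    X[:, 0] = 1.0
    for c in FEATURE_COLUMNS:
        mu, sd = stats[c]
        z = (features[c].to_numpy(dtype=float) - mu) / sd
        X[:, COLUMN_NAMES.index(c)] = z
        if c in QUADRATIC:
            X[:, COLUMN_NAMES.index(c + "_sq")] = z * z

    units = features[list(unit_columns)].copy() if unit_columns else None
    return DesignMatrix(X=X, stats=stats, units=units)
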