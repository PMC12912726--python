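"""Body proportions, encephalization quotient, and brain-body allometry.

Eight intrinsic body proportions are computed from raw linear
measurements (all in one common length unit): relative tail, forelimb
and hindlimb lengths (% of body length), the intermembral index
(forelimb without hand / hindlimb without foot, x100), relative hand and
foot lengths (% of the limb without its autopod), and relative pollex
and hallux lengths (% of hand and foot length).

The encephalization quotient (EQ) is the observed brain mass divided by
the brain mass expected from a reference brain-body allometry
``E[brain] = c * body**b`` (Jerison form, c = 0.12 g, b = 2/3 by
default); EQ > 1 means a heavier brain than expected for the body mass.
Endocranial volume converts to brain mass at 1.0 g/cm^3 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RAW_LENGTHS",
    "PROPORTION_COLUMNS",
    "compute_body_proportions",
    "brain_mass_from_ecv",
    "encephalization_quotient",
    "MajorAxisFit",
    "major_axis_fit",
    "read_morphology_table",
    "morphology_profiles",
]

RAW_LENGTHS = [
    "body_length", "tail_length", "forelimb_length", "hindlimb_length",
    "hand_length", "foot_length", "pollex_length", "hallux_length",
]

PROPORTION_COLUMNS = [
    "pct_tail_body", "pct_forelimb_body", "pct_hindlimb_body", "intermembral_index",
    "pct_hand_forelimb", "pct_foot_hindlimb", "pct_pollex_hand", "pct_hallux_foot",
]


def _ratio(num: float, den: float, what: str) -> float:
    if np.isnan(num) or np.isnan(den):
        return float("nan")
    if den <= 0:
        raise ValueError(f"non-positive denominator computing {what}")
    return 100.0 * num / den


def compute_body_proportions(lengths: dict[str, float] | pd.Series) -> dict[str, float]:
    """The eight body proportions from raw lengths; NaN where inputs are missing.

    Raw lengths must share one unit; every ratio is scale-invariant.
    """
    g = {k: float(lengths.get(k, np.nan)) for k in RAW_LENGTHS}
    for k, v in g.items():
        if not np.isnan(v) and v <= 0:
            raise ValueError(f"raw length {k} must be positive, got {v}")
    fore_wo_hand = g["forelimb_length"] - g["hand_length"]
    hind_wo_foot = g["hindlimb_length"] - g["foot_length"]
    return {
        "pct_tail_body": _ratio(g["tail_length"], g["body_length"], "tail/body"),
        "pct_forelimb_body": _ratio(g["forelimb_length"], g["body_length"], "forelimb/body"),
        "pct_hindlimb_body": _ratio(g["hindlimb_length"], g["body_length"], "hindlimb/body"),
        "intermembral_index": _ratio(fore_wo_hand, hind_wo_foot, "intermembral index"),
        "pct_hand_forelimb": _ratio(g["hand_length"], fore_wo_hand, "hand/forelimb"),
        "pct_foot_hindlimb": _ratio(g["foot_length"], hind_wo_foot, "foot/hindlimb"),
        "pct_pollex_hand": _ratio(g["pollex_length"], g["hand_length"], "pollex/hand"),
        "pct_hallux_foot": _ratio(g["hallux_length"], g["foot_length"], "hallux/foot"),
    }


def brain_mass_from_ecv(ecv_cm3: float, density_g_cm3: float = 1.0) -> float:
    """Brain mass (g) from endocranial volume (cm^3) at the given density."""
    if ecv_cm3 <= 0 or density_g_cm3 <= 0:
        raise ValueError("endocranial volume and density must be positive")
    return ecv_cm3 * density_g_cm3


def encephalization_quotient(
    brain_mass_g: float, body_mass_g: float, coef: float = 0.12, exponent: float = 2.0 / 3.0
) -> float:
    """EQ = brain mass / (coef * body_mass**exponent); dimensionless."""
    if brain_mass_g <= 0 or body_mass_g <= 0:
        raise ValueError("brain and body mass must be positive")
    return brain_mass_g / (coef * body_mass_g ** exponent)


@dataclass(frozen=True)
class MajorAxisFit:
    """Major-axis (orthogonal) regression summary on log scale."""

    slope: float
    intercept: float
    r2: float
    r: float
    df: int
    p: float


def major_axis_fit(log_x, log_y) -> MajorAxisFit:
    """Major-axis orthogonal regression of ``log_y`` on ``log_x``.

    The slope is the direction of the first principal axis of the 2x2
    covariance matrix; significance is the two-sided Pearson correlation
    test with n - 2 degrees of freedom.
    """
    x = np.asarray(log_x, dtype=float)
    y = np.asarray(log_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("major axis fit needs two equal-length 1-d arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in major axis fit")
    cov = np.cov(x, y)
    if cov[0, 0] <= 0 or cov[1, 1] <= 0:
        raise ValueError("zero variance on an axis; slope undefined")
    # largest-eigenvalue eigenvector of the covariance matrix, closed form
    sxx, syy, sxy = cov[0, 0], cov[1, 1], cov[0, 1]
    lam = 0.5 * (sxx + syy + np.hypot(sxx - syy, 2.0 * sxy))
    if sxy == 0 and sxx >= syy:
        slope = 0.0
    else:
        slope = (lam - sxx) / sxy if sxy != 0 else np.inf
    intercept = float(np.mean(y) - slope * np.mean(x))
    r, p = stats.pearsonr(x, y)
    return MajorAxisFit(float(slope), intercept, float(r**2), float(r), x.size - 2, float(p))


# ---------------------------------------------------------------------------
# delimited-text I/O

MASS_COLUMNS = ["body_mass_g", "ecv_cm3"]


def read_morphology_table(path: str | Path) -> pd.DataFrame:
    """One row per taxon; NA-coded missing cells (fossil rows); indexed by species."""
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("morphology table needs a 'species' column")
    return df.set_index("species")


def morphology_profiles(
    table: pd.DataFrame, eq_coef: float = 0.12, eq_exponent: float = 2.0 / 3.0
) -> pd.DataFrame:
    """Per-taxon morphological profile: masses, EQ, and the eight proportions.

    Missing raw cells propagate to NaN ratios (fossil rows stay partially
    observed rather than erroring out).
    """
    out = {}
    for species, row in table.iterrows():
        profile = compute_body_proportions(row)
        profile["body_mass_g"] = float(row.get("body_mass_g", np.nan))
        ecv = float(row.get("ecv_cm3", np.nan))
        profile["ecv_cm3"] = ecv
        if np.isnan(ecv) or np.isnan(profile["body_mass_g"]):
            profile["eq"] = float("nan")
        else:
            profile["eq"] = encephalization_quotient(
                brain_mass_from_ecv(ecv), profile["body_mass_g"], eq_coef, eq_exponent
            )
        out[species] = profile
    cols = ["body_mass_g", "ecv_cm3", "eq"] + PROPORTION_COLUMNS
    return pd.DataFrame(out).T[cols].rename_axis("species")
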