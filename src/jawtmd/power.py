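"""z-score normalisation, two-group sample-size formula and the per-feature
bootstrap distinguishability study.

The sample-size formula for detecting a difference between two group means
with a two-sided test at level α and power 1−β is

    n = 2 (z_α + z_β)² σ² / (μ₁ − μ₂)²

per group, with z_α = 1.96 (α = 0.05, two-tailed) and z_β = 0.84 (80% power)
by default. Applied feature-by-feature to a small pilot cohort, with group
means and SDs stabilised by bootstrap, it flags which features cannot
distinguish a given group pair at a practical cohort size.

SD convention: the n−1 (sample) denominator is used everywhere in this
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "NormalizationParams",
    "zscore_fit",
    "zscore_apply",
    "required_n",
    "feature_power_table",
    "GROUP_PAIRS",
]

GROUP_PAIRS = (("CG", "AG"), ("CG", "MG"), ("AG", "MG"))

Z_ALPHA = 1.96  # two-tailed, alpha = 0.05
Z_BETA = 0.84  # power 80%


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean and SD (n−1 convention) used for z-scoring."""

    mean: pd.Series
    std: pd.Series


def _feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    if not cols:  # plain numeric matrix: use all columns
        return table
    return table.loc[:, cols]


def zscore_fit(table: pd.DataFrame) -> NormalizationParams:
    """Fit per-feature z-score parameters on a feature table.

    Raises ``ValueError`` naming the feature if any column is constant
    (zero variance makes the z-score undefined).
    """
    feats = _feature_frame(table)
    if len(feats) < 2:
        raise ValueError("need at least 2 rows to fit z-score parameters")
    mean = feats.mean()
    std = feats.std(ddof=1)
    zero = std.index[std == 0].tolist()
    if zero:
        raise ValueError(f"zero variance: {', '.join(zero)}")
    return NormalizationParams(mean=mean, std=std)


def zscore_apply(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Standardise the feature columns; non-feature columns pass through."""
    out = table.copy()
    for col in params.mean.index:
        out[col] = (out[col] - params.mean[col]) / params.std[col]
    return out


def required_n(
    sigma: float,
    mu1: float,
    mu2: float,
    z_alpha: float = Z_ALPHA,
    z_beta: float = Z_BETA,
) -> int:
    """Per-group sample size to distinguish two means, rounded up, minimum 2.

    Raises ``ValueError`` when the means are equal (no finite sample size can
    distinguish identical means).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if mu1 == mu2:
        raise ValueError("infeasible: equal group means")
    raw = 2.0 * ((z_alpha + z_beta) ** 2 * sigma**2) / (mu1 - mu2) ** 2
    return max(2, math.ceil(raw))


def feature_power_table(
    pilot: pd.DataFrame,
    n_boot: int = 1000,
    threshold: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature, per-group-pair required sample sizes from a pilot cohort.

    Subjects of each group are resampled with replacement ``n_boot`` times;
    each feature's group mean and SD are taken as the average of the
    bootstrap replicates' sample means and sample SDs. The two group SDs are
    pooled as their root mean square (the equal-variance assumption behind
    the sample-size formula), and the required n computed per pair. Rows
    where it exceeds ``threshold`` are flagged; pairs with exactly equal
    bootstrap means are marked infeasible.

    Returns a long-format DataFrame with columns
    ``feature, pair, required_n, exceeds_threshold, infeasible``.
    """
    if "group" not in pilot.columns:
        raise ValueError("pilot table needs a 'group' column")
    present = set(pilot["group"])
    pairs = [p for p in GROUP_PAIRS if set(p) <= present]
    if not pairs:
        raise ValueError("pilot table needs at least two of the groups CG/MG/AG")
    feats = _feature_frame(pilot)
    rng = np.random.default_rng(seed)

    boot_stats: dict[str, tuple[pd.Series, pd.Series]] = {}
    for group in sorted({g for pair in pairs for g in pair}):
        members = feats[pilot["group"] == group]
        n_g = len(members)
        if n_g < 2:
            raise ValueError(f"group {group} has {n_g} subjects (need >= 2)")
        values = members.to_numpy(float)  # (n_g, n_features)
        idx = rng.integers(0, n_g, size=(n_boot, n_g))
        draws = values[idx]  # (n_boot, n_g, n_features)
        boot_means = draws.mean(axis=1)
        boot_sds = draws.std(axis=1, ddof=1)
        boot_stats[group] = (
            pd.Series(boot_means.mean(axis=0), index=feats.columns),
            pd.Series(boot_sds.mean(axis=0), index=feats.columns),
        )

    rows = []
    for feature in feats.columns:
        for g1, g2 in pairs:
            mu1, sd1 = boot_stats[g1][0][feature], boot_stats[g1][1][feature]
            mu2, sd2 = boot_stats[g2][0][feature], boot_stats[g2][1][feature]
            sigma = math.sqrt((sd1**2 + sd2**2) / 2.0)
            if mu1 == mu2:
                n, infeasible = math.nan, True
            elif sigma == 0:  # distinct constant groups: any two subjects suffice
                n, infeasible = 2, False
            else:
                n, infeasible = required_n(sigma, mu1, mu2), False
            rows.append(
                {
                    "feature": feature,
                    "pair": f"{g1}-{g2}",
                    "required_n": n,
                    "exceeds_threshold": (not infeasible) and n > threshold,
                    "infeasible": infeasible,
                }
            )
    return pd.DataFrame(rows)
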