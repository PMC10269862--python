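"""Motility-halo analysis: mixed-effects genotype test and Dunnett contrasts.

Halo diameters from soft-agar plates are modelled with a random intercept
per batch (plate/replicate) and genotype as a fixed effect; the genotype
effect is a Wald chi-square over the genotype coefficients.  When the
batch variance estimates at (or collapses to) zero, the model reduces to
one-way fixed-effects ANOVA and the result says so.  Each mutant is then
compared with the wild-type control by Dunnett's many-to-one procedure,
whose familywise-adjusted p-values come from the equicorrelated
multivariate t distribution (evaluated numerically with a fixed seed, so
results are reproducible to the integration tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

HALO_COLUMNS = ["strain", "batch", "diameter_mm"]


@dataclass
class HaloModelResult:
    """Genotype-effect test from the halo model."""

    statistic: float
    df: int
    p: float
    method: str  # "mixed" or "anova"
    batch_variance: float


def _validate_halo(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = set(HALO_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"halo table missing columns: {sorted(missing)}")
    if (measurements["diameter_mm"] <= 0).any():
        raise ValueError("diameters must be positive")
    if measurements["strain"].nunique() < 2:
        raise ValueError("need at least two strains")
    counts = measurements.groupby("strain").size()
    if (counts < 2).any():
        raise ValueError("every strain needs at least two measurements")
    return measurements


def fit_halo_model(measurements: pd.DataFrame) -> HaloModelResult:
    """Test for a genotype effect on halo diameter.

    Fits diameter ~ genotype with a random intercept per batch and returns
    a Wald chi-square over the genotype coefficients.  Falls back to
    one-way ANOVA (statistic F, numerator df reported) with a warning when
    the batch variance estimates at zero or the mixed fit fails.
    """
    df = _validate_halo(measurements)
    k = df["strain"].nunique()
    if np.allclose(df["diameter_mm"], df["diameter_mm"].iloc[0]):
        return HaloModelResult(0.0, k - 1, 1.0, "anova", 0.0)

    import statsmodels.formula.api as smf

    mixed_ok = df["batch"].nunique() >= 2
    if mixed_ok:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm(
                    "diameter_mm ~ C(strain)", df, groups=df["batch"]
                ).fit(reml=True)
                batch_var = float(fit.cov_re.iloc[0, 0])
            except Exception:
                fit, batch_var = None, 0.0
        if fit is not None and batch_var > 1e-10:
            names = [n for n in fit.params.index if n.startswith("C(strain)")]
            idx = [list(fit.params.index).index(n) for n in names]
            beta = fit.params.iloc[idx].to_numpy()
            cov = fit.cov_params().iloc[idx, idx].to_numpy()
            stat = float(beta @ np.linalg.solve(cov, beta))
            p = float(_sps.chi2.sf(stat, len(names)))
            return HaloModelResult(stat, len(names), p, "mixed", batch_var)

    warnings.warn(
        "batch variance at zero; falling back to one-way ANOVA", stacklevel=2
    )
    groups = [g["diameter_mm"].to_numpy(float) for _, g in df.groupby("strain")]
    f_stat, p = _sps.f_oneway(*groups)
    return HaloModelResult(float(f_stat), k - 1, float(p), "anova", 0.0)


def dunnett_vs_control(
    measurements: pd.DataFrame,
    control: str,
    *,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of each mutant against the control.

    Adjusted p-values use the equicorrelated multivariate t reference
    (seeded, hence reproducible).  ``flagged`` marks mutants whose mean
    diameter differs from the control at familywise level ``alpha``.
    """
    df = _validate_halo(measurements)
    strains = sorted(df["strain"].unique())
    if control not in strains:
        raise ValueError(f"control strain {control!r} missing")
    mutants = [s for s in strains if s != control]
    samples = [df.loc[df["strain"] == s, "diameter_mm"].to_numpy(float) for s in mutants]
    control_values = df.loc[df["strain"] == control, "diameter_mm"].to_numpy(float)
    res = _sps.dunnett(
        *samples,
        control=control_values,
        alternative="two-sided",
        rng=np.random.default_rng(seed),
    )
    control_mean = float(control_values.mean())
    rows = []
    for strain, sample, stat, p in zip(
        mutants, samples, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    ):
        rows.append(
            {
                "strain": strain,
                "n": len(sample),
                "mean_diameter": float(sample.mean()),
                "contrast": float(sample.mean() - control_mean),
                "statistic": float(stat),
                "adjusted_p": float(p),
                "flagged": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
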