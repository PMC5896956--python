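"""Saturation radioligand-binding analysis: K_D and Bmax estimation.

A saturation binding assay measures bound radioligand (scintillation
counts) across a ladder of ligand concentrations.  Total binding at
concentration ``c`` is modelled as

    total(c) = Bmax * c / (K_D + c) + ns * c

where the first term is specific binding to the receptor (a rectangular
hyperbola with half-saturation at ``c = K_D`` and plateau ``Bmax``) and
the second is a linear nonspecific component, measured directly in paired
wells containing a saturating unlabelled competitor.  Specific binding is
obtained by subtracting the nonspecific wells from the total wells, and
``B(c) = Bmax*c/(K_D + c)`` is fitted by nonlinear least squares.

Replicate experiments run under two conditions (e.g. vehicle vs drug) are
compared with a paired two-tailed t test on the per-replicate parameter
estimates, reporting the percent change in mean Bmax (a receptor-number
proxy) and in K_D (affinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import DegenerateInputError

#: Concentration ladder (nM) used by the CFT saturation assays this
#: package was built around; the generator's default.
DEFAULT_CONCENTRATIONS_NM = (4.12, 7.25, 13.5, 26.0, 51.0, 101.0)


@dataclass
class BindingDataset:
    """Saturation-binding count data for one condition.

    ``points`` is a DataFrame with columns ``replicate``,
    ``concentration_nM``, ``total_counts``, ``nonspecific_counts``.
    """

    points: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"replicate", "concentration_nM", "total_counts", "nonspecific_counts"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"binding dataset missing columns {sorted(missing)}")
        conc = self.points["concentration_nM"].to_numpy(dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be > 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.unique(self.points["concentration_nM"].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "BindingDataset":
        df = pd.read_csv(path)
        if condition is not None:
            df = df[df["condition"] == condition]
        label = condition or (df["condition"].iloc[0] if "condition" in df else "")
        return cls(points=df.reset_index(drop=True), condition=str(label))


@dataclass
class SaturationFit:
    """Result of fitting B(c) = Bmax*c/(K_D + c) to specific binding."""

    kd: float                 # nM
    bmax: float               # counts (or fmol-equivalent units)
    kd_se: float
    bmax_se: float
    rss: float                # residual sum of squares
    converged: bool
    n_points: int = 0
    condition: str = ""
    replicate: object = None


def specific_binding(dataset: BindingDataset) -> pd.DataFrame:
    """Subtract nonspecific from total counts, replicate-matched.

    Every concentration must have a nonspecific pair.  Negative specific
    values are retained (clamping would bias the subsequent fit at low
    concentrations where total and nonspecific are comparable).

    Returns a DataFrame with columns ``replicate``, ``concentration_nM``,
    ``specific_counts``.
    """
    df = dataset.points
    if df["nonspecific_counts"].isna().any():
        bad = df.loc[df["nonspecific_counts"].isna(), "concentration_nM"].tolist()
        raise ValueError(f"concentrations without a nonspecific pair: {bad}")
    out = df[["replicate", "concentration_nM"]].copy()
    out["specific_counts"] = (
        df["total_counts"].to_numpy(dtype=float)
        - df["nonspecific_counts"].to_numpy(dtype=float)
    )
    return out


def _hyperbola(c, bmax, kd):
    return bmax * c / (kd + c)


def fit_saturation(
    specific: pd.DataFrame,
    weight_poisson: bool = False,
    max_iterations: int = 500,
) -> SaturationFit:
    """Fit the one-site saturation hyperbola to specific binding points.

    Initialisation: ``Bmax0`` is the maximum observed specific count and
    ``K_D0`` the concentration whose specific count is nearest Bmax0/2.
    Unweighted least squares by default (``weight_poisson=True`` weights by
    1/sqrt(max(specific,1)) for counting statistics).  Standard errors come
    from the Jacobian-based covariance at the optimum.
    """
    c = specific["concentration_nM"].to_numpy(dtype=float)
    b = specific["specific_counts"].to_numpy(dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations to fit")
    if np.all(b <= 0):
        raise DegenerateInputError("all specific counts are <= 0; nothing to fit")

    bmax0 = float(np.max(b))
    kd0 = float(c[np.argmin(np.abs(b - bmax0 / 2.0))])
    sigma = np.sqrt(np.maximum(b, 1.0)) if weight_poisson else None
    try:
        popt, pcov = optimize.curve_fit(
            _hyperbola,
            c,
            b,
            p0=[bmax0, kd0],
            sigma=sigma,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            maxfev=max_iterations * len(c),
        )
        converged = True
    except RuntimeError:
        popt = np.array([bmax0, kd0])
        pcov = np.full((2, 2), np.nan)
        converged = False

    bmax, kd = float(popt[0]), float(popt[1])
    resid = b - _hyperbola(c, bmax, kd)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.inf, np.inf])
    return SaturationFit(
        kd=kd,
        bmax=bmax,
        kd_se=float(se[1]),
        bmax_se=float(se[0]),
        rss=float(np.sum(resid**2)),
        converged=converged,
        n_points=len(c),
    )


def fit_dataset_by_replicate(dataset: BindingDataset, **kwargs) -> list[SaturationFit]:
    """Fit each replicate experiment separately (one fit per replicate)."""
    spec = specific_binding(dataset)
    fits = []
    for rep, grp in spec.groupby("replicate", sort=True):
        fit = fit_saturation(grp, **kwargs)
        fit.condition = dataset.condition
        fit.replicate = rep
        fits.append(fit)
    return fits


@dataclass
class BmaxComparison:
    percent_change_bmax: float
    p_bmax: float
    t_bmax: float
    percent_change_kd: float
    p_kd: float
    t_kd: float
    n_replicates: int = 0


def compare_bmax(fits_a: list[SaturationFit], fits_b: list[SaturationFit]) -> BmaxComparison:
    """Compare Bmax (and K_D) between two conditions across paired replicates.

    Replicates are paired positionally (the i-th fit of each condition came
    from the same experiment).  Percent change is
    ``100 * (mean_B - mean_A) / mean_A``; significance is a paired
    two-tailed t test on the per-replicate estimates.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("conditions must have equal, paired replicate counts")
    if len(fits_a) < 3:
        raise ValueError("need >= 3 paired replicates")
    bmax_a = np.array([f.bmax for f in fits_a])
    bmax_b = np.array([f.bmax for f in fits_b])
    kd_a = np.array([f.kd for f in fits_a])
    kd_b = np.array([f.kd for f in fits_b])

    def _pair(x, y):
        change = 100.0 * (np.mean(y) - np.mean(x)) / np.mean(x)
        if np.allclose(x, y):
            return float(change), 1.0, 0.0
        t, p = stats.ttest_rel(x, y)
        return float(change), float(p), float(t)

    cb, pb, tb = _pair(bmax_a, bmax_b)
    ck, pk, tk = _pair(kd_a, kd_b)
    return BmaxComparison(
        percent_change_bmax=cb, p_bmax=pb, t_bmax=tb,
        percent_change_kd=ck, p_kd=pk, t_kd=tk,
        n_replicates=len(fits_a),
    )


def fits_to_frame(fits: list[SaturationFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [f.condition for f in fits],
            "replicate": [f.replicate for f in fits],
            "kd_nM": [f.kd for f in fits],
            "kd_se": [f.kd_se for f in fits],
            "bmax": [f.bmax for f in fits],
            "bmax_se": [f.bmax_se for f in fits],
            "rss": [f.rss for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
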