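"""Relative gene copy number by the double-standard-curve qPCR method.

Each gene (the target ace-1 and the single-copy reference rps7) gets its
own standard curve fitted on a tenfold dilution series of a PCR product:
Cq is linear in log10 relative concentration with slope −1/log10(1+E),
E the amplification efficiency.  An unknown well's concentration is read
off its gene's own curve, and the sample's copy number is the ratio of
target to reference concentrations, averaged over replicate well pairs.
Because the reference gene is single-copy, the ratio is directly the
target copy number per haploid genome; no absolute calibration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CopyNumberEstimate",
    "fit_standard_curve",
    "concentration_from_cq",
    "copy_ratio",
    "estimates_from_plate",
    "population_copy_number",
]

#: Efficiency window outside which a fitted curve is flagged.
EFFICIENCY_BOUNDS = (0.0, 1.1)


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10 relative concentration for one gene."""

    gene: str
    slope: float  #: cycles per log10 concentration; < 0 for a valid curve
    intercept: float  #: Cq at relative concentration 1 (undiluted standard)
    r2: float
    n_levels: int

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(−1/slope) − 1 (1.0 = perfect
        doubling each cycle, slope −3.3219)."""
        return 10 ** (-1.0 / self.slope) - 1.0

    @property
    def is_valid(self) -> bool:
        lo, hi = EFFICIENCY_BOUNDS
        return self.slope < 0 and lo < self.efficiency <= hi


def fit_standard_curve(standards: pd.DataFrame, gene: str | None = None) -> StandardCurve:
    """Fit a standard curve from dilution-series wells.

    ``standards`` needs columns ``dilution_level`` (integer tenfold steps;
    level k means relative concentration 10^−k, level 0 undiluted) and
    ``cq``; optionally ``gene`` to select one gene's wells.
    """
    df = standards
    if gene is not None:
        df = df[df["gene"] == gene]
    if df.empty:
        raise ValueError("no standard wells")
    levels = df["dilution_level"].to_numpy(dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    x = -levels  # log10 relative concentration
    y = df["cq"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    return StandardCurve(
        gene=gene or str(df["gene"].iloc[0]) if "gene" in df else "",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_levels=int(np.unique(levels).size),
    )


def concentration_from_cq(cq: float, curve: StandardCurve) -> float:
    """Relative concentration read off the curve: 10^((cq − intercept)/slope)."""
    if not curve.is_valid:
        raise ValueError(
            f"invalid standard curve (slope {curve.slope:.3g}, "
            f"efficiency {curve.efficiency:.3g})"
        )
    return float(10 ** ((cq - curve.intercept) / curve.slope))


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    population: str
    ratio: float  #: target/reference concentration ratio = copies per haploid genome
    replicate_ratios: tuple[float, ...]


def copy_ratio(
    sample_wells: pd.DataFrame,
    target_curve: StandardCurve,
    ref_curve: StandardCurve,
    target_gene: str = "ace1",
    ref_gene: str = "rps7",
    geometric: bool = False,
) -> CopyNumberEstimate:
    """Per-sample copy number from its unknown wells.

    Replicate target and reference wells are paired in file order; the
    sample ratio is the arithmetic mean of replicate ratios (geometric
    optionally).
    """
    t_cq = sample_wells.loc[sample_wells["gene"] == target_gene, "cq"].to_numpy(dtype=float)
    r_cq = sample_wells.loc[sample_wells["gene"] == ref_gene, "cq"].to_numpy(dtype=float)
    n = min(t_cq.size, r_cq.size)
    if n < 1:
        raise ValueError("need at least one replicate pair (both genes present)")
    ratios = np.array(
        [
            concentration_from_cq(t, target_curve) / concentration_from_cq(r, ref_curve)
            for t, r in zip(t_cq[:n], r_cq[:n])
        ]
    )
    mean = float(np.exp(np.log(ratios).mean())) if geometric else float(ratios.mean())
    sid = str(sample_wells["sample_id"].iloc[0]) if "sample_id" in sample_wells else ""
    pop = str(sample_wells["population"].iloc[0]) if "population" in sample_wells else ""
    return CopyNumberEstimate(sid, pop, mean, tuple(ratios))


def estimates_from_plate(
    plate: pd.DataFrame,
    target_gene: str = "ace1",
    ref_gene: str = "rps7",
    geometric: bool = False,
    require_melt_ok: bool = True,
) -> tuple[list[CopyNumberEstimate], dict[str, StandardCurve]]:
    """Analyse a full plate CSV (sample_id, population, gene, role,
    dilution_level, cq[, melt_ok]): fit both standard curves, then estimate
    every unknown sample's copy ratio."""
    df = plate.copy()
    if require_melt_ok and "melt_ok" in df.columns:
        df = df[df["melt_ok"].astype(bool)]
    curves = {
        g: fit_standard_curve(df[(df["role"] == "standard")], gene=g)
        for g in (target_gene, ref_gene)
    }
    unknowns = df[df["role"] == "unknown"]
    if unknowns.empty:
        raise ValueError("plate has no unknown wells")
    estimates = [
        copy_ratio(grp, curves[target_gene], curves[ref_gene], target_gene, ref_gene, geometric)
        for _, grp in unknowns.groupby("sample_id", sort=True)
    ]
    return estimates, curves


def population_copy_number(
    estimates: list[CopyNumberEstimate], reference_population: str = "LP"
) -> pd.DataFrame:
    """Per-population mean ± sd of sample copy ratios plus a Welch t-test
    against the sensitive reference population."""
    df = pd.DataFrame(
        [{"population": e.population, "sample_id": e.sample_id, "ratio": e.ratio} for e in estimates]
    )
    if reference_population not in set(df["population"]):
        raise ValueError(f"reference population {reference_population!r} absent")
    ref = df.loc[df["population"] == reference_population, "ratio"].to_numpy()
    rows = []
    for pop, grp in df.groupby("population", sort=True):
        vals = grp["ratio"].to_numpy()
        if pop == reference_population:
            t = p = np.nan
        else:
            if vals.size < 2 or ref.size < 2:
                raise ValueError("need at least two samples per compared population")
            t, p = (float(v) for v in stats.ttest_ind(vals, ref, equal_var=False))
        rows.append(
            {
                "population": pop,
                "n_samples": vals.size,
                "mean_copy": float(vals.mean()),
                "sd_copy": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "t_vs_reference": t,
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)
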