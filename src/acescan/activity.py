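"""Propoxur-inhibited AChE1 residual activity from OD readings.

The Ellman-type kit assay reads absorbance at 412 nm in paired wells: an
uninhibited (ethanol) well giving OD_total and a propoxur-inhibited well
giving OD_inhibitory.  Residual activity in U per gram of tissue collapses
to ``activity = c · ΔA / W`` with ΔA = OD_total − OD_inhibitory, W the
tissue mass in grams and c the kit constant (2255 for the assay modeled
here).  Resistant AChE1 keeps hydrolysing substrate in the presence of the
carbamate, so high residual activity marks resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityConfig",
    "ActivityRecord",
    "residual_activity",
    "compare_to_reference",
    "activity_table",
    "population_comparison_table",
]


@dataclass(frozen=True)
class ActivityConfig:
    """Kit calibration.

    ``kit_constant`` is the collapsed constant c in activity = c·ΔA/W.  The
    long-form components (molar extinction coefficient ε, cuvette path d,
    the assay volumes in the same units the kit states, and reaction time T
    in minutes) may be supplied instead; when all are present the constant
    is recomputed as

        c = 1/(ε·d) · V_coloration · 1e9 / (V_sample/V_total · V_supernatant/V_enzyme) / T
    """

    kit_constant: float = 2255.0
    epsilon: float | None = None
    path_cm: float | None = None
    v_coloration: float | None = None
    v_sample: float | None = None
    v_total: float | None = None
    v_supernatant: float | None = None
    v_enzyme: float | None = None
    reaction_time: float | None = None

    @property
    def constant(self) -> float:
        parts = (
            self.epsilon,
            self.path_cm,
            self.v_coloration,
            self.v_sample,
            self.v_total,
            self.v_supernatant,
            self.v_enzyme,
            self.reaction_time,
        )
        if all(p is not None for p in parts):
            return (
                1.0
                / (self.epsilon * self.path_cm)
                * self.v_coloration
                * 1e9
                / (self.v_sample / self.v_total * self.v_supernatant / self.v_enzyme)
                / self.reaction_time
            )
        if self.kit_constant <= 0:
            raise ValueError("kit constant must be positive")
        return self.kit_constant


@dataclass(frozen=True)
class ActivityRecord:
    population: str
    replicate_id: str
    od_total: float
    od_inhibitory: float
    weight_g: float
    delta_a: float
    activity: float  #: U/g
    clipped: bool = False  #: ΔA < 0 clipped to zero


def residual_activity(
    od_total: float,
    od_inhibitory: float,
    weight_g: float,
    cfg: ActivityConfig = ActivityConfig(),
    population: str = "",
    replicate_id: str = "",
) -> ActivityRecord:
    """Residual activity of one replicate.

    Negative ΔA (inhibited well darker than the uninhibited one, i.e.
    apparent negative inhibition) is physically meaningless noise and is
    clipped to zero with the record flagged.
    """
    if weight_g <= 0:
        raise ValueError("tissue weight must be positive")
    if od_total < 0 or od_inhibitory < 0:
        raise ValueError("absorbances must be nonnegative")
    delta = od_total - od_inhibitory
    clipped = delta < 0
    if clipped:
        delta = 0.0
    return ActivityRecord(
        population=population,
        replicate_id=replicate_id,
        od_total=od_total,
        od_inhibitory=od_inhibitory,
        weight_g=weight_g,
        delta_a=delta,
        activity=cfg.constant * delta / weight_g,
        clipped=clipped,
    )


def compare_to_reference(
    pop_activities, ref_activities, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test of a population's residual activities against the
    sensitive reference population (Welch by default)."""
    a = np.asarray(list(pop_activities), dtype=float)
    b = np.asarray(list(ref_activities), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replicates per group")
    if a.std() == 0 and b.std() == 0:
        # degenerate: identical constants in both groups
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def activity_table(od_csv: str | Path, cfg: ActivityConfig = ActivityConfig()) -> pd.DataFrame:
    """Compute per-replicate activities from an OD plate CSV
    (population,replicate_id,od_total,od_inhibitory,weight_g)."""
    df = pd.read_csv(od_csv)
    recs = [
        residual_activity(
            r.od_total, r.od_inhibitory, r.weight_g, cfg, str(r.population), str(r.replicate_id)
        )
        for r in df.itertuples()
    ]
    return pd.DataFrame([r.__dict__ for r in recs])


def population_comparison_table(
    activities: pd.DataFrame,
    reference: str = "LP",
    equal_var: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-population mean ± sd plus the t-test of each population against
    the reference.  Bonferroni correction over the non-reference
    comparisons is off by default."""
    if reference not in set(activities["population"]):
        raise ValueError(f"reference population {reference!r} absent")
    ref_vals = activities.loc[activities["population"] == reference, "activity"]
    rows = []
    others = [p for p in activities["population"].unique() if p != reference]
    for pop, grp in activities.groupby("population", sort=True):
        vals = grp["activity"]
        if pop == reference:
            t = p = np.nan
        else:
            t, p = compare_to_reference(vals, ref_vals, equal_var=equal_var)
            if bonferroni:
                p = min(1.0, p * len(others))
        rows.append(
            {
                "population": pop,
                "n": len(vals),
                "mean_activity": float(vals.mean()),
                "sd_activity": float(vals.std(ddof=1)),
                "t_vs_reference": t,
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows)
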