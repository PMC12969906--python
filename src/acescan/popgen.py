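"""Population-genetic statistics for codon-119 genotype tables.

Implements allele frequencies, the exact Hardy–Weinberg test by full
enumeration of heterozygote configurations conditional on the observed
allele counts, heterozygote excess direction against the Levene
expectation, and the K×2 Pearson chi-square test of allele-frequency
heterogeneity across populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .genotyping import PopulationCounts

__all__ = [
    "HWEResult",
    "HeterogeneityResult",
    "allele_counts",
    "hwe_exact",
    "hwe_configuration_log_probs",
    "heterogeneity_chi2",
    "summarize",
    "counts_from_percentages",
    "load_guizhou_counts",
    "read_counts_csv",
    "counts_from_genotype_table",
]

#: Relative tolerance for "no more probable than observed" in the exact test.
_TAIL_RTOL = 1e-12


@dataclass(frozen=True)
class HWEResult:
    """Exact Hardy–Weinberg test result for one population."""

    p_exact: float
    observed_het: int
    expected_het: float  #: Levene expectation nG·nS/(2n−1)
    direction: str  #: "excess" | "deficit" | "none"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Pearson chi-square on the K×2 table of allele counts."""

    chi2: float
    df: int
    p: float


def allele_counts(t: PopulationCounts) -> tuple[int, int]:
    """Return (nG, nS) allele counts; GGT is pooled into the G class."""
    if t.n == 0:
        raise ValueError("empty population")
    n_s = 2 * t.n_ss + t.n_gs
    n_g = 2 * t.n_gg + t.n_gs
    return n_g, n_s


def hwe_configuration_log_probs(n_g: int, n_s: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every heterozygote count compatible with the
    allele counts.

    Conditional on (nG, nS) the probability of observing h heterozygotes in
    n = (nG+nS)/2 diploids is

        P(h) = n! nG! nS! 2^h / [ (2n)! nGG! h! nSS! ]

    with nGG = (nG−h)/2 and nSS = (nS−h)/2.  Valid h share the parity of nS
    (equivalently of nG) and range over [h_min, min(nG, nS)].

    Returns ``(hs, logps)`` with the heterozygote counts and their log
    probabilities.
    """
    if n_g < 0 or n_s < 0 or (n_g + n_s) % 2:
        raise ValueError("allele counts must be nonnegative with even total")
    n = (n_g + n_s) // 2
    h_max = min(n_g, n_s)
    hs = np.arange(h_max % 2, h_max + 1, 2)
    if hs.size == 0:  # one allele absent: single configuration, probability 1
        hs = np.array([0])
    n_gg = (n_g - hs) // 2
    n_ss = (n_s - hs) // 2
    logps = (
        gammaln(n + 1)
        + gammaln(n_g + 1)
        + gammaln(n_s + 1)
        + hs * math.log(2)
        - gammaln(2 * n + 1)
        - gammaln(n_gg + 1)
        - gammaln(hs + 1)
        - gammaln(n_ss + 1)
    )
    return hs, logps


def hwe_exact(t: PopulationCounts) -> HWEResult:
    """Exact Hardy–Weinberg test by full enumeration.

    The two-sided p-value sums the conditional probabilities of every
    heterozygote configuration no more probable than the observed one
    (within a relative tolerance), the convention under which the observed
    modal configuration yields p = 1.
    """
    if t.n < 1:
        raise ValueError("need at least one individual")
    n_g, n_s = allele_counts(t)
    hs, logps = hwe_configuration_log_probs(n_g, n_s)
    obs_idx = np.flatnonzero(hs == t.n_gs)
    if obs_idx.size != 1:
        raise ValueError("observed heterozygote count incompatible with allele counts")
    log_obs = logps[obs_idx[0]]
    if hs.size == 1:
        p = 1.0  # single admissible configuration; avoid log-space rounding
    else:
        tail = logps <= log_obs + math.log1p(_TAIL_RTOL)
        p = min(float(np.exp(logsumexp(logps[tail]))), 1.0)
    expected_het = n_g * n_s / (2 * t.n - 1) if t.n > 0 else 0.0
    if t.n_gs > expected_het:
        direction = "excess"
    elif t.n_gs < expected_het:
        direction = "deficit"
    else:
        direction = "none"
    return HWEResult(p_exact=p, observed_het=t.n_gs, expected_het=expected_het, direction=direction)


def heterogeneity_chi2(tables: Sequence[PopulationCounts]) -> HeterogeneityResult:
    """Pearson chi-square for allele-frequency heterogeneity across
    populations (K×2 contingency table of G-class vs S allele counts, no
    continuity correction)."""
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    table = np.array([allele_counts(t) for t in tables])
    if (table.sum(axis=1) == 0).any():
        raise ValueError("population with zero alleles")
    res = stats.chi2_contingency(table, correction=False)
    return HeterogeneityResult(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def summarize(
    tables: Sequence[PopulationCounts],
    alpha: float = 0.05,
    mutant_threshold_pct: float = 66.0,
) -> dict:
    """Per-population frequencies plus the pooled and across-population
    summaries: unweighted column means, allele-count-weighted pooled S
    frequency, HWE-deviant population count, and the count of populations
    whose mutant-genotype (GS+SS) frequency reaches the threshold."""
    if not tables:
        raise ValueError("no populations")
    rows = []
    for t in tables:
        n_g, n_s = allele_counts(t)
        two_n = 2 * t.n
        hwe = hwe_exact(t)
        rows.append(
            {
                "population": t.population,
                "n": t.n,
                "pct_GG": 100 * t.n_gg / t.n,
                "pct_GS": 100 * t.n_gs / t.n,
                "pct_SS": 100 * t.n_ss / t.n,
                "pct_mutant": 100 * (t.n_gs + t.n_ss) / t.n,
                "pct_allele_GGC": 100 * (n_g - t.n_ggt_alleles) / two_n,
                "pct_allele_GGT": 100 * t.n_ggt_alleles / two_n,
                "pct_allele_S": 100 * n_s / two_n,
                "hwe_p": hwe.p_exact,
                "hwe_direction": hwe.direction,
                "expected_het": hwe.expected_het,
            }
        )
    df = pd.DataFrame(rows)
    total_alleles = int(sum(2 * t.n for t in tables))
    total_s = int(sum(allele_counts(t)[1] for t in tables))
    summary = {
        "per_population": df,
        "n_total": int(sum(t.n for t in tables)),
        "mean_pct_GG": float(df["pct_GG"].mean()),
        "mean_pct_GS": float(df["pct_GS"].mean()),
        "mean_pct_SS": float(df["pct_SS"].mean()),
        "pooled_pct_S": 100 * total_s / total_alleles,
        "n_hwe_deviant": int((df["hwe_p"] < alpha).sum()),
        "n_mutant_over_threshold": int((df["pct_mutant"] >= mutant_threshold_pct).sum()),
    }
    return summary


def counts_from_percentages(
    population: str,
    n: int,
    pct_gg: float,
    pct_ss: float,
    pct_gs: float,
    n_ggt_alleles: int = 0,
) -> PopulationCounts:
    """Reconstruct genotype counts from printed percentages.

    Counts are round(n × %/100); the reconstruction is rejected unless the
    counts sum back to n (all published rows this package ships do).
    """
    n_gg = round(n * pct_gg / 100)
    n_ss = round(n * pct_ss / 100)
    n_gs = round(n * pct_gs / 100)
    if n_gg + n_gs + n_ss != n:
        raise ValueError(
            f"{population}: reconstructed counts {n_gg}+{n_gs}+{n_ss} != n={n}"
        )
    return PopulationCounts(population, n, n_gg, n_gs, n_ss, n_ggt_alleles)


def load_guizhou_counts() -> list[PopulationCounts]:
    """The packaged 12-population Guizhou survey table (printed genotype
    percentages), reconstructed to integer genotype counts."""
    with resources.files("acescan.data").joinpath("guizhou_genotype_table.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return [
        counts_from_percentages(
            r.population, int(r.n), r.pct_GG, r.pct_SS, r.pct_GS, int(r.n_GGT_alleles)
        )
        for r in df.itertuples()
    ]


def read_counts_csv(path: str | Path) -> list[PopulationCounts]:
    """Read a direct population-count CSV
    (population,n,nGG,nGS,nSS[,nGGT_alleles])."""
    df = pd.read_csv(path)
    ggt = df["nGGT_alleles"] if "nGGT_alleles" in df else pd.Series(0, index=df.index)
    return [
        PopulationCounts(str(r["population"]), int(r["n"]), int(r["nGG"]), int(r["nGS"]), int(r["nSS"]), int(g))
        for (_, r), g in zip(df.iterrows(), ggt)
    ]


def counts_from_genotype_table(path: str | Path) -> list[PopulationCounts]:
    """Tally a per-sample genotype CSV (the genotyping stage output) into
    per-population counts."""
    df = pd.read_csv(path, keep_default_na=False)
    df = df[df["qc_flag"] == "ok"]
    out = []
    for pop, grp in df.groupby("population", sort=True):
        cls = grp["genotype_class"].value_counts()
        n_ggt = int((grp["allele1"] == "GGT").sum() + (grp["allele2"] == "GGT").sum())
        out.append(
            PopulationCounts(
                str(pop),
                len(grp),
                int(cls.get("GG", 0)),
                int(cls.get("GS", 0)),
                int(cls.get("SS", 0)),
                n_ggt,
            )
        )
    return out
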