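"""Consolidated report over the pipeline stages.

``run_report`` is a pure function of whatever stage outputs are present:
the popgen summary, the activity comparison table, duplication calls and
the qPCR copy-number table.  It merges them into one JSON document plus a
human-readable markdown table, with frequencies at 2 decimal places and
p-values at 3.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import DuplicationCall

__all__ = ["run_report", "write_report"]


def _round(x, nd):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)


def _population_sets(stages: dict) -> list[set[str]]:
    sets = []
    if "popgen" in stages:
        sets.append(set(stages["popgen"]["per_population"]["population"]))
    if "activity" in stages:
        sets.append(set(stages["activity"]["population"]))
    if "qpcr" in stages:
        sets.append(set(stages["qpcr"]["population"]))
    return sets


def run_report(
    popgen_summary: dict | None = None,
    activity_comparison: pd.DataFrame | None = None,
    duplication_calls: list[DuplicationCall] | None = None,
    qpcr_populations: pd.DataFrame | None = None,
) -> dict:
    """Merge stage outputs into one report dict.

    Raises
    ------
    ValueError
        If no stage output is given, or stages that name populations share
        none (disjoint names indicate mismatched inputs).
    """
    stages = {}
    if popgen_summary is not None:
        stages["popgen"] = popgen_summary
    if activity_comparison is not None:
        stages["activity"] = activity_comparison
    if qpcr_populations is not None:
        stages["qpcr"] = qpcr_populations
    if not stages and not duplication_calls:
        raise ValueError("no stage outputs to report")
    sets = _population_sets(stages)
    if len(sets) > 1 and not set.intersection(*sets):
        raise ValueError("stage outputs name disjoint populations; inputs look mismatched")

    report: dict = {"stages": sorted(stages) + (["cnv"] if duplication_calls else [])}
    if popgen_summary is not None:
        per_pop = popgen_summary["per_population"]
        report["popgen"] = {
            "n_total": popgen_summary["n_total"],
            "pooled_pct_S": _round(popgen_summary["pooled_pct_S"], 2),
            "mean_pct_GS": _round(popgen_summary["mean_pct_GS"], 2),
            "n_hwe_deviant": popgen_summary["n_hwe_deviant"],
            "n_mutant_over_threshold": popgen_summary["n_mutant_over_threshold"],
            "populations": [
                {
                    "population": r.population,
                    "n": int(r.n),
                    "pct_GG": _round(r.pct_GG, 2),
                    "pct_GS": _round(r.pct_GS, 2),
                    "pct_SS": _round(r.pct_SS, 2),
                    "pct_allele_S": _round(r.pct_allele_S, 2),
                    "hwe_p": _round(r.hwe_p, 3),
                    "hwe_direction": r.hwe_direction,
                }
                for r in per_pop.itertuples()
            ],
        }
        if "heterogeneity" in popgen_summary:
            het = popgen_summary["heterogeneity"]
            report["popgen"]["heterogeneity_chi2"] = {
                "chi2": _round(het.chi2, 2),
                "df": het.df,
                "p": _round(het.p, 3),
            }
    if activity_comparison is not None:
        report["activity"] = [
            {
                "population": r.population,
                "n": int(r.n),
                "mean_activity": _round(r.mean_activity, 2),
                "sd_activity": _round(r.sd_activity, 2),
                "t_vs_reference": _round(r.t_vs_reference, 3),
                "p_vs_reference": _round(r.p_vs_reference, 3),
            }
            for r in activity_comparison.itertuples()
        ]
    if duplication_calls:
        report["cnv"] = [
            {
                "locus": c.locus_name,
                "contig": c.span.contig,
                "start": c.span.start,
                "end": c.span.end,
                "mean_ratio": _round(c.mean_ratio, 3),
                "copy_estimate": _round(c.copy_estimate, 3),
                "is_duplicated": c.is_duplicated,
                "control_mean_ratio": _round(c.control_mean_ratio, 3),
                "control_ok": c.control_ok,
            }
            for c in duplication_calls
        ]
    if qpcr_populations is not None:
        report["qpcr"] = [
            {
                "population": r.population,
                "n_samples": int(r.n_samples),
                "mean_copy": _round(r.mean_copy, 2),
                "sd_copy": _round(r.sd_copy, 2),
                "t_vs_reference": _round(r.t_vs_reference, 3),
                "p_vs_reference": _round(r.p_vs_reference, 3),
            }
            for r in qpcr_populations.itertuples()
        ]
    return report


def _markdown(report: dict) -> str:
    lines = ["# ace-1 resistance survey report", ""]
    if "popgen" in report:
        pg = report["popgen"]
        lines += [
            "## Genotype and allele frequencies",
            "",
            f"Total genotyped: {pg['n_total']}; pooled S-allele frequency "
            f"{pg['pooled_pct_S']}%; {pg['n_hwe_deviant']} populations deviate from HWE.",
            "",
            "| population | n | %GG | %GS | %SS | %S allele | HWE p | direction |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for r in pg["populations"]:
            lines.append(
                f"| {r['population']} | {r['n']} | {r['pct_GG']} | {r['pct_GS']} | "
                f"{r['pct_SS']} | {r['pct_allele_S']} | {r['hwe_p']} | {r['hwe_direction']} |"
            )
        if "heterogeneity_chi2" in pg:
            h = pg["heterogeneity_chi2"]
            lines += ["", f"Allele heterogeneity: chi2 = {h['chi2']}, df = {h['df']}, p = {h['p']}"]
        lines.append("")
    if "activity" in report:
        lines += [
            "## AChE1 residual activity",
            "",
            "| population | n | mean (U/g) | sd | t vs ref | p |",
            "|---|---|---|---|---|---|",
        ]
        for r in report["activity"]:
            lines.append(
                f"| {r['population']} | {r['n']} | {r['mean_activity']} | {r['sd_activity']} | "
                f"{r['t_vs_reference']} | {r['p_vs_reference']} |"
            )
        lines.append("")
    if "cnv" in report:
        lines += ["## Duplication calls", ""]
        for c in report["cnv"]:
            verdict = "DUPLICATED" if c["is_duplicated"] else "single-copy"
            lines.append(
                f"- {c['locus']} ({c['contig']}:{c['start']}-{c['end']}): mean DOC ratio "
                f"{c['mean_ratio']}, copy estimate {c['copy_estimate']} — {verdict} "
                f"(control ratio {c['control_mean_ratio']}, ok={c['control_ok']})"
            )
        lines.append("")
    if "qpcr" in report:
        lines += [
            "## qPCR copy number",
            "",
            "| population | samples | mean copy | sd | t vs ref | p |",
            "|---|---|---|---|---|---|",
        ]
        for r in report["qpcr"]:
            lines.append(
                f"| {r['population']} | {r['n_samples']} | {r['mean_copy']} | {r['sd_copy']} | "
                f"{r['t_vs_reference']} | {r['p_vs_reference']} |"
            )
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, json_path: str | Path, md_path: str | Path | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    if md_path is not None:
        Path(md_path).write_text(_markdown(report))
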