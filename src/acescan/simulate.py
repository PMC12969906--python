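"""Synthetic inputs for every pipeline stage.

Field data for an ace-1 resistance survey comes in four shapes: Sanger
amplicon consensus sequences, whole-genome per-base depth tables, qPCR
plates and OD plates.  The generators here emulate each with the
statistical structure the analysis assumes — diploid genotypes with a
tunable inbreeding-style coefficient F (negative F ⇒ heterozygote
excess, the signature of the heterogeneous duplication), Poisson or
negative-binomial coverage with a duplicated span, Cq values under stated
amplification efficiencies, and OD pairs inverted from target activities —
so every stage is testable without sequencing data.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genotyping import (
    AmpliconRef,
    DEFAULT_REF,
    KNOWN_ALLELES,
    SET_TO_IUPAC,
)

__all__ = [
    "PopulationSpec",
    "CoverageSpec",
    "QpcrSpec",
    "ActivitySpec",
    "gen_genotypes",
    "gen_amplicons",
    "write_amplicon_fasta",
    "gen_depth",
    "write_depth_tsv",
    "gen_qpcr",
    "gen_activity",
    "generate_scenario",
    "GUIZHOU_SCENARIO",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population.

    ``p_s`` is the resistant (AGC/S) allele frequency; ``f`` the
    inbreeding-style coefficient shaping genotype frequencies
    (P(het) = 2p(1−p)(1−F); negative F inflates heterozygotes, as a
    duplicated S+R haplotype would); ``p_ggt`` the fraction of G-class
    alleles that are the synonymous GGT variant.
    """

    name: str
    n: int
    p_s: float
    f: float = 0.0
    p_ggt: float = 0.0

    def genotype_probs(self) -> np.ndarray:
        """(P(GG), P(GS), P(SS)) with F, clamped to [0,1] and renormalized."""
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        if not -1.0 <= self.f <= 1.0:
            raise ValueError("F must lie in [-1, 1]")
        p, q, f = self.p_s, 1.0 - self.p_s, self.f
        probs = np.array([q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q])
        probs = np.clip(probs, 0.0, None)
        total = probs.sum()
        if total <= 0:
            raise ValueError("degenerate genotype probabilities")
        return probs / total


@dataclass(frozen=True)
class CoverageSpec:
    """WGS pool coverage: contig lengths, mean depth, optional
    overdispersion (negative binomial when ``dispersion`` is finite) and
    the duplicated span with its relative copy number in resistant
    pools."""

    target_contig: str = "KE524393-like"
    target_length: int = 41_288
    control_contig: str = "vgsc_contig"
    control_length: int = 35_000
    mean_depth: float = 30.0
    dispersion: float = float("inf")  #: NB size parameter; inf = Poisson
    dup_start: int = 20_000  #: 0-based half-open span on the target contig
    dup_end: int = 24_000
    copy_number: float = 2.0


@dataclass(frozen=True)
class QpcrSpec:
    """Plate design: per-gene efficiency/intercept, dilution levels for the
    tenfold standard series, replicate count and Cq noise for unknowns."""

    target_gene: str = "ace1"
    ref_gene: str = "rps7"
    efficiency: Mapping[str, float] = field(
        default_factory=lambda: {"ace1": 0.97, "rps7": 0.99}
    )
    intercept: Mapping[str, float] = field(
        default_factory=lambda: {"ace1": 21.0, "rps7": 19.5}
    )
    dilution_levels: int = 5
    standard_replicates: int = 3
    replicates: int = 4
    cq_sigma: float = 0.1
    standard_sigma: float = 0.0
    base_concentration: float = 0.1  #: relative conc. of a 1-copy unknown

    def slope(self, gene: str) -> float:
        e = self.efficiency[gene]
        if not 0.7 < e <= 1.1:
            raise ValueError(f"efficiency {e} outside (0.7, 1.1]")
        return -1.0 / np.log10(1.0 + e)


@dataclass(frozen=True)
class ActivitySpec:
    """OD plate design: per-population target mean residual activity (U/g),
    lognormal CV, replicates, tissue weight and the uninhibited-well
    baseline absorbance."""

    mean_activity: Mapping[str, float]
    cv: float = 0.10
    replicates: int = 5
    weight_g: float = 0.1
    od_total: float = 1.0
    kit_constant: float = 2255.0


def gen_genotypes(spec: PopulationSpec, seed: int) -> list[tuple[str, str]]:
    """Draw one allele pair per individual.

    Returns a list of unordered codon pairs; GGT is substituted for GGC
    independently per G allele with probability ``p_ggt``.  GS heterozygotes
    never receive GGT: a GGT/AGC consensus (RGY) is ambiguous at two codon
    positions and cannot be phased from a Sanger consensus, so the caller
    would reject it — and the only GGT carrier ever observed in the survey
    this emulates was a homozygote.
    """
    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=spec.n, p=spec.genotype_probs())
    pairs = []
    for c in classes:
        alleles = [["GGC", "GGC"], ["GGC", "AGC"], ["AGC", "AGC"]][c][:]
        for i, a in enumerate(alleles):
            if a == "GGC" and c == 0 and spec.p_ggt > 0 and rng.random() < spec.p_ggt:
                alleles[i] = "GGT"
        pairs.append(tuple(sorted(alleles)))
    return pairs


def _consensus_codon(pair: Sequence[str]) -> str:
    """IUPAC consensus of two codon alleles (what direct Sanger sequencing
    of a heterozygote reports)."""
    return "".join(
        SET_TO_IUPAC[frozenset({a, b})] for a, b in zip(pair[0], pair[1])
    )


def gen_amplicons(
    individuals: Sequence[tuple[str, str]],
    population: str,
    ref: AmpliconRef = DEFAULT_REF,
    seed: int = 0,
    error_rate: float = 0.0,
    id_delimiter: str = "|",
) -> list[SeqRecord]:
    """One amplicon consensus record per individual; heterozygous codon
    positions are emitted as IUPAC ambiguity codes.  A uniform substitution
    error rate (default 0) can corrupt non-codon positions."""
    rng = np.random.default_rng(seed)
    off = ref.codon119_offset
    records = []
    for i, pair in enumerate(individuals, start=1):
        codon = _consensus_codon(pair)
        seq = ref.sequence[:off] + codon + ref.sequence[off + 3 :]
        if error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if off <= j < off + 3:
                    continue
                if rng.random() < error_rate:
                    chars[j] = rng.choice([b for b in "ACGT" if b != chars[j]])
            seq = "".join(chars)
        records.append(
            SeqRecord(Seq(seq), id=f"{population}-{i:03d}{id_delimiter}{population}", description="")
        )
    return records


def write_amplicon_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def gen_depth(
    spec: CoverageSpec, seed: int, resistant: bool, omit_zeros: bool = True
) -> pd.DataFrame:
    """Per-base depth table for one pool (samtools-depth layout).

    Resistant pools carry ``copy_number`` relative copies over the
    duplicated span of the target contig; sensitive pools are single-copy
    throughout.  Depth is Poisson(λ) or negative binomial with the given
    dispersion (size) parameter.  Zero-depth rows are omitted by default,
    as samtools does.
    """
    if spec.mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if not 0 <= spec.dup_start < spec.dup_end <= spec.target_length:
        raise ValueError("duplication span outside the target contig")
    rng = np.random.default_rng(seed)
    frames = []
    for contig, length in (
        (spec.target_contig, spec.target_length),
        (spec.control_contig, spec.control_length),
    ):
        lam = np.full(length, spec.mean_depth)
        if resistant and contig == spec.target_contig:
            lam[spec.dup_start : spec.dup_end] *= spec.copy_number
        if np.isinf(spec.dispersion):
            depth = rng.poisson(lam)
        else:
            k = spec.dispersion
            depth = rng.negative_binomial(k, k / (k + lam))
        frames.append(
            pd.DataFrame(
                {"contig": contig, "pos": np.arange(1, length + 1), "depth": depth}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if omit_zeros:
        df = df[df["depth"] > 0].reset_index(drop=True)
    return df


def write_depth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def gen_qpcr(
    spec: QpcrSpec,
    true_copies: Mapping[str, float],
    populations: Mapping[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR plate for samples with known true copy numbers.

    Standards for both genes follow Cq = intercept + slope·log10(10^−k)
    over the tenfold dilution series.  Unknown wells put each sample's
    target-gene concentration at copy × base_concentration and its
    reference-gene concentration at base_concentration (the reference is
    single-copy by construction), with Normal(0, cq_sigma) noise on Cq.
    """
    rng = np.random.default_rng(seed)
    populations = populations or {}
    rows = []
    for gene in (spec.target_gene, spec.ref_gene):
        slope, icpt = spec.slope(gene), spec.intercept[gene]
        for level in range(spec.dilution_levels):
            for _ in range(spec.standard_replicates):
                cq = icpt + slope * (-level) + rng.normal(0.0, spec.standard_sigma)
                rows.append(
                    {
                        "sample_id": f"std-{gene}",
                        "population": "",
                        "gene": gene,
                        "role": "standard",
                        "dilution_level": level,
                        "cq": cq,
                        "melt_ok": True,
                    }
                )
    for sample, copy in true_copies.items():
        if copy <= 0:
            raise ValueError("true copy number must be positive")
        for gene, conc in (
            (spec.target_gene, copy * spec.base_concentration),
            (spec.ref_gene, spec.base_concentration),
        ):
            slope, icpt = spec.slope(gene), spec.intercept[gene]
            for _ in range(spec.replicates):
                cq = icpt + slope * np.log10(conc) + rng.normal(0.0, spec.cq_sigma)
                rows.append(
                    {
                        "sample_id": sample,
                        "population": populations.get(sample, ""),
                        "gene": gene,
                        "role": "unknown",
                        "dilution_level": "",
                        "cq": cq,
                        "melt_ok": True,
                    }
                )
    return pd.DataFrame(rows)


def gen_activity(spec: ActivitySpec, seed: int = 0) -> pd.DataFrame:
    """Simulate an OD plate.

    The inhibited-well absorbance is set so that the kit equation
    activity = c·ΔA/W recovers each population's target mean activity,
    with multiplicative lognormal noise of the given CV on activity.
    Targets whose noiseless ΔA would exceed the uninhibited baseline are
    rejected as infeasible.
    """
    if spec.cv < 0:
        raise ValueError("CV must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(spec.cv**2))
    rows = []
    for pop, target in spec.mean_activity.items():
        base_delta = target * spec.weight_g / spec.kit_constant
        if base_delta > spec.od_total:
            raise ValueError(
                f"{pop}: target activity {target} needs ΔA {base_delta:.3f} > "
                f"OD_total {spec.od_total}"
            )
        for r in range(1, spec.replicates + 1):
            noise = rng.lognormal(-(sigma**2) / 2, sigma) if spec.cv > 0 else 1.0
            delta = min(base_delta * noise, spec.od_total)
            rows.append(
                {
                    "population": pop,
                    "replicate_id": f"{pop}-r{r}",
                    "od_total": spec.od_total,
                    "od_inhibitory": spec.od_total - delta,
                    "weight_g": spec.weight_g,
                }
            )
    return pd.DataFrame(rows)


# The bundled survey-like scenario: 12 populations at the surveyed S-allele
# frequencies, F < 0 for the six heterozygote-excess populations, one
# GGT-homozygote-bearing population, a copy-2 resistant coverage pool vs a
# single-copy sensitive pool, duplicated (copy-2) and single-copy qPCR
# populations, and residual activity high in the sensitive reference
# relative to the mutated populations.
GUIZHOU_SCENARIO: dict = {
    "populations": [
        PopulationSpec("LP", 50, 0.06, 0.0),
        PopulationSpec("CH", 50, 0.67, -0.5),
        PopulationSpec("LD", 25, 0.70, -0.3),
        PopulationSpec("SD", 49, 0.61, -0.5),
        PopulationSpec("XR", 51, 0.68, 0.0),
        PopulationSpec("PB", 50, 0.45, -0.2),
        PopulationSpec("ZJ", 50, 0.55, -0.1, 0.02),
        PopulationSpec("HX", 50, 0.48, -0.2),
        PopulationSpec("DY", 50, 0.35, -0.4),
        PopulationSpec("XS", 26, 0.54, -0.6),
        PopulationSpec("TZ", 50, 0.50, -0.8),
        PopulationSpec("DJ", 50, 0.57, -0.6),
    ],
    "coverage": CoverageSpec(),
    "qpcr_copies": {"LP": 1.0, "CH": 2.0, "TZ": 2.0, "DJ": 2.0},
    "qpcr_samples_per_pop": 5,
    "activity": ActivitySpec(
        mean_activity={
            "LP": 1500.0,
            **{p: 600.0 for p in ("CH", "LD", "SD", "XR", "PB", "ZJ", "DY", "XS", "TZ", "DJ")},
            "HX": 1450.0,  # the one population indistinguishable from the reference
        }
    ),
}


def generate_scenario(outdir: str | Path, seed: int, scenario: dict | None = None) -> dict:
    """Write the full synthetic input bundle to ``outdir`` and return a
    manifest of paths.  Deterministic: the same seed yields byte-identical
    files."""
    sc = scenario or GUIZHOU_SCENARIO
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": {}}

    records = []
    for i, pop in enumerate(sc["populations"]):
        pairs = gen_genotypes(pop, seed=int(rng.integers(2**31)))
        records.extend(gen_amplicons(pairs, pop.name, seed=int(rng.integers(2**31))))
    fasta = out / "amplicons.fasta"
    write_amplicon_fasta(records, fasta)
    manifest["files"]["amplicons"] = str(fasta)

    cov = sc["coverage"]
    for label, resistant in (("resistant", True), ("sensitive", False)):
        df = gen_depth(cov, seed=int(rng.integers(2**31)), resistant=resistant)
        path = out / f"depth_{label}.tsv"
        write_depth_tsv(df, path)
        manifest["files"][f"depth_{label}"] = str(path)
    bed = out / "loci.bed"
    with open(bed, "w") as fh:
        fh.write(f"{cov.target_contig}\t{cov.dup_start}\t{cov.dup_end}\tace1\n")
        fh.write(f"{cov.control_contig}\t5000\t9000\tvgsc\n")
    manifest["files"]["loci_bed"] = str(bed)

    copies, pops = {}, {}
    for pop, copy in sc["qpcr_copies"].items():
        for k in range(1, sc["qpcr_samples_per_pop"] + 1):
            sid = f"{pop}-q{k}"
            copies[sid] = copy
            pops[sid] = pop
    plate = gen_qpcr(QpcrSpec(), copies, pops, seed=int(rng.integers(2**31)))
    qpcr_path = out / "qpcr_plate.csv"
    plate.to_csv(qpcr_path, index=False)
    manifest["files"]["qpcr_plate"] = str(qpcr_path)

    od = gen_activity(sc["activity"], seed=int(rng.integers(2**31)))
    od_path = out / "od_plate.csv"
    od.to_csv(od_path, index=False)
    manifest["files"]["od_plate"] = str(od_path)
    return manifest
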