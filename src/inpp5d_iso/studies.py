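"""End-to-end study routines built from the pipeline pieces.

These drive the simulator through the counting and statistics stages for
the package's calibration and null analyses: the balanced genomic-DNA
control simulation (the assay's technical-bias check), and repeated-cohort
runs of the conditional AEI rank-sum test for type-I error and power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aei_stats import (aei_table, rank_sum_test,
                        stratify_for_conditional_test)
from .amplicon_aei import count_alleles, parse_allele_kmer, RS1141328_KMER_SPEC
from .cohort_sim import (CohortSample, ExpressionState, SimConfig,
                         haplotype_frequencies, load_paper_fixture,
                         simulate_allele_counts, simulate_amplicon_reads,
                         simulate_cohort, stage_rng)

__all__ = [
    "fixture_het_cohort",
    "null_gdna_mean_ratio",
    "conditional_aei_pvalue",
    "conditional_aei_rejection_rate",
]


def fixture_het_cohort() -> list[CohortSample]:
    """The 26 reporter-SNP heterozygotes of the packaged cohort fixture."""
    _, cohort_table = load_paper_fixture()
    hets = cohort_table[cohort_table.genotype_rs1141328 == "GA"]
    return [CohortSample(**row) for row in hets.to_dict("records")]


def null_gdna_mean_ratio(seed: int, depth: int = 10_000,
                         error_rate: float = 0.005) -> tuple[float, list]:
    """Mean per-sample G:A ratio of simulated balanced gDNA read sets.

    Runs the full read-level path for the 26 fixture heterozygotes: amplicon
    simulation at the given depth and substitution error rate (true allele
    fraction 0.5 — genomic DNA carries one copy of each allele), 16-mer
    allele counting, per-sample ratio.  Returns (mean ratio, per-sample
    ratios); the mean estimates the assay's technical bias and should sit
    at 1 within sampling noise.
    """
    kmer = parse_allele_kmer(RS1141328_KMER_SPEC)
    ratios = []
    for sample in fixture_het_cohort():
        state = ExpressionState(sample.sample_id, {}, 0.13, 1.0)
        reads = simulate_amplicon_reads(
            sample, "gDNA", state, kmer, depth=depth, error_rate=error_rate,
            barcode="ACGTACGT",
            seed=stage_rng(seed, f"gdna:{sample.sample_id}"))
        counts = count_alleles(reads, kmer)
        ratios.append(counts.n_allele1 / counts.n_allele2)
    return float(np.mean(ratios)), ratios


def conditional_aei_pvalue(seed: int, n: int = 56, aei_effect: float = 1.0,
                           depth: int = 10_000,
                           test_snp: str = "rs35349669",
                           conditioning_snp: str = "rs10933431") -> float | None:
    """One simulated cohort -> conditional AEI rank-sum p-value.

    Counts are drawn on the fast binomial path (equivalent in distribution
    to error-free read counting).  Returns None when a stratum is empty.
    """
    hap = haplotype_frequencies(0.498, 0.220, 0.18)
    cohort = simulate_cohort(n, hap, seed=stage_rng(seed, "cohort"))
    config = SimConfig(aei_effect=aei_effect, aei_snp=test_snp)
    from .cohort_sim import simulate_expression

    states = simulate_expression(cohort, config,
                                 seed=stage_rng(seed, "expression"))
    by_id = {s.sample_id: s for s in states}
    hets = [s for s in cohort if s.is_heterozygous("rs1141328")]
    if len(hets) < 4:
        return None
    ids, cdna, gdna = [], [], []
    for i, s in enumerate(hets):
        st = by_id[s.sample_id]
        c1, c2 = simulate_allele_counts(
            s, "cDNA", st, depth, seed=stage_rng(seed, f"c:{s.sample_id}"))
        g1, g2 = simulate_allele_counts(
            s, "gDNA", st, depth, seed=stage_rng(seed, f"g:{s.sample_id}"))
        if c2 == 0 or g2 == 0:
            continue
        ids.append(s.sample_id)
        cdna.append(c1 / c2)
        gdna.append(g1 / g2)
    table = aei_table(ids, cdna, gdna, mode="cohort_mean")
    geno = pd.DataFrame({
        "sample_id": [s.sample_id for s in hets if s.sample_id in set(ids)],
        test_snp: [s.genotype(test_snp) for s in hets
                   if s.sample_id in set(ids)],
        conditioning_snp: [s.genotype(conditioning_snp) for s in hets
                           if s.sample_id in set(ids)],
    })
    merged = table.merge(geno, on="sample_id")
    groups = stratify_for_conditional_test(merged, test_snp, conditioning_snp)
    if not groups.group_homozygous or not groups.group_heterozygous:
        return None
    mags = dict(zip(merged.sample_id, merged.aei_magnitude))
    res = rank_sum_test([mags[i] for i in groups.group_homozygous],
                        [mags[i] for i in groups.group_heterozygous])
    return res.p_two_sided


def conditional_aei_rejection_rate(n_cohorts: int, seed: int,
                                   aei_effect: float = 1.0,
                                   alpha: float = 0.05,
                                   **kwargs) -> tuple[float, int]:
    """Rejection rate of the conditional test over repeated cohorts."""
    rejections = evaluated = 0
    for i in range(n_cohorts):
        p = conditional_aei_pvalue(seed * 1_000_003 % (2 ** 31) + i,
                                   aei_effect=aei_effect, **kwargs)
        if p is None:
            continue
        evaluated += 1
        rejections += p <= alpha
    return (rejections / evaluated if evaluated else float("nan")), evaluated
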