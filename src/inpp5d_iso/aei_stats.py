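"""AEI statistics: gDNA normalization, deviation magnitudes, conditional
genotype stratification and the Mann-Whitney rank-sum test.

The imbalance statistic is the absolute deviation of each heterozygote's
gDNA-normalized cDNA allelic ratio from the cohort mean of those normalized
ratios.  Because the two AD SNPs are in weak LD and phase is unknown, each
SNP's effect on AEI is tested only in subjects homozygous at the other SNP
(conditional stratification), comparing test-SNP homozygotes (both classes
pooled) against heterozygotes with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AeiRecord",
    "StratifiedGroups",
    "RankSumResult",
    "normalize_to_gdna",
    "aei_magnitude",
    "aei_table",
    "stratify_for_conditional_test",
    "expand_genotype_counts",
    "rank_sum_test",
]

# exact null enumeration whenever both bounds hold; larger samples use the
# normal approximation with tie and continuity corrections
EXACT_MIN_N = 10
EXACT_TOTAL_N = 30


@dataclass
class AeiRecord:
    sample_id: str
    raw_ratio_cdna: float
    raw_ratio_gdna: float | None
    normalized_ratio: float
    aei_magnitude: float


def normalize_to_gdna(cdna_ratios, gdna_ratios, mode: str = "cohort_mean"):
    """Normalize cDNA allelic ratios by the genomic-DNA control ratios.

    gDNA is expected to be balanced (1:1); dividing by it cancels
    amplification and counting bias.  ``cohort_mean`` divides every cDNA
    ratio by the mean of all gDNA ratios; ``paired`` divides each sample's
    cDNA ratio by its own gDNA ratio (requires aligned, equal-length
    inputs).
    """
    cdna = np.asarray(cdna_ratios, dtype=float)
    gdna = np.asarray(gdna_ratios, dtype=float)
    if gdna.size == 0:
        raise ValueError("gDNA ratio set is empty")
    if np.any(cdna <= 0) or np.any(gdna <= 0):
        raise ValueError("ratios must be strictly positive")
    if mode == "cohort_mean":
        return cdna / gdna.mean()
    if mode == "paired":
        if cdna.shape != gdna.shape:
            raise ValueError("paired mode requires a gDNA ratio per cDNA sample")
        return cdna / gdna
    raise ValueError(f"unknown normalization mode: {mode!r}")


def aei_magnitude(normalized_ratios, anchor: float | None = None):
    """Per-sample AEI magnitudes |r_i - anchor|.

    The anchor defaults to the mean of the normalized ratios over the
    included samples; pass ``anchor=1.0`` to measure deviation from perfect
    balance instead.
    """
    r = np.asarray(normalized_ratios, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 samples to anchor the deviation")
    a = r.mean() if anchor is None else float(anchor)
    return np.abs(r - a)


def aei_table(sample_ids: Sequence[str], cdna_ratios, gdna_ratios,
              mode: str = "cohort_mean",
              anchor: float | None = None) -> pd.DataFrame:
    """Assemble the per-sample AEI record table."""
    norm = normalize_to_gdna(cdna_ratios, gdna_ratios, mode=mode)
    mags = aei_magnitude(norm, anchor=anchor)
    gd = (list(gdna_ratios) if mode == "paired"
          else [float(np.mean(gdna_ratios))] * len(norm))
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "raw_ratio_cdna": np.asarray(cdna_ratios, dtype=float),
        "raw_ratio_gdna": gd,
        "normalized_ratio": norm,
        "aei_magnitude": mags,
    })


# --------------------------------------------------------------------------
# conditional stratification

@dataclass
class StratifiedGroups:
    test_snp: str
    conditioning_snp: str
    group_homozygous: list
    group_heterozygous: list
    n_excluded: int

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.group_homozygous), len(self.group_heterozygous)


def _is_het(genotype: str) -> bool:
    if (not isinstance(genotype, str) or len(genotype) != 2
            or any(b not in "ACGT" for b in genotype)):
        raise ValueError(f"unknown genotype code: {genotype!r}")
    return genotype[0] != genotype[1]


def expand_genotype_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Expand a genotype cross-tabulation into one row per sample.

    ``table`` has row index labelled with one SNP's genotypes and columns
    with the other's (as in a published genotype count table); the result
    has one row per counted sample with both genotype columns named after
    the index/column names.
    """
    row_snp = table.index.name or "snp_rows"
    col_snp = table.columns.name or "snp_cols"
    rows = []
    for g_row, row in table.iterrows():
        for g_col, count in row.items():
            rows.extend({row_snp: g_row, col_snp: g_col}
                        for _ in range(int(count)))
    out = pd.DataFrame(rows)
    out.insert(0, "sample_id", [f"G{i + 1:03d}" for i in range(len(out))])
    return out


def stratify_for_conditional_test(genotype_table: pd.DataFrame,
                                  test_snp: str,
                                  conditioning_snp: str) -> StratifiedGroups:
    """Split samples for the conditional AEI test.

    Retains only subjects homozygous at ``conditioning_snp`` (phase with the
    test SNP would otherwise be ambiguous), then splits by zygosity at
    ``test_snp``: both homozygote classes pooled versus heterozygotes.
    Columns may be named either exactly after the SNPs or as
    ``genotype_<snp>``.
    """
    def col(snp):
        for c in (snp, f"genotype_{snp}"):
            if c in genotype_table.columns:
                return c
        raise ValueError(f"genotype column for {snp} not found")

    if genotype_table.empty:
        return StratifiedGroups(test_snp, conditioning_snp, [], [], 0)
    tcol, ccol = col(test_snp), col(conditioning_snp)
    bad = []
    for i, row in genotype_table.iterrows():
        for c in (tcol, ccol):
            try:
                _is_het(row[c])
            except ValueError:
                bad.append(i)
    if bad:
        raise ValueError(f"unknown genotype codes in rows: {sorted(set(bad))}")

    cond_het = genotype_table[ccol].map(_is_het)
    kept = genotype_table[~cond_het]
    test_het = kept[tcol].map(_is_het)
    ids = (kept["sample_id"] if "sample_id" in kept.columns
           else kept.index.to_series())
    return StratifiedGroups(
        test_snp=test_snp,
        conditioning_snp=conditioning_snp,
        group_homozygous=list(ids[~test_het]),
        group_heterozygous=list(ids[test_het]),
        n_excluded=int(cond_het.sum()),
    )


# --------------------------------------------------------------------------
# rank-sum test

@dataclass
class RankSumResult:
    u_statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str   # "exact" | "normal-approximation-with-tie-correction"


def _exact_rank_sum_p(ranks1_doubled: np.ndarray,
                      all_doubled: np.ndarray) -> float:
    """Exact two-sided p over all equally likely group-1 label assignments.

    Works on doubled midranks (integers even under ties) with the
    Streitberg-Roehmel shift algorithm: count, for each achievable rank sum,
    the number of size-n1 subsets attaining it.
    """
    n1 = ranks1_doubled.size
    total = int(all_doubled.sum())
    # dp[k, s] = number of k-subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for score in all_doubled:
        sc = int(score)
        dp[1:, sc:] += dp[:-1, :total + 1 - sc]
    dist = dp[n1]
    n_subsets = dist.sum()
    obs = int(ranks1_doubled.sum())
    p_le = dist[:obs + 1].sum() / n_subsets
    p_ge = dist[obs:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def rank_sum_test(values_group1, values_group2) -> RankSumResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Uses exact enumeration of the permutation null (valid under ties)
    whenever min(n1, n2) <= 10 and n1 + n2 <= 30; otherwise the normal
    approximation with tie and continuity corrections.  U is reported for
    group 1 (number of (x, y) pairs with x > y, ties counting one half).
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if min(n1, n2) <= EXACT_MIN_N and n1 + n2 <= EXACT_TOTAL_N:
        doubled = np.round(2 * ranks).astype(np.int64)
        p = _exact_rank_sum_p(doubled[:n1], doubled)
        method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:       # all observations tied
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
        method = "normal-approximation-with-tie-correction"
    return RankSumResult(u_statistic=float(u1), n1=n1, n2=n2,
                         p_two_sided=p, method=method)
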