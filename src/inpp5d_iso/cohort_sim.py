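"""Synthetic cohorts, expression states, amplicon reads, qPCR plates and
cycloheximide time courses.

The generator emulates the study design the downstream statistics assume:

* two AD-associated intronic SNPs (rs35349669, minor allele T, MAF 0.498;
  rs10933431, minor allele G, MAF 0.220) in weak linkage disequilibrium
  (r² = 0.18), sampled as haplotype pairs under Hardy–Weinberg equilibrium;
* an unlinked transcribed reporter SNP (rs1141328, G/A) in the 5'UTR used for
  allelic-expression-imbalance (AEI) readout;
* per-sample isoform copy numbers (log-normal) with configurable
  neuropathology (NIARI) fold effects, a D47 splice-variant fraction
  (default mean 0.13 of exon-12-containing transcripts), and a
  haplotype-linked true allelic ratio for reporter heterozygotes;
* amplicon read sets embedding the reporter 16-mer in fixed flanking
  sequence, with binomial allele sampling (unbiased for genomic DNA) and
  uniform substitution errors;
* qPCR Cq observations around a log-linear standard curve; and
* a cycloheximide (CHX) time course in which the fraction of a
  PTC-containing isoform rises linearly with treatment time.

All randomness is routed through integer seeds; a fixed seed reproduces
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeModel",
    "CohortSample",
    "ExpressionState",
    "SimConfig",
    "ChxParams",
    "FastqRead",
    "haplotype_frequencies",
    "simulate_cohort",
    "load_paper_fixture",
    "simulate_expression",
    "simulate_amplicon_reads",
    "simulate_allele_counts",
    "simulate_qpcr_plate",
    "simulate_chx_timecourse",
    "write_fastq",
    "stage_rng",
    "ASSAYS",
    "AMPLICON_LEFT_FLANK",
    "AMPLICON_RIGHT_FLANK",
]

# --------------------------------------------------------------------------
# seeding

def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a per-stage random generator from one global seed.

    The substream is keyed by a CRC32 hash of the stage name so each pipeline
    stage is independently reproducible from the single run seed.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         zlib.crc32(stage.encode())]))


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# haplotype model

@dataclass(frozen=True)
class HaplotypeModel:
    """Two-locus haplotype frequency model parameterized by MAFs and r².

    ``haplotype_freqs`` maps (is_minor_at_A, is_minor_at_B) to the haplotype
    frequency; the four frequencies sum to one and reproduce the marginal
    minor-allele frequencies and the requested squared LD correlation.
    """

    maf_a: float
    maf_b: float
    r2: float
    d: float
    haplotype_freqs: dict

    def as_array(self) -> np.ndarray:
        """Frequencies ordered (mm, mM, Mm, MM); m = minor allele."""
        f = self.haplotype_freqs
        return np.array([f[(True, True)], f[(True, False)],
                         f[(False, True)], f[(False, False)]])


def haplotype_frequencies(maf_a: float, maf_b: float, r2: float,
                          d_sign: int = 1) -> HaplotypeModel:
    """Solve two-locus haplotype frequencies from MAFs and r².

    r² is sign-free, so a coupling convention is required: by default D > 0
    (minor alleles co-occur more often than independence predicts);
    ``d_sign=-1`` couples minor with major.

    Raises ``ValueError`` when the requested r² exceeds the Lewontin bound
    for the given allele frequencies, naming the maximum achievable r².
    """
    if not (0 < maf_a < 1 and 0 < maf_b < 1):
        raise ValueError("MAFs must lie strictly between 0 and 1")
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if d_sign not in (1, -1):
        raise ValueError("d_sign must be +1 or -1")
    pa, qa = maf_a, 1.0 - maf_a
    pb, qb = maf_b, 1.0 - maf_b
    denom = pa * qa * pb * qb
    d = d_sign * math.sqrt(r2 * denom)
    d_max = min(pa * qb, qa * pb) if d_sign > 0 else min(pa * pb, qa * qb)
    if abs(d) > d_max + 1e-12:
        r2_max = d_max ** 2 / denom
        raise ValueError(
            f"r2={r2} not achievable for MAFs ({maf_a}, {maf_b}) with "
            f"d_sign={d_sign:+d}: maximum achievable r2 is {r2_max:.6g}")
    freqs = {
        (True, True): pa * pb + d,
        (True, False): pa * qb - d,
        (False, True): qa * pb - d,
        (False, False): qa * qb + d,
    }
    # clip negative rounding residue
    freqs = {k: max(v, 0.0) for k, v in freqs.items()}
    return HaplotypeModel(maf_a=maf_a, maf_b=maf_b, r2=r2, d=d,
                          haplotype_freqs=freqs)


# --------------------------------------------------------------------------
# cohort

# allele letters, minor first, per SNP
SNP_ALLELES = {
    "rs35349669": ("T", "C"),
    "rs10933431": ("G", "C"),
    "rs1141328": ("G", "A"),   # G:A is the reported ratio orientation
}


def _genotype_string(snp: str, n_minor: int) -> str:
    minor, major = SNP_ALLELES[snp]
    return minor * n_minor + major * (2 - n_minor)


@dataclass
class CohortSample:
    """One subject: genotypes at the three SNPs, pathology class, covariates."""

    sample_id: str
    genotype_rs35349669: str
    genotype_rs10933431: str
    genotype_rs1141328: str
    niari: str            # "low" | "high"
    ad_status: str        # "AD" | "non-AD"
    sex: str              # "M" | "F"
    age_years: float
    pmi_hours: float

    def genotype(self, snp: str) -> str:
        return getattr(self, f"genotype_{snp}")

    def is_heterozygous(self, snp: str) -> bool:
        g = self.genotype(snp)
        return g[0] != g[1]


def simulate_cohort(n: int, haplotype_model: HaplotypeModel,
                    reporter_maf: float = 0.45, ad_fraction: float = 0.5,
                    seed=0) -> list[CohortSample]:
    """Draw a cohort of ``n`` subjects.

    Genotypes at rs35349669/rs10933431 come from two independent haplotypes
    of ``haplotype_model``; the reporter SNP is drawn independently (it is
    not co-inherited with either AD SNP).  Exactly ``round(n*ad_fraction)``
    subjects are AD cases (an exact design split, not a binomial draw), and
    high NIARI neuropathology coincides with AD status, as in the modelled
    cohort.  ``reporter_maf`` is the frequency of the A allele of rs1141328.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= ad_fraction <= 1:
        raise ValueError("ad_fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    probs = haplotype_model.as_array()
    probs = probs / probs.sum()
    hap_idx = rng.choice(4, size=(n, 2), p=probs)
    # haplotype index -> (minor at A?, minor at B?)
    minor_a = (hap_idx <= 1)
    minor_b = (hap_idx % 2 == 0)
    n_minor_a = minor_a.sum(axis=1)
    n_minor_b = minor_b.sum(axis=1)
    rep_alleles = rng.random((n, 2)) < reporter_maf   # True -> A allele
    n_minor_rep = 2 - rep_alleles.sum(axis=1)         # count of G alleles

    n_ad = round(n * ad_fraction)
    ad_flags = np.zeros(n, dtype=bool)
    ad_flags[rng.permutation(n)[:n_ad]] = True

    samples = []
    for i in range(n):
        ad = bool(ad_flags[i])
        age = float(rng.normal(82.0, 6.0 if ad else 9.0))
        pmi = float(max(rng.normal(3.4 if ad else 2.8, 0.6 if ad else 0.9), 0.5))
        samples.append(CohortSample(
            sample_id=f"S{i + 1:03d}",
            genotype_rs35349669=_genotype_string("rs35349669", int(n_minor_a[i])),
            genotype_rs10933431=_genotype_string("rs10933431", int(n_minor_b[i])),
            genotype_rs1141328=_genotype_string("rs1141328", int(n_minor_rep[i])),
            niari="high" if ad else "low",
            ad_status="AD" if ad else "non-AD",
            sex="M" if rng.random() < 0.5 else "F",
            age_years=round(age, 1),
            pmi_hours=round(pmi, 1),
        ))
    return samples


def cohort_to_frame(samples: Sequence[CohortSample]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in samples])


# --------------------------------------------------------------------------
# printed-table fixture

# rs10933431 (rows GG/GC/CC) x rs35349669 (columns TT/TC/CC); 61 samples total
_GENOTYPE_TABLE_CELLS = [[0, 2, 2], [1, 15, 7], [10, 19, 5]]


def load_paper_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged fixture of the study's printed cohort composition.

    Returns ``(genotype_table, cohort_table)``.  The genotype table is the
    published 3x3 cross-tabulation of rs10933431 (rows GG/GC/CC) by
    rs35349669 (columns TT/TC/CC); its cells sum to 61 genotyped samples.
    The cohort table describes the 56-subject expression cohort (28 AD of
    12 M / 16 F, 28 non-AD of 14 M / 14 F) including the 26 rs1141328
    heterozygotes used for AEI (11 AD: 5 M, 6 F; 15 non-AD: 8 M, 7 F).
    The two tables are deliberately kept as distinct artifacts; the source
    counts do not reconcile to a single roster.

    AD-SNP genotypes on the cohort table are a deterministic synthetic
    assignment cycling through the genotype-table cells; only the documented
    marginal counts above are meaningful.
    """
    genotype_table = pd.DataFrame(
        _GENOTYPE_TABLE_CELLS,
        index=pd.Index(["GG", "GC", "CC"], name="rs10933431"),
        columns=pd.Index(["TT", "TC", "CC"], name="rs35349669"),
    )

    # expand the 61 genotype pairs in fixed order, take the first 56
    pairs = []
    for g10, row in genotype_table.iterrows():
        for g35, count in row.items():
            pairs.extend([(g35, g10)] * int(count))
    pairs = pairs[:56]

    rows = []
    idx = 0
    for ad_status, n_m, n_f, het_m, het_f in (("AD", 12, 16, 5, 6),
                                              ("non-AD", 14, 14, 8, 7)):
        ad = ad_status == "AD"
        for sex, n_sex, n_het in (("M", n_m, het_m), ("F", n_f, het_f)):
            for j in range(n_sex):
                het = j < n_het
                g35, g10 = pairs[idx]
                rows.append({
                    "sample_id": f"P{idx + 1:03d}",
                    "genotype_rs35349669": g35,
                    "genotype_rs10933431": g10,
                    "genotype_rs1141328": "GA" if het else ("GG" if j % 2 else "AA"),
                    "niari": "high" if ad else "low",
                    "ad_status": ad_status,
                    "sex": sex,
                    "age_years": 82.0,
                    "pmi_hours": 3.4 if ad else 2.8,
                })
                idx += 1
    cohort_table = pd.DataFrame(rows)
    return genotype_table, cohort_table


# --------------------------------------------------------------------------
# expression states

ASSAYS = ("ex2-ex3", "ex10-ex12", "ex11-ex12", "ex15-ex16", "in14-ex16",
          "D47", "ex26-present", "ITGAM")

# baseline copies per reaction; ex26-present sits ~105x above ex15-ex16, the
# scale the exon-26-retention comparator assay reports
_BASE_COPIES = {
    "ITGAM": 1.0e4,
    "ex2-ex3": 2.0e3,
    "ex10-ex12": 3.0e3,
    "ex11-ex12": 3.0e3,
    "ex15-ex16": 1.0e3,
    "in14-ex16": 2.0e2,
    "ex26-present": 1.047e5,
}


@dataclass
class ChxParams:
    """Cycloheximide time-course generator settings.

    ``baseline`` is the vehicle-arm D47 fraction, ``increment`` the per-hour
    rise under CHX (NMD blocked, the PTC isoform accumulates), with
    ``replicates`` wells per arm at each of ``timepoints`` (hours).
    """

    baseline: float = 0.13
    increment: float = 0.02
    replicates: int = 3
    timepoints: tuple = (1.0, 3.0, 5.0, 8.0)
    noise_sd: float = 0.01


@dataclass
class SimConfig:
    """Generator knobs; defaults are the modelled study conditions.

    ``aei_effect`` is the multiplicative true allelic ratio attached to the
    risk haplotype of ``aei_snp`` (1.0 = no imbalance; the default direction
    has the rs35349669 minor allele increasing expression, sign switchable
    via the effect value itself).  ``niari_fold_effects`` scale mean copies
    of each assay in high-NIARI subjects.  ``d47_fraction`` is the mean
    proportion of exon-12-containing transcripts that are D47.
    """

    seed: int = 0
    depth: int = 10_000
    error_rate: float = 0.005
    read_length: int = 250
    niari_fold_effects: dict = field(
        default_factory=lambda: {a: 1.5 for a in ASSAYS if a != "ITGAM"})
    aei_effect: float = 1.0
    aei_snp: str = "rs35349669"
    d47_fraction: float = 0.13
    d47_fraction_sd: float = 0.03
    microglia_log10_sd: float = 0.5
    assay_log10_sd: float = 0.15
    reference_log10_sd: float = 0.05
    qpcr_sd: float = 0.15
    chx_params: ChxParams = field(default_factory=ChxParams)

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ExpressionState:
    """Latent per-sample truth: copies per assay, D47 fraction, allelic ratio.

    ``allelic_ratio_true`` (G:A) is defined only for reporter-SNP
    heterozygotes; it is None otherwise.
    """

    sample_id: str
    copies: dict
    d47_fraction: float
    allelic_ratio_true: float | None


def simulate_expression(cohort: Sequence[CohortSample], config: SimConfig,
                        seed=None) -> list[ExpressionState]:
    """Draw latent expression states for a cohort.

    Copies per assay are log10-normal around assay baselines scaled by a
    shared per-sample microglial abundance factor (which ITGAM tracks) and
    by the configured NIARI fold effects in high-pathology subjects.  D47
    copies are a noisy fraction (mean ``d47_fraction``) of the ex11-ex12
    assay.  Reporter heterozygotes that are also heterozygous at the
    effect SNP receive a true allelic ratio of ``aei_effect`` or
    ``1/aei_effect`` depending on which reporter allele the risk haplotype
    carries (random phase — the reporter is unlinked); all other reporter
    heterozygotes have ratio 1.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    for assay, fold in config.niari_fold_effects.items():
        if fold <= 0:
            raise ValueError(f"nonpositive NIARI fold effect for {assay}")
    if config.aei_effect <= 0:
        raise ValueError("aei_effect must be > 0")
    rng = _as_rng(config.seed if seed is None else seed)
    states = []
    for s in cohort:
        m = 10.0 ** rng.normal(0.0, config.microglia_log10_sd)
        copies = {}
        for assay in ASSAYS:
            if assay == "D47":
                continue
            base = _BASE_COPIES[assay]
            fold = config.niari_fold_effects.get(assay, 1.0)
            if s.niari == "high":
                base = base * fold
            sd = (config.reference_log10_sd if assay == "ITGAM"
                  else config.assay_log10_sd)
            copies[assay] = base * m * 10.0 ** rng.normal(0.0, sd)
        frac = float(np.clip(rng.normal(config.d47_fraction,
                                        config.d47_fraction_sd), 0.01, 0.9))
        copies["D47"] = frac * copies["ex11-ex12"]

        ratio = None
        if s.is_heterozygous("rs1141328"):
            ratio = 1.0
            if config.aei_effect != 1.0 and s.is_heterozygous(config.aei_snp):
                # unlinked reporter: risk haplotype carries G or A with equal
                # probability; imbalance direction follows the phase
                g_on_risk = rng.random() < 0.5
                ratio = (config.aei_effect if g_on_risk
                         else 1.0 / config.aei_effect)
        states.append(ExpressionState(sample_id=s.sample_id, copies=copies,
                                      d47_fraction=frac,
                                      allelic_ratio_true=ratio))
    return states


# --------------------------------------------------------------------------
# amplicon reads

# Fixed flanking sequence around the reporter 16-mer (synthetic amplicon
# context; constant so simulated read sets are reproducible byte-for-byte).
AMPLICON_LEFT_FLANK = (
    "TAAGCGTTCTGGTGCTAGTGCGCAATCATAACTAGCGTATGTGGTGGATA"
    "CGCGTTCCCCAAGTGGCATTATAAGTATCAGTATCCTTATTAACGACTAA"
)
AMPLICON_RIGHT_FLANK = (
    "TACCCCCCTGGTTGAGGTGGCGATCCTTGGTGTTCGGGTTGTAGTTCCGG"
    "AAGGCCCCACTTTCACGTGGTCCCGTTACCGCAGACTTAATATTATAGTA"
    "TAACATAATTATGTAATGCATTGGAGAGCAAACGAAAACATGTGTGGGGC"
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str


def _allele_fraction(sample: CohortSample, material: str,
                     expression_state: ExpressionState) -> float:
    """True probability that a read carries the G (allele-1) k-mer."""
    g = sample.genotype_rs1141328
    n_g = g.count("G")
    if n_g == 2:
        return 1.0
    if n_g == 0:
        return 0.0
    if material == "gDNA":
        return 0.5
    r = expression_state.allelic_ratio_true
    r = 1.0 if r is None else r
    return r / (1.0 + r)


def simulate_amplicon_reads(sample: CohortSample, material: str,
                            expression_state: ExpressionState,
                            kmer_pair, depth: int, error_rate: float,
                            barcode: str, seed=0,
                            read_length: int = 250) -> list[FastqRead]:
    """Simulate one sample's amplicon read set for the reporter SNP.

    Each read is ``barcode`` + fixed left flank + one allele k-mer + fixed
    right flank, truncated to ``read_length``; the number of allele-1 (G)
    reads is Binomial(depth, p) with p from the sample's true allelic ratio
    for cDNA heterozygotes, 0.5 for gDNA heterozygotes and 0/1 for
    homozygotes.  Substitution errors are applied uniformly per base at
    ``error_rate`` (substitution-only; no indels).
    """
    if material not in ("cDNA", "gDNA"):
        raise ValueError(f"unknown material label: {material!r}")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = _as_rng(seed)
    p = _allele_fraction(sample, material, expression_state)
    n1 = int(rng.binomial(depth, p))

    templates = []
    for kmer in (kmer_pair.kmer_allele1, kmer_pair.kmer_allele2):
        t = (barcode + AMPLICON_LEFT_FLANK + kmer + AMPLICON_RIGHT_FLANK)
        t = t[:read_length]
        templates.append(np.frombuffer(t.encode(), dtype=np.uint8))
    length = templates[0].size

    which = np.zeros(depth, dtype=np.int64)
    which[n1:] = 1
    which = rng.permutation(which)
    mat = np.where(which[:, None] == 0, templates[0][None, :],
                   templates[1][None, :])
    if error_rate > 0:
        err = rng.random((depth, length)) < error_rate
        # substitute with a uniformly chosen different base
        shift = rng.integers(1, 4, size=(depth, length))
        idx = np.searchsorted(_BASES, mat)
        mat = np.where(err, _BASES[(idx + shift) % 4], mat)
    seqs = mat.tobytes().decode()
    reads = [FastqRead(f"{sample.sample_id}:{material}:{i + 1}",
                       seqs[i * length:(i + 1) * length])
             for i in range(depth)]
    return reads


def simulate_allele_counts(sample: CohortSample, material: str,
                           expression_state: ExpressionState,
                           depth: int, seed=0) -> tuple[int, int]:
    """Fast path: draw the (allele1, allele2) read counts directly.

    Identical in distribution to counting error-free simulated reads; used
    for calibration studies where per-read strings are unnecessary.
    """
    if material not in ("cDNA", "gDNA"):
        raise ValueError(f"unknown material label: {material!r}")
    rng = _as_rng(seed)
    p = _allele_fraction(sample, material, expression_state)
    n1 = int(rng.binomial(depth, p))
    return n1, depth - n1


def write_fastq(reads: Iterable[FastqRead], path, quality_char: str = "I"):
    """Write 4-line FASTQ records with constant Phred+33 qualities."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n"
                     f"{quality_char * len(r.sequence)}\n")


# --------------------------------------------------------------------------
# qPCR plates

def simulate_qpcr_plate(expression_states: Sequence[ExpressionState],
                        standard_curve, qpcr_sd: float, seed=0,
                        replicates: int = 3,
                        standard_copies: Sequence[float] = (
                            1e1, 1e2, 1e3, 1e4, 1e5, 1e6)) -> pd.DataFrame:
    """Simulate a qPCR plate table for every assay of every sample.

    Cq = intercept + slope*log10(copies) + Normal(0, qpcr_sd).  The plate
    includes standard-dilution wells (``well_type == "standard"`` with known
    ``copies``) so the curve can be refit from the plate alone.
    """
    if standard_curve.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    rng = _as_rng(seed)
    rows = []

    def cq_of(copies):
        if copies <= 0:
            raise ValueError("copies must be > 0")
        return (standard_curve.intercept
                + standard_curve.slope * math.log10(copies)
                + (rng.normal(0.0, qpcr_sd) if qpcr_sd > 0 else 0.0))

    for copies in standard_copies:
        for rep in range(1, replicates + 1):
            rows.append({"sample_id": "STD", "assay": "standard",
                         "well_type": "standard", "copies": float(copies),
                         "replicate": rep, "cq": cq_of(copies)})
    for st in expression_states:
        for assay, copies in st.copies.items():
            for rep in range(1, replicates + 1):
                rows.append({"sample_id": st.sample_id, "assay": assay,
                             "well_type": "unknown", "copies": np.nan,
                             "replicate": rep, "cq": cq_of(copies)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CHX time course

def simulate_chx_timecourse(chx_params: ChxParams, seed=0) -> pd.DataFrame:
    """Simulate the cycloheximide NMD time course.

    The CHX arm's D47 fraction is baseline + increment*hours + noise
    (truncated to [0, 1]); the vehicle arm stays flat at baseline + noise.
    """
    p = chx_params
    if not 0 <= p.baseline <= 1:
        raise ValueError("baseline must lie in [0, 1]")
    if not p.timepoints:
        raise ValueError("timepoints must be nonempty")
    if p.replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _as_rng(seed)
    rows = []
    for t in p.timepoints:
        for arm in ("CHX", "vehicle"):
            mean = p.baseline + (p.increment * t if arm == "CHX" else 0.0)
            for rep in range(1, p.replicates + 1):
                noise = rng.normal(0.0, p.noise_sd) if p.noise_sd > 0 else 0.0
                rows.append({"time_h": float(t), "treatment": arm,
                             "replicate": rep,
                             "d47_fraction": float(np.clip(mean + noise,
                                                           0.0, 1.0))})
    return pd.DataFrame(rows)
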