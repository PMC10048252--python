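"""Transcript-isoform catalog, primer capture sets, deletion variants,
ORF/PTC annotation, NMD candidacy and amplicon-length prediction.

Coordinates are 1-based, closed intervals in spliced-transcript space.
Exon labels follow the gene's global exon numbering (``ex1`` .. ``ex27``),
with the retained intron-14 segment ``in14`` that serves as the leader of
the TSS-C isoform.  The packaged catalog is a *synthetic* toy catalog: it
reproduces the real gene's isoform topology — full-length isoforms 201/204
(TSS-A, exon 1), the non-coding SH2-only 205, the TSS-B (exon 11) isoform
202, and the non-coding TSS-C (intron 14) isoform 213 — with
deterministically generated sequences, not the real gene sequence.  Exon 12
is sized so that deleting its first 47 nt (the D47 splice variant) shifts
the reading frame, and exons 26/27 are engineered so that skipping exon 26
(D26) shifts frame into the novel 17-residue carboxyl tail reported for
the real variant.  A loader accepts a user-supplied JSON catalog carrying
real sequences in the same schema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "Exon",
    "Deletion",
    "Transcript",
    "IsoformCatalog",
    "PrimerSite",
    "PrimerPair",
    "OrfAnnotation",
    "GLOBAL_SEGMENT_ORDER",
    "D26_NOVEL_TAIL",
    "build_toy_catalog",
    "capture_set",
    "apply_deletion",
    "annotate_orf",
    "nmd_candidate",
    "predict_amplicon_length",
    "catalog_to_json",
    "catalog_from_json",
]

D26_NOVEL_TAIL = "SEALSELPLSREPRGTA"

# global 5'->3' segment ordering; in14 sits between ex14 and ex15
GLOBAL_SEGMENT_ORDER = (
    [f"ex{i}" for i in range(1, 15)] + ["in14"]
    + [f"ex{i}" for i in range(15, 28)]
)
_SEGMENT_INDEX = {label: i for i, label in enumerate(GLOBAL_SEGMENT_ORDER)}

_STOPS = set(standard_dna_table.stop_codons)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
_SENSE_CODONS = sorted(standard_dna_table.forward_table)


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Exon:
    label: str
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.label not in _SEGMENT_INDEX:
            raise ValueError(f"unknown exon/segment label: {self.label!r}")
        if self.length <= 0:
            raise ValueError(f"exon {self.label}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"exon {self.label}: sequence/length mismatch")


@dataclass(frozen=True)
class Deletion:
    """A deletion applied within one exon; offset is 0-based, nt in the exon
    coordinates current at application time."""

    exon_label: str
    offset_nt: int
    length_nt: int


@dataclass(frozen=True)
class Transcript:
    isoform_id: str
    exons: tuple
    tss_label: str | None = None       # "A" | "B" | "C"
    cds_start: int | None = None       # 1-based in spliced transcript
    coding: bool = False
    deletions: tuple = ()
    parent_id: str | None = None

    def __post_init__(self):
        idx = [_SEGMENT_INDEX[e.label] for e in self.exons]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"{self.isoform_id}: exon labels must be "
                             "strictly ordered by the global numbering")
        if self.cds_start is not None and not (
                1 <= self.cds_start <= self.spliced_length):
            raise ValueError(f"{self.isoform_id}: cds_start outside transcript")

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_labels(self) -> tuple:
        return tuple(e.label for e in self.exons)

    @property
    def sequence(self) -> str:
        parts = []
        for e in self.exons:
            if e.sequence is None:
                raise ValueError(f"{self.isoform_id}: exon {e.label} carries "
                                 "no sequence")
            parts.append(e.sequence)
        return "".join(parts)

    def exon(self, label: str) -> Exon:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(label)

    def exon_start(self, label: str) -> int:
        """1-based spliced coordinate of the exon's first base."""
        pos = 1
        for e in self.exons:
            if e.label == label:
                return pos
            pos += e.length
        raise KeyError(label)


@dataclass
class IsoformCatalog:
    """Transcripts plus primer-pair and domain annotations."""

    transcripts: dict
    capture_pairs: dict = field(default_factory=dict)     # name -> (a1, a2)
    primer_pairs: dict = field(default_factory=dict)      # name -> PrimerPair
    annotations: dict = field(default_factory=dict)

    def __getitem__(self, isoform_id: str) -> Transcript:
        return self.transcripts[isoform_id]

    def tss_isoforms(self) -> dict:
        out: dict[str, set] = {}
        for t in self.transcripts.values():
            if t.tss_label:
                out.setdefault(t.tss_label, set()).add(t.isoform_id)
        return out

    def capture_table(self) -> dict:
        return {name: capture_set(pair, self)
                for name, pair in self.capture_pairs.items()}


@dataclass(frozen=True)
class PrimerSite:
    """A primer footprint anchored in original-exon coordinates (1-based)."""

    exon_label: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: PrimerSite
    reverse: PrimerSite


@dataclass
class OrfAnnotation:
    protein: str
    frameshift: bool
    ptc_position: int | None      # 1-based codon index of the premature stop
    novel_tail: str
    nmd_candidate: bool
    non_stop: bool                # no stop codon before transcript end
    deletions: tuple


# --------------------------------------------------------------------------
# capture sets

def capture_set(primer_pair, catalog: IsoformCatalog) -> set:
    """Isoforms a primer pair amplifies.

    An isoform is captured iff it contains both anchors and every *exon*
    between them in the global numbering (a missing internal exon breaks the
    amplicon as drawn; retained-intron segments are not required).
    """
    a1, a2 = primer_pair
    for a in (a1, a2):
        if a not in _SEGMENT_INDEX:
            raise ValueError(f"unknown anchor: {a!r}")
    i1, i2 = sorted((_SEGMENT_INDEX[a1], _SEGMENT_INDEX[a2]))
    required_between = [lab for lab in GLOBAL_SEGMENT_ORDER[i1 + 1:i2]
                        if lab.startswith("ex")]
    captured = set()
    for t in catalog.transcripts.values():
        labels = set(t.exon_labels)
        if (GLOBAL_SEGMENT_ORDER[i1] in labels
                and GLOBAL_SEGMENT_ORDER[i2] in labels
                and all(lab in labels for lab in required_between)):
            captured.add(t.isoform_id)
    return captured


# --------------------------------------------------------------------------
# deletions

def apply_deletion(transcript: Transcript, exon_label: str, offset_nt: int,
                   length_nt: int, variant_id: str | None = None) -> Transcript:
    """Delete ``length_nt`` bases starting at 0-based ``offset_nt`` of the
    named exon; a whole-exon skip is offset 0, length = exon length.

    The spliced length shrinks by exactly ``length_nt``; the exon is removed
    entirely when fully deleted.  ``cds_start`` shifts left by the number of
    deleted bases upstream of it.  A zero-length deletion returns an
    identical transcript.
    """
    exon = transcript.exon(exon_label)
    if offset_nt < 0 or length_nt < 0:
        raise ValueError("offset and length must be >= 0")
    if offset_nt + length_nt > exon.length:
        raise ValueError(
            f"deletion {exon_label}:{offset_nt}+{length_nt} exceeds the "
            f"exon boundary (length {exon.length})")
    if length_nt == 0:
        return replace(transcript)

    new_exons = []
    for e in transcript.exons:
        if e.label != exon_label:
            new_exons.append(e)
            continue
        new_len = e.length - length_nt
        if new_len == 0:
            continue
        seq = None
        if e.sequence is not None:
            seq = e.sequence[:offset_nt] + e.sequence[offset_nt + length_nt:]
        new_exons.append(Exon(e.label, new_len, seq))

    del_spliced_start = transcript.exon_start(exon_label) + offset_nt
    cds = transcript.cds_start
    if cds is not None and del_spliced_start <= cds:
        cds -= min(length_nt, cds - del_spliced_start)
        cds = max(cds, 1)
    vid = variant_id or (f"{transcript.isoform_id}-del-"
                         f"{exon_label}:{offset_nt}:{length_nt}")
    return Transcript(
        isoform_id=vid,
        exons=tuple(new_exons),
        tss_label=transcript.tss_label,
        cds_start=cds,
        coding=transcript.coding,
        deletions=transcript.deletions + (
            Deletion(exon_label, offset_nt, length_nt),),
        parent_id=transcript.isoform_id,
    )


# --------------------------------------------------------------------------
# ORF annotation

def _translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate from the first base; returns (protein, stop_found)."""
    trimmed = seq[:len(seq) - len(seq) % 3]
    aa = str(Seq(trimmed).translate())
    if "*" in aa:
        return aa.split("*", 1)[0], True
    return aa, False


def annotate_orf(transcript: Transcript, reference: Transcript | None = None,
                 nmd_threshold_nt: int = 50) -> OrfAnnotation:
    """Translate a transcript and flag frameshift / PTC / novel tail.

    ``reference`` is the undisturbed parent transcript; a stop is premature
    when the variant protein is shorter than the reference protein, and the
    novel tail is everything after the last residue identical to the
    reference (longest common prefix).  A transcript without a stop before
    its end is flagged ``non_stop`` rather than raising.
    """
    if transcript.cds_start is None:
        raise ValueError(f"{transcript.isoform_id}: no cds_start; cannot "
                         "annotate an ORF")
    protein, stop_found = _translate_to_stop(
        transcript.sequence[transcript.cds_start - 1:])
    frameshift = any(d.length_nt % 3 != 0 for d in transcript.deletions)

    ptc_position = None
    novel_tail = ""
    if reference is not None:
        if reference.cds_start is None:
            raise ValueError("reference transcript must be coding")
        ref_protein, _ = _translate_to_stop(
            reference.sequence[reference.cds_start - 1:])
        if stop_found and len(protein) < len(ref_protein):
            ptc_position = len(protein) + 1
        if frameshift:
            lcp = 0
            for a, b in zip(protein, ref_protein):
                if a != b:
                    break
                lcp += 1
            novel_tail = protein[lcp:]

    nmd = (nmd_candidate(transcript, ptc_position, nmd_threshold_nt)
           if ptc_position is not None else False)
    return OrfAnnotation(protein=protein, frameshift=frameshift,
                         ptc_position=ptc_position, novel_tail=novel_tail,
                         nmd_candidate=nmd, non_stop=not stop_found,
                         deletions=transcript.deletions)


def nmd_candidate(transcript: Transcript, ptc_position: int,
                  rule_threshold_nt: int = 50) -> bool:
    """Apply the last-exon-junction rule for nonsense-mediated decay.

    True iff the premature stop codon ends more than ``rule_threshold_nt``
    nucleotides (strict inequality) upstream of the final exon-exon
    junction.  A PTC in the last exon — or any stop in a single-exon
    transcript — is not an NMD trigger.
    """
    if ptc_position is None or ptc_position < 1:
        raise ValueError("ptc_position must be a positive codon index")
    if len(transcript.exons) < 2:
        return False
    if transcript.cds_start is None:
        raise ValueError("transcript must carry cds_start")
    ptc_end_nt = transcript.cds_start - 1 + 3 * ptc_position
    last_junction = transcript.spliced_length - transcript.exons[-1].length
    if ptc_end_nt > last_junction:
        return False
    return (last_junction - ptc_end_nt) > rule_threshold_nt


# --------------------------------------------------------------------------
# amplicon lengths

def _map_exon_position(transcript: Transcript, exon_label: str,
                       pos: int) -> int | None:
    """Map a 1-based position in *original* exon coordinates to the spliced
    coordinate on ``transcript``; None when the exon or the base is absent.

    Recorded deletions are replayed in application order, so coordinates
    compose correctly for sequential deletions.
    """
    for d in transcript.deletions:
        if d.exon_label != exon_label:
            continue
        if d.offset_nt < pos <= d.offset_nt + d.length_nt:
            return None
        if pos > d.offset_nt + d.length_nt:
            pos -= d.length_nt
    if exon_label not in transcript.exon_labels:
        return None
    return transcript.exon_start(exon_label) + pos - 1


def predict_amplicon_length(primer_pair: PrimerPair,
                            transcript: Transcript,
                            reference: Transcript | None = None) -> int | None:
    """PCR product length of a primer pair on a transcript, or None.

    Primer footprints are given in original-exon coordinates of the
    reference isoform.  No product results when either primer's exon is
    absent or its footprint is disrupted by a deletion; a deletion between
    the primers shortens the product by the deleted overlap.  Positions
    beyond the original exon boundary are an error.
    """
    ref = reference if reference is not None else transcript
    for site in (primer_pair.forward, primer_pair.reverse):
        if site.exon_label not in _SEGMENT_INDEX:
            raise ValueError(f"unknown anchor exon: {site.exon_label!r}")
        orig_len = _original_exon_length(transcript, ref, site.exon_label)
        if orig_len is not None and (site.start < 1 or site.end > orig_len):
            raise ValueError(
                f"primer {primer_pair.name}: site {site.exon_label}:"
                f"{site.start}-{site.end} out of exon bounds (1-{orig_len})")

    ends = []
    for site, pick in ((primer_pair.forward, "start"),
                       (primer_pair.reverse, "end")):
        a = _map_exon_position(transcript, site.exon_label, site.start)
        b = _map_exon_position(transcript, site.exon_label, site.end)
        if a is None or b is None or (b - a + 1) != site.length:
            return None                      # footprint lost or disrupted
        ends.append(a if pick == "start" else b)
    start, end = ends
    if end <= start:
        return None
    return end - start + 1


def _original_exon_length(transcript: Transcript, reference: Transcript,
                          label: str) -> int | None:
    """Pre-deletion length of an exon, or None when it is unknowable
    (exon absent from both the transcript and the reference)."""
    if label in reference.exon_labels:
        return reference.exon(label).length
    deleted = sum(d.length_nt for d in transcript.deletions
                  if d.exon_label == label)
    if label in transcript.exon_labels:
        return transcript.exon(label).length + deleted
    return deleted or None


# --------------------------------------------------------------------------
# toy catalog construction

# exon lengths (nt); ex12 >= 48 so the D47 deletion stays internal, exon 26
# not a multiple of 3 so skipping it shifts frame
_EXON_LENGTHS = {
    **{f"ex{i}": 60 for i in range(1, 9)},
    "ex9": 120, "ex10": 150, "ex11": 99, "ex12": 150, "ex13": 81,
    "ex14": 69, "ex15": 90, "ex16": 90,
    **{f"ex{i}": 60 for i in range(17, 26)},
    "ex26": 44, "ex27": 120,
}
_IN14_LENGTH = 50
_CDS_START = 31        # 30 nt 5'UTR in exon 1
_TOY_SEED = 70311


def _shifted_stop_free(t: str) -> bool:
    """No stop codon in the +1-shifted frame (codons starting at base 2)."""
    return all(t[i:i + 3] not in _STOPS for i in range(1, len(t) - 2, 3))


def _encode_tail(peptide: str) -> str:
    """Choose codons for the tail peptide avoiding shifted-frame stops."""
    s = ""
    for aa in peptide:
        for codon in _AA_TO_CODONS[aa]:
            if _shifted_stop_free(s + codon):
                s = s + codon
                break
        else:   # pragma: no cover - cannot happen for this peptide
            raise AssertionError(f"no stop-free codon for {aa}")
    return s


def _random_bases(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _random_sense_codons(rng, n: int) -> str:
    return "".join(_SENSE_CODONS[i]
                   for i in rng.integers(0, len(_SENSE_CODONS), n))


def build_toy_catalog() -> IsoformCatalog:
    """Build the packaged synthetic isoform catalog (deterministic).

    Topology and capture behaviour mirror the real gene; sequences are
    engineered so that (a) the reading frame is open from the CDS start in
    exon 1 through a designed stop in exon 27, (b) skipping exon 26 (44 nt,
    frame-shifting) reads exon 27 in the +1 frame as the 17-residue novel
    tail ``SEALSELPLSREPRGTA`` followed by a stop, and (c) primer pairs
    spanning exon 9-12 and exon 11-12 give 458/224 nt products that shrink
    to 411/177 nt on the D47 (del 47 nt of exon 12) variant.
    """
    rng = np.random.default_rng(_TOY_SEED)

    utr5 = _random_bases(rng, _CDS_START - 1)
    # CDS through exon 25 ends exactly on a codon boundary
    n_codons_prefix = (sum(_EXON_LENGTHS[f"ex{i}"] for i in range(1, 26))
                       - (_CDS_START - 1)) // 3
    cds_prefix = "ATG" + _random_sense_codons(rng, n_codons_prefix - 1)
    # first exon-26 codon fixed to Gly so the reference protein diverges from
    # the D26 tail (which begins with Ser) at the first post-junction residue
    ex26_seq = "GGT" + _random_sense_codons(rng, 13) + "CA"   # 44 nt, 2-nt carry
    tail_nt = _encode_tail(D26_NOVEL_TAIL)               # 51 nt
    # exon 27: tail + variant stop; then one pad base and the reference-frame
    # stop (the +1 frame reads ...AAA TAA), then 3'UTR filler
    ex27_seq = tail_nt + "TAA" + "A" + "TAA" + _random_bases(rng, 62)
    assert len(ex27_seq) == _EXON_LENGTHS["ex27"]

    spliced_201 = utr5 + cds_prefix + ex26_seq + ex27_seq
    assert len(spliced_201) == sum(_EXON_LENGTHS.values())

    exons = {}
    pos = 0
    for i in range(1, 28):
        label = f"ex{i}"
        length = _EXON_LENGTHS[label]
        exons[label] = Exon(label, length, spliced_201[pos:pos + length])
        pos += length
    in14 = Exon("in14", _IN14_LENGTH, _random_bases(rng, _IN14_LENGTH))

    def make(iso_id, labels, tss, cds_start, coding):
        return Transcript(
            isoform_id=iso_id,
            exons=tuple(in14 if lab == "in14" else exons[lab]
                        for lab in labels),
            tss_label=tss, cds_start=cds_start, coding=coding)

    all_ex = [f"ex{i}" for i in range(1, 28)]
    transcripts = {
        "201": make("201", all_ex, "A", _CDS_START, True),
        "204": make("204", all_ex, "A", _CDS_START, True),
        "205": make("205", [f"ex{i}" for i in range(1, 7)], "A", None, False),
        "202": make("202", [f"ex{i}" for i in range(11, 28)], "B", 1, True),
        "213": make("213", ["in14"] + [f"ex{i}" for i in range(15, 28)],
                    "C", None, False),
    }

    capture_pairs = {
        "ex2-ex3": ("ex2", "ex3"),
        "ex10-ex12": ("ex10", "ex12"),
        "ex11-ex12": ("ex11", "ex12"),
        "ex15-ex16": ("ex15", "ex16"),
        "in14-ex16": ("in14", "ex16"),
    }
    primer_pairs = {
        "ex9-ex12": PrimerPair("ex9-ex12",
                               PrimerSite("ex9", 62, 20),
                               PrimerSite("ex12", 131, 20)),
        "ex11-ex12": PrimerPair("ex11-ex12",
                                PrimerSite("ex11", 26, 20),
                                PrimerSite("ex12", 131, 20)),
    }
    annotations = {
        "sh2_domain_exons": ["ex2", "ex6"],
        "phosphatase_domain_exons": ["ex11", "ex19"],
        "d26_novel_tail": D26_NOVEL_TAIL,
    }
    return IsoformCatalog(transcripts=transcripts,
                          capture_pairs=capture_pairs,
                          primer_pairs=primer_pairs,
                          annotations=annotations)


def d47_variant(catalog: IsoformCatalog,
                parent: str = "201") -> Transcript:
    """The D47 splice variant: first 47 nt of exon 12 removed."""
    return apply_deletion(catalog[parent], "ex12", 0, 47,
                          variant_id=f"{parent}-D47")


def d26_variant(catalog: IsoformCatalog,
                parent: str = "201") -> Transcript:
    """The D26 splice variant: exon 26 skipped entirely."""
    ex26 = catalog[parent].exon("ex26")
    return apply_deletion(catalog[parent], "ex26", 0, ex26.length,
                          variant_id=f"{parent}-D26")


# --------------------------------------------------------------------------
# JSON schema

SCHEMA_VERSION = 1


def catalog_to_json(catalog: IsoformCatalog, path=None) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "transcripts": [
            {
                "isoform_id": t.isoform_id,
                "tss": t.tss_label,
                "coding": t.coding,
                "cds_start": t.cds_start,
                "exons": [{"label": e.label, "length": e.length,
                           **({"sequence": e.sequence}
                              if e.sequence is not None else {})}
                          for e in t.exons],
            }
            for _, t in sorted(catalog.transcripts.items())
        ],
        "capture_pairs": {k: list(v)
                          for k, v in sorted(catalog.capture_pairs.items())},
        "primer_pairs": {
            name: {"forward": dataclasses.asdict(p.forward),
                   "reverse": dataclasses.asdict(p.reverse)}
            for name, p in sorted(catalog.primer_pairs.items())},
        "annotations": catalog.annotations,
    }
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def catalog_from_json(source) -> IsoformCatalog:
    """Load a catalog from a JSON string or file path."""
    is_path = isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source
        and not source.lstrip().startswith("{"))
    if is_path:
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"catalog schema version {version!r} is not "
                         f"supported (expected {SCHEMA_VERSION}); migrate "
                         "the file first")
    transcripts = {}
    for td in doc["transcripts"]:
        transcripts[td["isoform_id"]] = Transcript(
            isoform_id=td["isoform_id"],
            exons=tuple(Exon(e["label"], e["length"], e.get("sequence"))
                        for e in td["exons"]),
            tss_label=td.get("tss"),
            cds_start=td.get("cds_start"),
            coding=bool(td.get("coding", False)),
        )
    primer_pairs = {
        name: PrimerPair(name,
                         PrimerSite(**pd["forward"]),
                         PrimerSite(**pd["reverse"]))
        for name, pd in doc.get("primer_pairs", {}).items()}
    return IsoformCatalog(
        transcripts=transcripts,
        capture_pairs={k: tuple(v)
                       for k, v in doc.get("capture_pairs", {}).items()},
        primer_pairs=primer_pairs,
        annotations=doc.get("annotations", {}),
    )
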