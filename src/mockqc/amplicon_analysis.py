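"""16S rRNA V4 amplicon quantification and primer-editing analysis.

Amplicons of the V4 hypervariable region are produced by the 515F/806R
primer pair.  Reference sequence variants are extracted from full-length
16S genes by locating the primer sites (IUPAC-degenerate matching, no
indels); merged reads are annotated against the variants at a >=97%
identity threshold; per-strain counts are corrected for 16S gene copy
number to yield a genome-level composition.

Proof-reading polymerases can "edit" primer-template mismatches during PCR,
so the primer-region bases of a raw read may match the template rather than
the synthesized primer.  ``classify_primer_regions`` compares the leading
19 bp (forward) or 20 bp (reverse) of raw reads against both expectations
by Hamming distance and classifies each read as edited-perfect,
unedited-perfect, or mismatch (reads containing undetermined N bases always
count as mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .compositional_stats import Composition
from .reference_data import MockReference

__all__ = [
    "IUPAC",
    "PrimerPair",
    "AmpliconReference",
    "PrimerRegionCall",
    "extract_amplicons",
    "expected_errors",
    "annotate_reads",
    "AnnotationResult",
    "copy_number_correct",
    "classify_primer_regions",
    "resolve_primer",
    "revcomp",
]

#: IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FORWARD_515F = "GTGYCAGCMGCCGCGGTAA"
REVERSE_806R = "GGACTACNVGGGTWTCTAAT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Locus-specific parts of the V4 amplification primers."""

    forward: str = FORWARD_515F
    reverse: str = REVERSE_806R

    def __post_init__(self) -> None:
        if len(self.forward) != 19 or len(self.reverse) != 20:
            raise ValueError("expected 19 nt forward and 20 nt reverse primer parts")
        for p in (self.forward, self.reverse):
            if any(b not in IUPAC for b in p):
                raise ValueError(f"non-IUPAC character in primer {p!r}")


def _iupac_mismatches(pattern: str, text: str) -> int:
    """Hamming distance of equal-length strings under IUPAC degeneracy in ``pattern``."""
    return sum(t not in IUPAC[p] for p, t in zip(pattern, text))


def _find_site(seq: str, pattern: str, max_mismatch: int, start: int = 0) -> int:
    """Leftmost position where ``pattern`` matches with <= max_mismatch; -1 if none."""
    n, m = len(seq), len(pattern)
    for i in range(start, n - m + 1):
        if _iupac_mismatches(pattern, seq[i : i + m]) <= max_mismatch:
            return i
    return -1


@dataclass
class AmpliconReference:
    """Unique V4 sequence variants per strain, with 16S copy number."""

    strain_id: str
    variants: tuple[str, ...]
    n_16s: int = 1
    shared_with: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.variants)) != len(self.variants):
            raise ValueError(f"{self.strain_id}: duplicate variants")


def _strain_of(record) -> str:
    for token in f"{record.id} {record.description}".split():
        if token.startswith("strain="):
            return token.split("=", 1)[1]
    return record.id.split("|")[0]


def extract_amplicons(
    rrna_sequences: str | Path | Mapping[str, Sequence[str]],
    primers: PrimerPair | None = None,
    max_error_rate: float = 0.2,
    ref: MockReference | None = None,
) -> dict[str, AmpliconReference]:
    """Trim 16S gene sequences to the expected V4 amplicon inserts.

    The forward primer site and the reverse-complemented reverse primer site
    are located by IUPAC-degenerate matching allowing up to
    ``floor(max_error_rate * len(primer))`` mismatches and no indels; both
    strands are searched.  The insert between (exclusive of) the primer
    sites is kept, deduplicated per strain.  Identical inserts shared by
    multiple strains are retained under each and flagged via ``shared_with``.

    ``rrna_sequences`` is a FASTA path (strain taken from a ``strain=ID``
    token or the record id before the first ``|``) or a mapping of strain id
    to gene sequences.  Sequences without both primer sites are skipped with
    a warning.
    """
    import warnings

    primers = primers or PrimerPair()
    if not isinstance(rrna_sequences, Mapping):
        seqs: dict[str, list[str]] = {}
        for rec in SeqIO.parse(str(rrna_sequences), "fasta"):
            seqs.setdefault(_strain_of(rec), []).append(str(rec.seq).upper())
    else:
        seqs = {k: [s.upper() for s in v] for k, v in rrna_sequences.items()}

    fw = primers.forward
    rv_rc = revcomp(primers.reverse)
    max_mm_fw = int(max_error_rate * len(primers.forward))
    max_mm_rv = int(max_error_rate * len(primers.reverse))

    inserts: dict[str, list[str]] = {}
    for strain, gene_seqs in seqs.items():
        for gene in gene_seqs:
            insert = None
            for oriented in (gene, revcomp(gene)):
                i = _find_site(oriented, fw, max_mm_fw)
                if i < 0:
                    continue
                j = _find_site(oriented, rv_rc, max_mm_rv, start=i + len(fw))
                if j < 0:
                    continue
                insert = oriented[i + len(fw) : j]
                break
            if insert is None:
                warnings.warn(f"{strain}: primer sites not found; sequence skipped", stacklevel=2)
                continue
            if insert not in inserts.setdefault(strain, []):
                inserts[strain].append(insert)

    by_insert: dict[str, list[str]] = {}
    for strain, variants in inserts.items():
        for v in variants:
            by_insert.setdefault(v, []).append(strain)
    out = {}
    for strain, variants in inserts.items():
        shared = sorted(
            {s for v in variants for s in by_insert[v] if s != strain}
        )
        n16 = ref.get(strain).n_16s if ref is not None and strain in ref else 1
        out[strain] = AmpliconReference(
            strain_id=strain, variants=tuple(variants), n_16s=n16, shared_with=tuple(shared)
        )
    return out


def expected_errors(quality_scores: Sequence[int] | np.ndarray) -> float:
    """Expected number of base errors of a read, ``sum 10^(-Q/10)``."""
    q = np.asarray(quality_scores, dtype=float)
    if q.size and q.min() < 0:
        raise ValueError("phred scores must be >= 0")
    return float(np.sum(10.0 ** (-q / 10.0)))


# ---------------------------------------------------------------------------
# read annotation
# ---------------------------------------------------------------------------

def _identity(read: str, ref: str, aligner: Align.PairwiseAligner) -> float:
    """Fraction of matching columns; Hamming for equal lengths, else
    end-gap-free global alignment (matches / non-end-gap columns)."""
    if len(read) == len(ref):
        mism = sum(a != b for a, b in zip(read, ref))
        return 1.0 - mism / len(ref)
    aln = aligner.align(read, ref)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    start, end = 0, len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(a == b and a != "-" for a, b in zip(s1[start:end], s2[start:end]))
    return matches / (end - start)


@dataclass
class AnnotationResult:
    """Per-strain read counts from amplicon annotation."""

    counts: dict[str, int]
    n_ambiguous: int
    n_unassigned: int
    n_total: int
    assignments: dict[str, str | None] = field(default_factory=dict)


def annotate_reads(
    reads: Iterable[tuple[str, str]] | str | Path,
    refs: Mapping[str, AmpliconReference],
    min_identity: float = 0.97,
) -> AnnotationResult:
    """Assign merged amplicon reads to reference variants by best identity.

    Each read goes to the strain of the best-identity variant meeting
    ``min_identity``; counts over a strain's variants are combined.  Reads
    whose best identity is achieved by variants of two or more strains are
    counted as ambiguous and excluded from per-strain counts; reads below
    the threshold are unassigned.
    """
    if not refs:
        raise ValueError("empty reference set")
    if isinstance(reads, (str, Path)):
        fmt = "fastq" if str(reads).endswith(("fastq", "fq")) else "fasta"
        reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(reads), fmt)]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0

    variant_index = [
        (strain, v) for strain, r in refs.items() for v in r.variants
    ]
    counts = {strain: 0 for strain in refs}
    n_amb = n_un = n_total = 0
    assignments: dict[str, str | None] = {}
    for read_id, seq in reads:
        n_total += 1
        best, best_strains = -1.0, set()
        for strain, variant in variant_index:
            ident = _identity(seq, variant, aligner)
            if ident > best + 1e-12:
                best, best_strains = ident, {strain}
            elif abs(ident - best) <= 1e-12:
                best_strains.add(strain)
        if best + 1e-12 < min_identity:
            n_un += 1
            assignments[read_id] = None
        elif len(best_strains) > 1:
            n_amb += 1
            assignments[read_id] = None
        else:
            strain = next(iter(best_strains))
            counts[strain] += 1
            assignments[read_id] = strain
    return AnnotationResult(
        counts=counts,
        n_ambiguous=n_amb,
        n_unassigned=n_un,
        n_total=n_total,
        assignments=assignments,
    )


def copy_number_correct(counts: Mapping[str, float], ref: MockReference) -> Composition:
    """Divide per-strain read counts by 16S copy number and close to percent."""
    unknown = [s for s in counts if s not in ref]
    if unknown:
        raise ValueError(f"strains not in registry: {sorted(unknown)}")
    corrected = {s: c / ref.get(s).n_16s for s, c in counts.items() if c > 0}
    if not corrected:
        raise ValueError("no nonzero counts to correct")
    return Composition(tuple(corrected), np.array(list(corrected.values())))


# ---------------------------------------------------------------------------
# primer editing
# ---------------------------------------------------------------------------

def resolve_primer(primer: str, template: str) -> str:
    """Synthesized-primer expectation: degenerate positions follow the
    template where compatible; fixed positions keep the primer base."""
    if len(primer) != len(template):
        raise ValueError("primer and template lengths differ")
    out = []
    for p, t in zip(primer, template):
        opts = IUPAC[p]
        if len(opts) == 1:
            out.append(opts)
        elif t in opts:
            out.append(t)
        else:
            out.append(opts[0])
    return "".join(out)


@dataclass(frozen=True)
class PrimerRegionCall:
    """Classification of one raw read's primer-region prefix."""

    read_id: str
    strain_id: str
    end: str  # "forward" | "reverse"
    observed_prefix: str
    hamming_d_edited: int
    hamming_d_unedited: int
    klass: str  # "edited_perfect" | "unedited_perfect" | "mismatch"
    degenerate_indistinguishable: bool = False


def classify_primer_regions(
    raw_reads: Iterable[tuple[str, str, str]],
    primers: PrimerPair | None = None,
    template_prefixes: Mapping[str, str] | None = None,
    end: str = "forward",
) -> tuple[list[PrimerRegionCall], dict]:
    """Classify primer regions of raw reads as edited / unedited / mismatch.

    ``raw_reads`` yields ``(read_id, strain_id, sequence)`` with the primer
    region at the 5' end; ``template_prefixes`` maps each strain to its true
    (edited) primer-region sequence.  Each prefix of length 19 (forward) or
    20 (reverse) is compared by Hamming distance to the template and to the
    synthesized primer resolved against the template.  Reads with an N in
    the prefix are mismatches regardless of other positions; when template
    and resolved primer coincide, editing is undetectable and perfect reads
    are reported unedited with a degenerate flag.

    Returns the calls and a summary with, per strain, the fraction edited
    among perfect (d == 0) calls.
    """
    primers = primers or PrimerPair()
    if template_prefixes is None:
        raise ValueError("template_prefixes are required")
    if end not in ("forward", "reverse"):
        raise ValueError("end must be 'forward' or 'reverse'")
    primer = primers.forward if end == "forward" else primers.reverse
    k = len(primer)

    calls: list[PrimerRegionCall] = []
    for read_id, strain_id, seq in raw_reads:
        if len(seq) < k:
            raise ValueError(f"read {read_id} shorter than primer region ({k} nt)")
        prefix = seq[:k].upper()
        template = template_prefixes[strain_id].upper()
        unedited = resolve_primer(primer, template)
        d_e = sum(a != b for a, b in zip(prefix, template))
        d_u = sum(a != b for a, b in zip(prefix, unedited))
        degenerate = template == unedited
        if "N" in prefix:
            klass = "mismatch"
        elif degenerate:
            klass = "unedited_perfect" if d_u == 0 else "mismatch"
        elif d_e == 0:
            klass = "edited_perfect"
        elif d_u == 0:
            klass = "unedited_perfect"
        else:
            klass = "mismatch"
        calls.append(
            PrimerRegionCall(
                read_id=read_id,
                strain_id=strain_id,
                end=end,
                observed_prefix=prefix,
                hamming_d_edited=d_e,
                hamming_d_unedited=d_u,
                klass=klass,
                degenerate_indistinguishable=degenerate,
            )
        )

    summary: dict[str, dict[str, float | int]] = {}
    for strain in {c.strain_id for c in calls}:
        cs = [c for c in calls if c.strain_id == strain]
        n_e = sum(c.klass == "edited_perfect" for c in cs)
        n_u = sum(c.klass == "unedited_perfect" for c in cs)
        n_m = sum(c.klass == "mismatch" for c in cs)
        perfect = n_e + n_u
        summary[strain] = {
            "n_reads": len(cs),
            "n_edited_perfect": n_e,
            "n_unedited_perfect": n_u,
            "n_mismatch": n_m,
            "pct_edited_of_perfect": 100.0 * n_e / perfect if perfect else float("nan"),
        }
    return calls, summary
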