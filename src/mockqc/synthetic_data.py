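"""Synthetic inputs with known ground truth for every pipeline stage.

Real mock-community sequencing data live in public archives; for testing
and demonstration the package instead generates every input it consumes —
genomes, 16S amplicon reads, quality-annotated shotgun read pairs and noisy
replicate profiles — from explicit generative models whose parameters are
the ground truth against which downstream modules are scored.

Two small models control the bias structure:

* :class:`NoiseModel` — replicate profiles are logistic-normal around the
  assigned composition (clr-space normal with configurable sd), optionally
  pre-multiplied by per-strain efficiency factors emulating protocol bias
  such as poor Gram-positive lysis in non-standard DNA extractions.
* :class:`QualityModel` — per-cycle phred scores follow a plateau with
  positional decay, Gaussian jitter, an optional abrupt mid-read quality
  drop, and an optional offset proportional to read GC fraction that
  couples base quality to genomic GC (negative values reproduce the
  GC-linked read-loss bias of stringent trimming).

Every generator is deterministic under a fixed seed and reports its
parameters alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acceptance_simulation import simulate_measured
from .amplicon_analysis import AmpliconReference, PrimerPair, resolve_primer, revcomp
from .compositional_stats import Composition, ProfileSet, closure
from .read_preprocessing_bias import LabeledReadPair, Mate
from .reference_data import MockReference

__all__ = [
    "NoiseModel",
    "QualityModel",
    "make_genome",
    "simulate_profile",
    "simulate_reads",
    "simulate_amplicon_reads",
    "AmpliconRead",
]

PHRED_MIN, PHRED_MAX = 2, 40


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise and protocol bias for replicate profiles."""

    profile_clr_sd: float = 0.05
    protocol_bias: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_clr_sd < 0:
            raise ValueError("profile_clr_sd must be >= 0")
        if self.protocol_bias is not None and any(
            v <= 0 for v in self.protocol_bias.values()
        ):
            raise ValueError("protocol bias factors must be > 0")


@dataclass(frozen=True)
class QualityModel:
    """Per-cycle phred score model; scores are clipped to [2, 40]."""

    base_quality: float = 36.0
    positional_decay: float = 0.02  # phred lost per cycle
    gc_penalty: float = 0.0  # phred offset per unit read GC fraction
    noise_sd: float = 2.0
    low_quality_run_prob: float = 0.0
    low_quality_run_start: int = 65
    low_quality_run_severity: float = 20.0

    def sample(self, rng: np.random.Generator, read_len: int, read_gc: float) -> np.ndarray:
        cycles = np.arange(read_len)
        q = (
            self.base_quality
            - self.positional_decay * cycles
            + self.gc_penalty * read_gc
            + rng.normal(0.0, self.noise_sd, size=read_len)
        )
        if self.low_quality_run_prob > 0 and rng.random() < self.low_quality_run_prob:
            q[self.low_quality_run_start :] -= self.low_quality_run_severity
        return np.clip(np.rint(q), PHRED_MIN, PHRED_MAX).astype(int)


def make_genome(length: int, gc_fraction: float, seed: int = 0) -> str:
    """Random genome with i.i.d. bases, P(G) = P(C) = gc_fraction / 2."""
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list("AGCT"), size=length, p=p))


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def simulate_profile(
    ref: MockReference,
    noise: NoiseModel,
    n_replicates: int,
    lab: str = "LabA",
    extraction_protocol: str = "sop",
    library_protocol: str = "sop",
    assay: str = "metagenome",
    sample_prefix: str = "rep",
) -> ProfileSet:
    """Replicate measurement profiles around a known center.

    The center is the closed assigned composition, multiplied by the
    protocol-bias factors (then re-closed) when a bias is active; draws are
    logistic-normal with per-strain clr sd ``profile_clr_sd``.
    """
    labels = ref.strain_ids
    assigned = closure(np.array([s.abundance(ref.community) for s in ref]))
    if noise.protocol_bias:
        factors = np.array([noise.protocol_bias.get(s, 1.0) for s in labels])
        center = closure(assigned * factors)
    else:
        center = assigned
    if noise.profile_clr_sd == 0:
        draws = np.tile(center, (n_replicates, 1))
    else:
        variances = np.full(len(labels), noise.profile_clr_sd**2)
        draws = simulate_measured(center, variances, n_draws=n_replicates, seed=noise.seed)
    index = [f"{sample_prefix}{i + 1}" for i in range(n_replicates)]
    abundances = pd.DataFrame(draws, index=index, columns=list(labels))
    metadata = pd.DataFrame(
        {
            "lab": lab,
            "extraction_protocol": extraction_protocol,
            "library_protocol": library_protocol,
            "assay": assay,
        },
        index=index,
    )
    ps = ProfileSet(abundances, metadata)
    ps.provenance = {"generator": "simulate_profile", **asdict(noise), "n_replicates": n_replicates}
    return ps


def simulate_reads(
    genomes: Mapping[str, str],
    composition: Composition,
    n_pairs: int,
    read_length: int = 151,
    quality: QualityModel | None = None,
    seed: int = 0,
    insert_gap: int = 50,
    length_weighted: bool = False,
) -> list[LabeledReadPair]:
    """Paired shotgun reads with strain-of-origin labels.

    Pairs are allocated to strains multinomially, proportional to the
    composition (per genome copy; set ``length_weighted`` for
    coverage-style truth weighted by genome length).  Fragments start
    uniformly; mate 1 is the fragment's 5' read, mate 2 the reverse
    complement of its 3' end.  Qualities come from the quality model, with
    the GC offset evaluated per read.
    """
    quality = quality or QualityModel()
    rng = np.random.default_rng(seed)
    labels = list(composition.labels)
    missing = [l for l in labels if l not in genomes]
    if missing:
        raise ValueError(f"genomes missing for strains: {missing}")
    frag_len = 2 * read_length + insert_gap
    for l in labels:
        if len(genomes[l]) < frag_len:
            raise ValueError(f"{l}: genome shorter than fragment length {frag_len}")
    probs = composition.values.copy()
    if length_weighted:
        probs = probs * np.array([len(genomes[l]) for l in labels])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_pairs, probs)

    pairs: list[LabeledReadPair] = []
    i = 0
    for label, n in zip(labels, counts):
        genome = genomes[label]
        starts = rng.integers(0, len(genome) - frag_len + 1, size=n)
        for s in starts:
            frag = genome[s : s + frag_len]
            b1 = frag[:read_length]
            b2 = revcomp(frag[-read_length:])
            q1 = quality.sample(rng, read_length, _gc(b1))
            q2 = quality.sample(rng, read_length, _gc(b2))
            pairs.append(
                LabeledReadPair(
                    read_id=f"read{i}",
                    strain_id=label,
                    mate1=Mate(b1, tuple(int(q) for q in q1)),
                    mate2=Mate(b2, tuple(int(q) for q in q2)),
                )
            )
            i += 1
    return pairs


@dataclass(frozen=True)
class AmpliconRead:
    """One raw merged amplicon read: primer regions flanking the insert."""

    read_id: str
    strain_id: str
    sequence: str
    quals: tuple[int, ...]
    edited: bool

    @property
    def insert(self) -> str:
        """Sequence with the 19 nt forward and 20 nt reverse regions stripped."""
        return self.sequence[19:-20]


def simulate_amplicon_reads(
    refs: Mapping[str, AmpliconReference],
    composition: Composition,
    primers: PrimerPair | None = None,
    edit_prob: float = 1.0,
    error_rate: float = 0.0,
    n_reads: int = 10_000,
    quality: QualityModel | None = None,
    seed: int = 0,
    fw_templates: Mapping[str, str] | None = None,
    rv_templates: Mapping[str, str] | None = None,
    random_degenerate_resolution: bool = False,
) -> list[AmpliconRead]:
    """Raw V4 amplicon reads from a known genome-level composition.

    Reads are allocated multinomially proportional to composition x 16S
    copy number (the pre-correction truth).  Each read is a forward primer
    region, a variant insert with i.i.d. substitution errors at
    ``error_rate``, and the reverse-complemented reverse primer region.
    With probability ``edit_prob`` the primer regions match the strain's
    template (primer editing); otherwise they are the synthesized primer,
    keeping the primer base at fixed primer-template mismatch positions.
    At degenerate positions unedited reads carry the template base by
    default — only template-complementary primer variants amplify
    efficiently — or a uniformly random resolution when
    ``random_degenerate_resolution`` is set.  Templates default to a fixed
    resolution of the primer (no mismatches); pass per-strain templates to
    model primer-template mismatches.
    """
    if not 0.0 <= edit_prob <= 1.0:
        raise ValueError("edit_prob must be in [0, 1]")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    primers = primers or PrimerPair()
    quality = quality or QualityModel()
    rng = np.random.default_rng(seed)
    labels = list(composition.labels)
    missing = [l for l in labels if l not in refs or not refs[l].variants]
    if missing:
        raise ValueError(f"no amplicon variants for strains: {missing}")
    from .amplicon_analysis import IUPAC

    def _fixed_resolution(primer: str) -> str:
        return "".join(IUPAC[b][0] for b in primer)

    fw_templates = dict(fw_templates or {})
    rv_templates = dict(rv_templates or {})
    for l in labels:
        fw_templates.setdefault(l, _fixed_resolution(primers.forward))
        rv_templates.setdefault(l, _fixed_resolution(primers.reverse))

    weights = composition.values * np.array([refs[l].n_16s for l in labels], dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(n_reads, weights)

    def _unedited(primer: str, template: str) -> str:
        if random_degenerate_resolution:
            return "".join(rng.choice(list(IUPAC[b])) for b in primer)
        return resolve_primer(primer, template)

    bases = np.array(list("ACGT"))
    reads: list[AmpliconRead] = []
    i = 0
    for label, n in zip(labels, counts):
        variants = refs[label].variants
        for _ in range(n):
            variant = variants[rng.integers(0, len(variants))]
            edited = bool(rng.random() < edit_prob)
            if edited:
                fw = fw_templates[label]
                rv = rv_templates[label]
            else:
                fw = _unedited(primers.forward, fw_templates[label])
                rv = _unedited(primers.reverse, rv_templates[label])
            insert = np.array(list(variant))
            if error_rate > 0:
                hit = rng.random(insert.size) < error_rate
                if hit.any():
                    subs = rng.choice(bases, size=int(hit.sum()))
                    same = insert[hit] == subs
                    while same.any():  # force a real substitution
                        subs[same] = rng.choice(bases, size=int(same.sum()))
                        same = insert[hit] == subs
                    insert[hit] = subs
            seq = fw + "".join(insert) + revcomp(rv)
            q = quality.sample(rng, len(seq), _gc(seq))
            reads.append(
                AmpliconRead(
                    read_id=f"amp{i}|strain={label}",
                    strain_id=label,
                    sequence=seq,
                    quals=tuple(int(x) for x in q),
                    edited=edited,
                )
            )
            i += 1
    return reads
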