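"""Read trimming/filtering and the GC-bias audit built on it.

Implements the minimal subset of fastp-style preprocessing whose parameter
space drives species-dependent read loss: fixed front/tail trims, trailing
poly-X removal, sliding-window quality trimming that cuts the read from the
first failing window ("cut right"), an unqualified-base-percentage filter
and a minimum-length filter.  A setting triple is labelled ``Q_U_L``
(window mean quality _ unqualified percent limit _ length required), e.g.
``15_100_65`` for 4-bp window trimming at Q15, and ``0_100_65`` for no
quality trimming with a 65-bp length floor.

Because low base quality correlates with read GC on some platforms,
stringent trimming removes reads from GC-rich genomes preferentially;
``gc_bias_report`` quantifies the resulting compositional shift as the
Aitchison distance between retained-read compositions under two settings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .compositional_stats import aitchison_distance, closure, replace_zeros
from .reference_data import MockReference

__all__ = [
    "TrimSettings",
    "Mate",
    "LabeledReadPair",
    "TrimResult",
    "trim_pair",
    "retention_by_strain",
    "gc_bias_report",
    "write_paired_fastq",
    "read_paired_fastq",
]


@dataclass(frozen=True)
class TrimSettings:
    """One trimming/filtering parameter triple plus fixed defaults.

    ``window_mean_quality`` 0 disables window trimming entirely.
    """

    window_mean_quality: int
    unqualified_percent_limit: float
    length_required: int
    window_size: int = 4
    qualified_quality_phred: int = 15
    trim_front: int = 5
    trim_tail: int = 1
    polyx_min_len: int = 10
    low_complexity_filter: bool = False

    def __post_init__(self) -> None:
        if self.window_mean_quality < 0:
            raise ValueError("window_mean_quality must be >= 0")
        if not 0 < self.unqualified_percent_limit <= 100:
            raise ValueError("unqualified_percent_limit must be in (0, 100]")
        if self.length_required < 1:
            raise ValueError("length_required must be positive")
        if self.low_complexity_filter:
            raise NotImplementedError(
                "low-complexity filtering is not implemented; it is orthogonal "
                "to the GC-bias mechanism audited here"
            )

    @property
    def label(self) -> str:
        u = self.unqualified_percent_limit
        u_str = str(int(u)) if float(u).is_integer() else str(u)
        return f"{self.window_mean_quality}_{u_str}_{self.length_required}"

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "TrimSettings":
        m = re.fullmatch(r"(\d+)_(\d+(?:\.\d+)?)_(\d+)", label)
        if not m:
            raise ValueError(f"settings label {label!r} does not match 'Q_U_L'")
        return cls(int(m.group(1)), float(m.group(2)), int(m.group(3)), **kwargs)


@dataclass(frozen=True)
class Mate:
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quality scores differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class LabeledReadPair:
    read_id: str
    strain_id: str
    mate1: Mate
    mate2: Mate


@dataclass(frozen=True)
class TrimResult:
    kept: bool
    pair: LabeledReadPair | None
    reason: str | None  # "quality" (unqualified-percent) | "length"


def _trim_mate(mate: Mate, s: TrimSettings, reapply_fixed: bool) -> tuple[Mate, str | None]:
    bases, quals = mate.bases, np.asarray(mate.quals, dtype=float)
    if reapply_fixed:
        end = len(bases) - s.trim_tail
        bases, quals = bases[s.trim_front : end], quals[s.trim_front : end]
    # trailing poly-X: any single-base run of >= polyx_min_len at the 3' end
    if len(bases) >= s.polyx_min_len:
        last = bases[-1]
        run = len(bases) - len(bases.rstrip(last))
        if run >= s.polyx_min_len:
            bases, quals = bases[:-run], quals[:-run]
    # sliding-window cut-right
    if s.window_mean_quality > 0 and len(bases):
        n, w = len(quals), s.window_size
        c = np.concatenate([[0.0], np.cumsum(quals)])
        starts = np.arange(n)
        sizes = np.minimum(w, n - starts)
        means = (c[starts + sizes] - c[starts]) / sizes
        fail = means < s.window_mean_quality
        if fail.any():
            cut = int(np.argmax(fail))
            bases, quals = bases[:cut], quals[:cut]
    # filters
    if len(bases) < s.length_required:
        return Mate(bases, tuple(int(q) for q in quals)), "length"
    if len(bases):
        unq = 100.0 * np.mean(quals < s.qualified_quality_phred)
        if unq > s.unqualified_percent_limit:
            return Mate(bases, tuple(int(q) for q in quals)), "quality"
    return Mate(bases, tuple(int(q) for q in quals)), None


def trim_pair(
    pair: LabeledReadPair, settings: TrimSettings, reapply_fixed: bool = True
) -> TrimResult:
    """Trim and filter one read pair; both mates are dropped together.

    Per mate, in order: fixed front/tail trims (skipped when
    ``reapply_fixed`` is false, which makes the operation idempotent on its
    own output), trailing poly-X removal, sliding-window quality cut, then
    the unqualified-percent and minimum-length filters.  Rejection is a
    result, not an error.
    """
    m1, r1 = _trim_mate(pair.mate1, settings, reapply_fixed)
    m2, r2 = _trim_mate(pair.mate2, settings, reapply_fixed)
    reason = r1 or r2
    if reason:
        return TrimResult(kept=False, pair=None, reason=reason)
    return TrimResult(
        kept=True,
        pair=LabeledReadPair(pair.read_id, pair.strain_id, m1, m2),
        reason=None,
    )


def retention_by_strain(
    batch: Sequence[LabeledReadPair], settings_ladder: Sequence[TrimSettings]
) -> pd.DataFrame:
    """Percent of raw read pairs retained, per setting and strain.

    An ``ALL`` row per setting reports overall retention.
    """
    if not batch:
        raise ValueError("empty read batch")
    strains = sorted({p.strain_id for p in batch})
    totals = {s: 0 for s in strains}
    for p in batch:
        totals[p.strain_id] += 1
    rows = []
    for s in settings_ladder:
        kept = {st: 0 for st in strains}
        for p in batch:
            if trim_pair(p, s).kept:
                kept[p.strain_id] += 1
        for st in strains:
            rows.append(
                {
                    "settings": s.label,
                    "strain_id": st,
                    "n_input": totals[st],
                    "n_retained": kept[st],
                    "pct_retained": 100.0 * kept[st] / totals[st],
                }
            )
        rows.append(
            {
                "settings": s.label,
                "strain_id": "ALL",
                "n_input": len(batch),
                "n_retained": sum(kept.values()),
                "pct_retained": 100.0 * sum(kept.values()) / len(batch),
            }
        )
    return pd.DataFrame(rows)


def _retained_composition(
    batch: Sequence[LabeledReadPair], settings: TrimSettings, labels: Sequence[str]
) -> np.ndarray:
    counts = {s: 0 for s in labels}
    for p in batch:
        if trim_pair(p, settings).kept:
            counts[p.strain_id] += 1
    vals = np.array([counts[s] for s in labels], dtype=float)
    if vals.sum() == 0:
        raise ValueError(f"no reads retained under settings {settings.label}")
    return closure(vals)


def gc_bias_report(
    batch: Sequence[LabeledReadPair],
    ref: MockReference,
    settings_a: TrimSettings,
    settings_b: TrimSettings,
) -> dict:
    """Compositional shift between two trimming settings, against strain GC.

    Returns the retained-read composition under each setting, their
    Aitchison distance, the per-strain log-ratio change (a vs b) with its
    Spearman rank correlation against genomic GC, and the batch's raw
    percent of bases at Q30 or above.
    """
    unknown = sorted({p.strain_id for p in batch} - set(ref.strain_ids))
    if unknown:
        raise ValueError(f"strains not in registry: {unknown}")
    labels = sorted({p.strain_id for p in batch})
    comp_a = _retained_composition(batch, settings_a, labels)
    comp_b = _retained_composition(batch, settings_b, labels)
    dist = float(aitchison_distance(comp_a, comp_b))
    log_ratio = np.log(replace_zeros(comp_a)) - np.log(replace_zeros(comp_b))
    gc = np.array([ref.get(s).gc_percent for s in labels])
    if len(labels) >= 3 and np.ptp(log_ratio) > 0:
        rho = spearmanr(gc, log_ratio).statistic
    else:  # undefined when nothing was differentially removed
        rho = float("nan")

    n_bases = n_q30 = 0
    for p in batch:
        for m in (p.mate1, p.mate2):
            q = np.asarray(m.quals)
            n_bases += q.size
            n_q30 += int((q >= 30).sum())
    return {
        "labels": labels,
        "composition_a": dict(zip(labels, comp_a)),
        "composition_b": dict(zip(labels, comp_b)),
        "settings_a": settings_a.label,
        "settings_b": settings_b.label,
        "aitchison_distance": dist,
        "log_ratio_change": dict(zip(labels, log_ratio)),
        "spearman_gc_log_ratio": float(rho),
        "pct_q30": 100.0 * n_q30 / n_bases if n_bases else float("nan"),
    }


# ---------------------------------------------------------------------------
# FASTQ I/O (phred+33; origin labels carried as a "|strain=ID" id suffix)
# ---------------------------------------------------------------------------

def _fastq_record(read_id: str, strain_id: str, mate: Mate, mate_no: int) -> str:
    qual = "".join(chr(q + 33) for q in mate.quals)
    return f"@{read_id}|strain={strain_id}/{mate_no}\n{mate.bases}\n+\n{qual}\n"


def write_paired_fastq(
    batch: Iterable[LabeledReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in batch:
            f1.write(_fastq_record(p.read_id, p.strain_id, p.mate1, 1))
            f2.write(_fastq_record(p.read_id, p.strain_id, p.mate2, 2))


def _parse_fastq(path: str | Path) -> list[tuple[str, str, Mate]]:
    out = []
    lines = Path(path).read_text().splitlines()
    for i in range(0, len(lines), 4):
        header = lines[i][1:]
        name = header.split("/")[0]
        read_id, _, strain = name.partition("|strain=")
        bases = lines[i + 1]
        quals = tuple(ord(c) - 33 for c in lines[i + 3])
        out.append((read_id, strain, Mate(bases, quals)))
    return out


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[LabeledReadPair]:
    r1, r2 = _parse_fastq(path1), _parse_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("mate files differ in read count")
    pairs = []
    for (id1, s1, m1), (id2, s2, m2) in zip(r1, r2):
        if id1 != id2:
            raise ValueError(f"mate files out of sync at read {id1!r} / {id2!r}")
        pairs.append(LabeledReadPair(id1, s1, m1, m2))
    return pairs
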