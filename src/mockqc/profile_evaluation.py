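"""Evaluation of taxonomic profiles against the known mock composition.

Profiler outputs (mpa-style reports, abundance tables, or per-replicon count
tables) are converted to closed compositions, observed taxon names are
matched to the expected strains by the registry's species-name search terms,
and the usual benchmarking summaries are computed: species-count precision
curves, expected-species fractions, false-positive tallies, protocol
dispersion, and Gram-type bias.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compositional_stats import (
    Composition,
    ProfileSet,
    aitchison_distance,
    bray_curtis,
    closure,
    gmafd,
    subcomposition,
)
from .reference_data import GramType, MockReference, gram_subset

__all__ = [
    "TaxonAssignment",
    "search_terms",
    "match_expected",
    "parse_mpa",
    "read_count_table",
    "counts_to_abundance",
    "species_count_curve",
    "evaluate_profile",
    "ProfileEvaluation",
    "protocol_dispersion",
    "gram_bias_summary",
]

#: Strain-specific search-term overrides; all other strains use their species
#: name with any subspecies epithet removed.  Alternatives are separated by
#: "|" and matched case-sensitively as substrings (grep semantics).
SPECIAL_SEARCH_TERMS = {
    "NBRC 113351": "Blautia producta",
    "NBRC 113350": "Bacteroides uniformis|Bacteroides rodentium/uniformis",
    "NBRC 113352": "Enterocloster clostridioformis|Clostridium clostridioforme",
}

_SUBSP = re.compile(r"\s+subsp\..*$")


@dataclass(frozen=True)
class TaxonAssignment:
    """Match of an observed taxon name to expected strain(s)."""

    observed_name: str
    matched_strains: tuple[str, ...]
    match_rule: str | None

    @property
    def matched(self) -> bool:
        return bool(self.matched_strains)


def search_terms(ref: MockReference) -> dict[str, list[str]]:
    """Per-strain list of literal search substrings."""
    terms = {}
    for s in ref:
        pattern = SPECIAL_SEARCH_TERMS.get(s.strain_id) or _SUBSP.sub("", s.species_name)
        terms[s.strain_id] = pattern.split("|")
    return terms


def _collapse_groups(terms: Mapping[str, list[str]]) -> list[tuple[str, ...]]:
    """Strains sharing identical search terms (species-level duplicates)."""
    by_terms: dict[tuple[str, ...], list[str]] = {}
    for sid, alts in terms.items():
        by_terms.setdefault(tuple(alts), []).append(sid)
    return [tuple(v) for v in by_terms.values() if len(v) > 1]


def match_expected(observed_names: Sequence[str], ref: MockReference) -> list[TaxonAssignment]:
    """Match observed taxon names against the registry's search terms.

    A name matching the search terms of two strains raises an ambiguity
    error, except when the matching strains share identical terms (the two
    B. longum strains are indistinguishable at species level); such names
    match the whole group.
    """
    terms = search_terms(ref)
    groups = {frozenset(g) for g in _collapse_groups(terms)}
    out = []
    for name in observed_names:
        hits, rules = [], []
        for sid, alts in terms.items():
            fired = [a for a in alts if a in name]
            if fired:
                hits.append(sid)
                rules.append(fired[0])
        if len(hits) > 1 and frozenset(hits) not in groups:
            raise ValueError(
                f"observed name {name!r} ambiguously matches strains {sorted(hits)}"
            )
        out.append(
            TaxonAssignment(
                observed_name=name,
                matched_strains=tuple(sorted(hits)),
                match_rule=rules[0] if rules else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# profiler-output readers
# ---------------------------------------------------------------------------

def parse_mpa(path: str | Path) -> dict[str, float]:
    """Parse an mpa-format report into {species name: abundance}.

    The species level is taken as lines whose deepest rank is ``s__``;
    the lineage is split on ``|``, the leading rank tag stripped, and
    underscores converted to spaces.
    """
    result: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        taxo, value = line.split("\t")[:2]
        deepest = taxo.split("|")[-1]
        if not deepest.startswith("s__"):
            continue
        name = deepest[3:].replace("_", " ")
        result[name] = result.get(name, 0.0) + float(value)
    return result


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a per-replicon count table (unit_id, strain_id, est_count, effective_length)."""
    df = pd.read_csv(path, sep="\t")
    required = {"unit_id", "strain_id", "est_count", "effective_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def counts_to_abundance(table: pd.DataFrame) -> Composition:
    """Convert per-replicon estimated counts to a strain composition.

    Counts are summed as coverages across replicons — each row contributes
    ``est_count / effective_length`` to its strain — and coverages are
    closed to relative abundances.
    """
    if (table["est_count"] < 0).any():
        raise ValueError("est_count must be non-negative")
    if (table["effective_length"] <= 0).any():
        raise ValueError("effective_length must be positive")
    cov = (
        (table["est_count"] / table["effective_length"])
        .groupby(table["strain_id"], sort=False)
        .sum()
    )
    if cov.sum() <= 0:
        raise ValueError("zero total coverage")
    return Composition(tuple(cov.index), cov.to_numpy())


# ---------------------------------------------------------------------------
# evaluation summaries
# ---------------------------------------------------------------------------

def species_count_curve(
    observed: Mapping[str, float], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Number of taxa at or above each minimum-abundance threshold."""
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    vals = np.asarray(list(observed.values()), dtype=float)
    rows = [{"threshold_pct": t, "n_species": int((vals >= t).sum())} for t in thresholds]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProfileEvaluation:
    """Summary of one observed profile against the expected composition."""

    expected_fraction_pct: float
    per_strain_pct: dict[str, float]
    missing: tuple[str, ...]
    false_positives: tuple[tuple[str, float], ...]
    false_positive_fraction_pct: float
    unassigned_fraction_pct: float
    bray_curtis_similarity_pct: float
    gmafd_vs_expected: float


def evaluate_profile(
    observed: Mapping[str, float],
    ref: MockReference,
    collapse_longum: bool = False,
    unassigned_labels: Sequence[str] = ("unassigned", "unclassified"),
) -> ProfileEvaluation:
    """Score an observed taxon-abundance table against the assigned composition.

    Observed rows matching one expected strain (or one species-level group
    when ``collapse_longum``) are summed per strain; expected strains with no
    matching row are reported missing at abundance zero.  Unmatched rows are
    false positives, except explicitly unassigned buckets which are tallied
    separately.  Agreement statistics (Bray-Curtis similarity, gmAFD) compare
    the per-strain abundances to the assigned composition, with zero
    replacement covering undetected strains.
    """
    observed = {k: float(v) for k, v in observed.items()}
    total = sum(observed.values())
    if total <= 0:
        raise ValueError("observed profile is empty")
    assignments = match_expected(list(observed), ref)

    groups = _collapse_groups(search_terms(ref))
    group_of = {sid: g for g in groups for sid in g}

    def bucket(strains: tuple[str, ...]) -> str:
        if len(strains) == 1:
            sid = strains[0]
            if collapse_longum and sid in group_of:
                return "+".join(group_of[sid])
            return sid
        return "+".join(strains)

    expected_buckets: dict[str, float] = {}
    for s in ref:
        b = bucket((s.strain_id,))
        expected_buckets[b] = expected_buckets.get(b, 0.0) + s.abundance(ref.community)

    measured = {b: 0.0 for b in expected_buckets}
    fp: dict[str, float] = {}
    unassigned = 0.0
    for a in assignments:
        value = observed[a.observed_name]
        if a.matched:
            if len(a.matched_strains) > 1 and not collapse_longum:
                # species-level duplicates cannot be attributed to one strain;
                # split evenly so totals are conserved
                for sid in a.matched_strains:
                    measured[bucket((sid,))] += value / len(a.matched_strains)
            else:
                measured[bucket(a.matched_strains)] += value
        elif a.observed_name.lower() in {u.lower() for u in unassigned_labels}:
            unassigned += value
        else:
            fp[a.observed_name] = fp.get(a.observed_name, 0.0) + value

    pct = 100.0 / total
    expected_total = sum(measured.values()) * pct
    fp_total = sum(fp.values()) * pct
    missing = tuple(b for b, v in measured.items() if v == 0.0)

    labels = tuple(expected_buckets)
    assigned = Composition(labels, np.array([expected_buckets[b] for b in labels]))
    meas_vals = np.array([measured[b] for b in labels])
    if meas_vals.sum() > 0:
        bc = bray_curtis(assigned.values, closure(meas_vals))
        gm = float(gmafd(assigned.values, closure(meas_vals)))
    else:
        bc, gm = 1.0, float("inf")

    return ProfileEvaluation(
        expected_fraction_pct=expected_total,
        per_strain_pct={b: v * pct for b, v in measured.items()},
        missing=missing,
        false_positives=tuple(sorted(((n, v * pct) for n, v in fp.items()), key=lambda t: -t[1])),
        false_positive_fraction_pct=fp_total,
        unassigned_fraction_pct=unassigned * pct,
        bray_curtis_similarity_pct=100.0 * (1.0 - bc),
        gmafd_vs_expected=gm,
    )


def protocol_dispersion(
    profiles: ProfileSet,
    grouping: str = "extraction_protocol",
    include_bray_curtis: bool = False,
) -> pd.DataFrame:
    """All pairwise Aitchison distances annotated with group membership.

    Each pair of profiles yields one row with the distance, the two sample
    ids, their labs (within-lab pairs are the repeatability set, between-lab
    pairs the reproducibility set) and their values of the ``grouping``
    metadata key.  Groups with fewer than two members contribute no
    within-group pair and are flagged with a warning.
    """
    meta = profiles.metadata
    if grouping in meta.columns:
        counts = meta[grouping].value_counts()
        for g, n in counts.items():
            if n < 2:
                warnings.warn(f"group {g!r} has fewer than 2 profiles", stacklevel=2)
    rows = []
    vals = profiles.abundances
    for a, b in itertools.combinations(profiles.sample_ids, 2):
        row = {
            "sample_a": a,
            "sample_b": b,
            "aitchison": float(aitchison_distance(vals.loc[a].to_numpy(), vals.loc[b].to_numpy())),
        }
        if include_bray_curtis:
            row["bray_curtis"] = bray_curtis(vals.loc[a].to_numpy(), vals.loc[b].to_numpy())
        if "lab" in meta.columns:
            row["lab_a"], row["lab_b"] = meta.loc[a, "lab"], meta.loc[b, "lab"]
            row["within_lab"] = row["lab_a"] == row["lab_b"]
        if grouping in meta.columns:
            row["group_a"], row["group_b"] = meta.loc[a, grouping], meta.loc[b, grouping]
            row["within_group"] = row["group_a"] == row["group_b"]
        rows.append(row)
    return pd.DataFrame(rows)


def gram_bias_summary(profiles: ProfileSet, ref: MockReference) -> dict:
    """Gram-type bias summary for cell-mock profiles.

    Returns per-profile cumulative Gram-positive abundance and, separately
    within the Gram-positive and Gram-negative subcompositions, all pairwise
    Aitchison distances (the subcompositions are re-closed, so a uniform
    scaling of one Gram class before closure leaves its internal distances
    unchanged).
    """
    pos = sorted(gram_subset(ref, GramType.POSITIVE) & set(profiles.labels))
    neg = sorted(gram_subset(ref, GramType.NEGATIVE) & set(profiles.labels))
    totals = profiles.abundances[pos].sum(axis=1).rename("gram_positive_pct")

    def _pairdist(labels: list[str]) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations(profiles.sample_ids, 2):
            ca = subcomposition(profiles.composition(a), labels)
            cb = subcomposition(profiles.composition(b), labels)
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "aitchison": float(aitchison_distance(ca.values, cb.values)),
                }
            )
        return pd.DataFrame(rows)

    return {
        "gram_positive_totals": totals.to_frame(),
        "gram_positive_pairdist": _pairdist(pos) if len(pos) >= 2 else pd.DataFrame(),
        "gram_negative_pairdist": _pairdist(neg) if len(neg) >= 2 else pd.DataFrame(),
    }
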