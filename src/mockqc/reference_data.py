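"""Registry of the mock-community reference composition.

The package ships a single tab-separated registry describing the defined
bacterial mixtures used as ground truth: one row per strain with its culture
collection accession, species name, genome size, genomic GC content, 16S rRNA
gene copy number, Gram type, and the relative abundance assigned to the strain
when each community was formulated (one column per community).  The DNA mock
contains 20 strains; the whole-cell mock omits the two strains whose cell-mock
abundance is zero, leaving 18 strains at an even 5.6% each.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GramType",
    "Community",
    "StrainRecord",
    "MockReference",
    "ValidationError",
    "load_reference",
    "packaged_registry_path",
    "write_reference",
    "gram_subset",
    "registry_summary",
]

#: Column order of the registry TSV (header row required).
REGISTRY_COLUMNS = [
    "strain_id",
    "species_name",
    "genome_size_bp",
    "gc_percent",
    "n_16s",
    "gram_type",
    "abundance_dna_pct",
    "abundance_cell_pct",
]

#: Tolerance on the sum of assigned abundances.  The registry stores values
#: rounded to one decimal, so an even 18-strain community prints 18 x 5.6 =
#: 100.8; the sum check therefore allows +-1.5 percentage points.
ABUNDANCE_SUM_TOL = 1.5


class ValidationError(ValueError):
    """Raised when a registry file violates the schema or its invariants."""


class GramType(str, enum.Enum):
    POSITIVE = "+"
    NEGATIVE = "-"
    VARIABLE = "+-"


class Community(str, enum.Enum):
    DNA = "dna"
    CELL = "cell"


@dataclass(frozen=True)
class StrainRecord:
    """One strain of the mock community and its assigned abundances."""

    strain_id: str
    species_name: str
    genome_size_bp: int
    gc_percent: float
    n_16s: int
    gram_type: GramType
    abundance_dna_pct: float
    abundance_cell_pct: float

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValidationError(f"{self.strain_id}: genome_size_bp must be positive")
        if not 0.0 < self.gc_percent < 100.0:
            raise ValidationError(f"{self.strain_id}: gc_percent must be in (0, 100)")
        if self.n_16s < 1:
            raise ValidationError(f"{self.strain_id}: n_16s must be >= 1")
        if self.abundance_dna_pct < 0 or self.abundance_cell_pct < 0:
            raise ValidationError(f"{self.strain_id}: abundances must be non-negative")

    def abundance(self, community: Community) -> float:
        return (
            self.abundance_dna_pct
            if community is Community.DNA
            else self.abundance_cell_pct
        )


@dataclass(frozen=True)
class MockReference:
    """Validated registry for one community (strains with nonzero abundance)."""

    strains: tuple[StrainRecord, ...]
    community: Community

    def __post_init__(self) -> None:
        ids = [s.strain_id for s in self.strains]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate strain_id: {', '.join(dupes)}")
        if self.strains:
            total = sum(s.abundance(self.community) for s in self.strains)
            if abs(total - 100.0) > ABUNDANCE_SUM_TOL:
                raise ValidationError(
                    f"assigned {self.community.value} abundances sum to {total:.2f}, "
                    f"expected 100 +- {ABUNDANCE_SUM_TOL}"
                )

    def __len__(self) -> int:
        return len(self.strains)

    def __iter__(self):
        return iter(self.strains)

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(s.strain_id for s in self.strains)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.species_name for s in self.strains)

    def abundances(self) -> dict[str, float]:
        """Assigned abundance (percent) per strain for this community."""
        return {s.strain_id: s.abundance(self.community) for s in self.strains}

    def get(self, strain_id: str) -> StrainRecord:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s
        raise KeyError(strain_id)

    def __contains__(self, strain_id: str) -> bool:
        return any(s.strain_id == strain_id for s in self.strains)


def packaged_registry_path() -> Path:
    """Path of the registry TSV shipped with the package."""
    return Path(str(resources.files("mockqc").joinpath("data/mock_registry.tsv")))


def load_reference(path: str | Path | None = None, community: str | Community = Community.DNA) -> MockReference:
    """Load and validate the strain registry for one community.

    Parameters
    ----------
    path
        Registry TSV; ``None`` uses the packaged registry.
    community
        ``"dna"`` or ``"cell"``.  The cell-mock registry retains only strains
        with nonzero cell-mock abundance.
    """
    community = Community(community)
    if path is None:
        path = packaged_registry_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"registry missing columns: {', '.join(missing)}")
    if df[REGISTRY_COLUMNS].isna().any().any():
        raise ValidationError("registry contains missing fields")
    records = []
    for row in df.itertuples(index=False):
        try:
            gram = GramType(row.gram_type)
        except ValueError as exc:
            raise ValidationError(
                f"{row.strain_id}: unknown gram_type {row.gram_type!r}"
            ) from exc
        rec = StrainRecord(
            strain_id=row.strain_id,
            species_name=row.species_name,
            genome_size_bp=int(row.genome_size_bp),
            gc_percent=float(row.gc_percent),
            n_16s=int(row.n_16s),
            gram_type=gram,
            abundance_dna_pct=float(row.abundance_dna_pct),
            abundance_cell_pct=float(row.abundance_cell_pct),
        )
        if rec.abundance(community) > 0:
            records.append(rec)
    return MockReference(strains=tuple(records), community=community)


def write_reference(ref_or_records: MockReference | Iterable[StrainRecord], path: str | Path) -> None:
    """Write strain records back to the registry TSV format (round-trip safe)."""
    strains = list(ref_or_records)
    rows = [
        {
            "strain_id": s.strain_id,
            "species_name": s.species_name,
            "genome_size_bp": s.genome_size_bp,
            "gc_percent": s.gc_percent,
            "n_16s": s.n_16s,
            "gram_type": s.gram_type.value,
            "abundance_dna_pct": s.abundance_dna_pct,
            "abundance_cell_pct": s.abundance_cell_pct,
        }
        for s in strains
    ]
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, sep="\t", index=False)


def gram_subset(ref: MockReference, which: str | GramType, include_variable: bool = False) -> set[str]:
    """Strain ids with the requested Gram type.

    Gram-variable strains are excluded from both subsets by default: the
    cell mock's expected Gram-positive total of 67.2% corresponds to the 12
    strictly Gram-positive strains at 5.6% each.
    """
    which = GramType(which)
    if which is GramType.VARIABLE:
        return {s.strain_id for s in ref if s.gram_type is GramType.VARIABLE}
    keep = {which} | ({GramType.VARIABLE} if include_variable else set())
    return {s.strain_id for s in ref if s.gram_type in keep}


@dataclass(frozen=True)
class RegistrySummary:
    n_strains: int
    min_abundance_pct: float
    min_abundance_strain: str
    max_abundance_pct: float
    max_abundance_strain: str
    min_gc_percent: float
    min_gc_strain: str
    max_gc_percent: float
    max_gc_strain: str


def registry_summary(ref: MockReference) -> RegistrySummary:
    """Extrema of assigned abundance and genomic GC over included strains."""
    if not len(ref):
        raise ValidationError("registry is empty")
    by_ab = sorted(ref, key=lambda s: (s.abundance(ref.community), s.strain_id))
    by_gc = sorted(ref, key=lambda s: (s.gc_percent, s.strain_id))
    return RegistrySummary(
        n_strains=len(ref),
        min_abundance_pct=by_ab[0].abundance(ref.community),
        min_abundance_strain=by_ab[0].strain_id,
        max_abundance_pct=by_ab[-1].abundance(ref.community),
        max_abundance_strain=by_ab[-1].strain_id,
        min_gc_percent=by_gc[0].gc_percent,
        min_gc_strain=by_gc[0].strain_id,
        max_gc_percent=by_gc[-1].gc_percent,
        max_gc_strain=by_gc[-1].strain_id,
    )
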