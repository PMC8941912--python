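"""Compositional mathematics for relative-abundance profiles.

Species profiles are compositions: non-negative vectors carrying only
relative information, closed to 100%.  All comparisons here respect that
geometry.  The centered log-ratio (clr) maps a composition x to
``ln(x_i / g(x))`` with g the geometric mean; the Aitchison distance is the
Euclidean distance between clr images.  Two scalar summaries are used
throughout the pipeline:

* ``gmafd(a, b)`` — geometric mean of species-wise absolute fold
  differences, ``exp(mean_i |ln(a_i/b_i)|)``; 1.0 means identical profiles.
* ``qmcv(X)`` — quadratic mean of species-wise coefficients of variation
  across replicate profiles; a single-number replicate-variability summary.

Zeros are incompatible with log-ratio analysis; the default policy is
multiplicative replacement (zeros set to half the smallest nonzero part,
the remaining parts scaled down to preserve the total) applied before any
log operation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = [
    "Composition",
    "ProfileSet",
    "closure",
    "replace_zeros",
    "clr",
    "aitchison_distance",
    "bray_curtis",
    "qmcv",
    "gmafd",
    "subcomposition",
    "center_and_clrvar",
]

logger = logging.getLogger(__name__)

TOTAL = 100.0


# ---------------------------------------------------------------------------
# array core (rows are compositions)
# ---------------------------------------------------------------------------

def closure(values: Sequence[float] | np.ndarray, total: float = TOTAL) -> np.ndarray:
    """Normalize non-negative parts to sum to ``total`` (percent by default)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("composition parts must be non-negative")
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot close an all-zero vector")
    return x / s * total


def replace_zeros(values: np.ndarray, delta_factor: float = 0.5) -> np.ndarray:
    """Multiplicative zero replacement on closed rows.

    Zeros become ``delta = delta_factor * min(nonzero parts)`` of their row;
    nonzero parts are scaled down proportionally so the row total is kept.
    Rows without zeros are returned unchanged.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    for row in x:
        zero = row == 0
        if not zero.any():
            continue
        if zero.all():
            raise ValueError("cannot replace zeros in an all-zero vector")
        delta = delta_factor * row[~zero].min()
        total = row.sum()
        row[~zero] *= (total - zero.sum() * delta) / total
        row[zero] = delta
    return x if np.asarray(values).ndim == 2 else x[0]


def clr(values: Sequence[float] | np.ndarray, delta_factor: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform; rows sum to zero.

    Input rows are closed and zero-replaced first, so the transform is
    defined for profiles with absent species.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("clr requires non-negative parts")
    x = replace_zeros(closure(x))
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("compositions must have the same number of parts")
    return a, b


def aitchison_distance(a, b, delta_factor: float = 0.5) -> float | np.ndarray:
    """Euclidean distance between clr-transformed compositions."""
    a, b = _pair(a, b)
    d = clr(a, delta_factor) - clr(b, delta_factor)
    return np.sqrt((d * d).sum(axis=-1))

def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity, ``sum|a-b| / sum(a+b)``, on closed percents."""
    a, b = _pair(a, b)
    return float(_scipy_braycurtis(closure(a), closure(b)))


def gmafd(a, b, delta_factor: float = 0.5) -> float | np.ndarray:
    """Geometric mean of species-wise absolute fold differences (>= 1)."""
    a, b = _pair(a, b)
    la = np.log(replace_zeros(closure(a), delta_factor))
    lb = np.log(replace_zeros(closure(b), delta_factor))
    return np.exp(np.abs(la - lb).mean(axis=-1))


def qmcv(profiles: np.ndarray | "ProfileSet", sample_sd: bool = True) -> float:
    """Quadratic mean of species-wise CVs across replicate profiles (percent).

    Per species, CV = sd/mean x 100 over all replicates (grand mean; sample
    sd with n-1 by default).  Species with zero mean across all replicates
    carry no fold information and are dropped with a warning.
    """
    if isinstance(profiles, ProfileSet):
        profiles = profiles.values
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("qmcv needs >= 2 replicate profiles")
    mean = x.mean(axis=0)
    keep = mean > 0
    if not keep.all():
        warnings.warn(
            f"qmcv: dropping {int((~keep).sum())} species with zero mean abundance",
            stacklevel=2,
        )
        x, mean = x[:, keep], mean[keep]
    sd = x.std(axis=0, ddof=1 if sample_sd else 0)
    cv = sd / mean * 100.0
    return float(np.sqrt(np.mean(cv**2)))


def geometric_center(profiles: np.ndarray, delta_factor: float = 0.5) -> np.ndarray:
    """Closed geometric mean of replicate profiles (the compositional center)."""
    x = replace_zeros(closure(np.atleast_2d(np.asarray(profiles, dtype=float))), delta_factor)
    return closure(np.exp(np.log(x).mean(axis=0)))


# ---------------------------------------------------------------------------
# labelled containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """A closed relative-abundance vector with unique part labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        vals = closure(self.values)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", vals)
        self.values.setflags(write=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "Composition":
        return cls(tuple(mapping.keys()), np.array(list(mapping.values()), dtype=float))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values))

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, label: str) -> float:
        return float(self.values[self.labels.index(label)])

    def reorder(self, labels: Sequence[str]) -> "Composition":
        if set(labels) != set(self.labels):
            raise ValueError("label mismatch")
        idx = [self.labels.index(l) for l in labels]
        return Composition(tuple(labels), self.values[idx])

    def aligned_values(self, labels: Sequence[str]) -> np.ndarray:
        return self.reorder(labels).values


def _aligned(a: Composition, b: Composition) -> tuple[np.ndarray, np.ndarray]:
    if set(a.labels) != set(b.labels):
        raise ValueError("compositions are defined on different label sets")
    return a.values, b.aligned_values(a.labels)


def subcomposition(comp: Composition, subset: Iterable[str]) -> Composition:
    """Restrict to a subset of parts and re-close to 100%."""
    subset = list(dict.fromkeys(subset))
    if not subset:
        raise ValueError("subset must be nonempty")
    missing = [s for s in subset if s not in comp.labels]
    if missing:
        raise ValueError(f"labels not in composition: {missing}")
    vals = np.array([comp[s] for s in subset])
    if vals.sum() <= 0:
        raise ValueError("subcomposition has zero total abundance")
    return Composition(tuple(subset), vals)


@dataclass
class ProfileSet:
    """Replicate compositions on a shared label set with per-sample metadata.

    ``abundances`` is a samples x labels DataFrame of closed percents;
    ``metadata`` is indexed by sample id with columns such as ``lab``,
    ``extraction_protocol`` ({sop, non_sop, not_applicable}),
    ``library_protocol`` ({sop, non_sop}) and ``assay``
    ({metagenome, amplicon}).
    """

    abundances: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = closure(self.abundances.to_numpy(dtype=float))
        self.abundances = pd.DataFrame(
            vals, index=self.abundances.index, columns=self.abundances.columns
        )
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.abundances.index)
        if not self.metadata.index.equals(self.abundances.index):
            self.metadata = self.metadata.reindex(self.abundances.index)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.abundances.columns)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.abundances.index)

    @property
    def values(self) -> np.ndarray:
        return self.abundances.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.abundances)

    def composition(self, sample_id: str) -> Composition:
        return Composition(self.labels, self.abundances.loc[sample_id].to_numpy())

    def compositions(self) -> dict[str, Composition]:
        return {sid: self.composition(sid) for sid in self.sample_ids}

    # -- I/O ---------------------------------------------------------------

    def to_long_tsv(self, path: str | Path) -> None:
        long = (
            self.abundances.rename_axis("sample_id")
            .reset_index()
            .melt(id_vars="sample_id", var_name="label", value_name="abundance_pct")
        )
        long.to_csv(path, sep="\t", index=False)

    def to_wide_tsv(self, path: str | Path) -> None:
        self.abundances.rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def from_long_tsv(cls, path: str | Path, metadata: pd.DataFrame | None = None) -> "ProfileSet":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="sample_id", columns="label", values="abundance_pct").fillna(0.0)
        wide.columns.name = None
        return cls(wide, metadata if metadata is not None else pd.DataFrame())

    @classmethod
    def from_wide_tsv(cls, path: str | Path, metadata: pd.DataFrame | None = None) -> "ProfileSet":
        wide = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(wide, metadata if metadata is not None else pd.DataFrame())

    @classmethod
    def with_sample_sheet(cls, wide_path: str | Path, sheet_path: str | Path) -> "ProfileSet":
        meta = pd.read_csv(sheet_path, sep="\t", index_col="sample_id")
        return cls.from_wide_tsv(wide_path, meta)


def center_and_clrvar(
    profiles: ProfileSet | np.ndarray, delta_factor: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Compositional center and per-part clr variances of replicate profiles.

    The center is the closed geometric mean; the variances are the diagonal
    of the covariance matrix of the clr-transformed profiles (sample
    covariance, n-1).  Together they parameterize the logistic-normal model
    used by the acceptance simulation.
    """
    x = profiles.values if isinstance(profiles, ProfileSet) else np.asarray(profiles, dtype=float)
    x = np.atleast_2d(x)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 profiles to estimate variances")
    center = geometric_center(x, delta_factor)
    variances = clr(x, delta_factor).var(axis=0, ddof=1)
    return center, variances
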