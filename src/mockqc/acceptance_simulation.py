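"""Simulation-based guidance values for allowable measurement errors.

The accuracy of a mock-community measurement is judged against two sources
of uncertainty: (i) the formulation itself — each strain's assigned
abundance carries a relative standard deviation of 5% (DNA mock, blended by
fluorometric total-DNA quantification) or 10% (cell mock, blended by
adenine-content quantification of whole cells) — and (ii) the measurement
process, modelled as a logistic normal around the compositional center of
replicate profiles with diagonal clr covariance.

Both arms are simulated, random (formulated, measured) pairs are drawn, and
the 95th percentile of the pairwise gmAFD becomes the allowable error; the
same pairs yield per-strain acceptance ranges, formulated abundance +- the
95th percentile of the absolute strain-wise difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .compositional_stats import Composition, closure, clr, replace_zeros
from .reference_data import MockReference

__all__ = [
    "SimulationConfig",
    "AcceptanceResult",
    "Verdict",
    "simulate_formulated",
    "simulate_measured",
    "allowable_error",
    "judge_measurement",
    "sample_pairs",
    "pair_gmafd_sample",
]

DEFAULT_N_DRAWS = 100_000
#: Relative sd of the assigned abundances by community, set by the
#: uncertainty of the total-DNA quantification used at formulation.
FORMULATED_REL_SD = {"dna": 0.05, "cell": 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the acceptance simulation."""

    n_draws: int = DEFAULT_N_DRAWS
    formulated_rel_sd: float = 0.05
    percentile: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 < self.formulated_rel_sd < 1.0:
            raise ValueError("formulated_rel_sd must be in (0, 1)")
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")

    @classmethod
    def for_community(cls, community: str, **kwargs) -> "SimulationConfig":
        sd = FORMULATED_REL_SD[str(community).lower()]
        return cls(formulated_rel_sd=sd, **kwargs)


@dataclass(frozen=True)
class AcceptanceResult:
    """Allowable gmAFD plus strain-wise acceptance ranges, with provenance."""

    labels: tuple[str, ...]
    allowable_gmafd: float
    strain_ranges: dict[str, tuple[float, float]]
    formulated: dict[str, float]
    percentile: float
    n_pairs: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["labels"] = list(self.labels)
        payload["strain_ranges"] = {k: list(v) for k, v in self.strain_ranges.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "AcceptanceResult":
        payload = json.loads(Path(path).read_text())
        payload["labels"] = tuple(payload["labels"])
        payload["strain_ranges"] = {
            k: (float(v[0]), float(v[1])) for k, v in payload["strain_ranges"].items()
        }
        return cls(**payload)


def simulate_formulated(ref: MockReference, cfg: SimulationConfig) -> np.ndarray:
    """Draw plausible formulated compositions (rows, percent, closed).

    Per strain, independent normal draws with the assigned abundance as mean
    and ``formulated_rel_sd`` times the mean as sd; negative draws are
    redrawn (rejection), then each row is closed to 100%.
    """
    rng = np.random.default_rng(cfg.seed)
    means = np.array([s.abundance(ref.community) for s in ref], dtype=float)
    sds = cfg.formulated_rel_sd * means
    draws = rng.normal(means, sds, size=(cfg.n_draws, means.size))
    bad = draws <= 0
    while bad.any():
        draws[bad] = rng.normal(
            np.broadcast_to(means, draws.shape)[bad],
            np.broadcast_to(sds, draws.shape)[bad],
        )
        bad = draws <= 0
    return closure(draws)


def simulate_measured(
    center: Composition | np.ndarray,
    clr_variances: np.ndarray,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> np.ndarray:
    """Draw logistic-normal compositions around a measured center.

    Multivariate normal in clr space, mean ``clr(center)`` and diagonal
    covariance ``clr_variances``, mapped back to the simplex by
    exponentiation and closure (rows, percent).
    """
    vals = center.values if isinstance(center, Composition) else np.asarray(center, dtype=float)
    var = np.asarray(clr_variances, dtype=float)
    if var.shape != (vals.size,):
        raise ValueError("clr_variances must have one entry per part")
    if np.any(var < 0):
        raise ValueError("clr variances must be non-negative")
    rng = np.random.default_rng(seed)
    mu = clr(vals)
    z = rng.normal(mu, np.sqrt(var), size=(n_draws, vals.size))
    return closure(np.exp(z))


def _pair_gmafd(f: np.ndarray, m: np.ndarray, delta_factor: float = 0.5) -> np.ndarray:
    lf = np.log(replace_zeros(f, delta_factor))
    lm = np.log(replace_zeros(m, delta_factor))
    return np.exp(np.abs(lf - lm).mean(axis=1))


def sample_pairs(
    formulated_draws: np.ndarray,
    measured_draws: np.ndarray,
    n_pairs: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """The random (formulated, measured) pair sample used by ``allowable_error``.

    Pairs are drawn uniformly with replacement, one member from each arm;
    the same ``seed`` reproduces exactly the sample the threshold was set on.
    """
    f = np.atleast_2d(np.asarray(formulated_draws, dtype=float))
    m = np.atleast_2d(np.asarray(measured_draws, dtype=float))
    rng = np.random.default_rng(seed)
    fi = rng.integers(0, f.shape[0], size=n_pairs)
    mi = rng.integers(0, m.shape[0], size=n_pairs)
    return f[fi], m[mi]


def pair_gmafd_sample(
    formulated_draws: np.ndarray,
    measured_draws: np.ndarray,
    n_pairs: int,
    seed: int,
) -> np.ndarray:
    """gmAFD of each sampled (formulated, measured) pair."""
    fp, mp = sample_pairs(formulated_draws, measured_draws, n_pairs, seed)
    return _pair_gmafd(fp, mp)


def allowable_error(
    formulated_draws: np.ndarray,
    measured_draws: np.ndarray,
    labels: tuple[str, ...],
    formulated: Composition | np.ndarray,
    percentile: float = 95.0,
    n_pairs: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> AcceptanceResult:
    """Derive the allowable gmAFD and strain-wise acceptance ranges.

    ``n_pairs`` random (formulated, measured) pairs are sampled with
    replacement, one member from each arm.  The allowable gmAFD is the
    requested percentile (linear-interpolation empirical quantile) of the
    pairwise gmAFD distribution; each strain's acceptance range is its
    formulated abundance +- the same percentile of the absolute strain-wise
    abundance difference over the same pairs, floored at zero.
    """
    f = np.atleast_2d(np.asarray(formulated_draws, dtype=float))
    m = np.atleast_2d(np.asarray(measured_draws, dtype=float))
    if f.shape[1] != m.shape[1] or f.shape[1] != len(labels):
        raise ValueError("arms and labels disagree on the number of strains")
    if n_pairs < 100:
        warnings.warn("fewer than 100 pairs yields unstable percentile estimates", stacklevel=2)
    fp, mp = sample_pairs(f, m, n_pairs, seed)
    gm = _pair_gmafd(fp, mp)
    threshold = float(np.percentile(gm, percentile))
    abs_diff_p = np.percentile(np.abs(fp - mp), percentile, axis=0)
    form = (
        formulated.aligned_values(labels)
        if isinstance(formulated, Composition)
        else closure(np.asarray(formulated, dtype=float))
    )
    ranges = {
        lab: (max(0.0, float(form[i] - abs_diff_p[i])), float(form[i] + abs_diff_p[i]))
        for i, lab in enumerate(labels)
    }
    return AcceptanceResult(
        labels=tuple(labels),
        allowable_gmafd=threshold,
        strain_ranges=ranges,
        formulated={lab: float(v) for lab, v in zip(labels, form)},
        percentile=float(percentile),
        n_pairs=int(n_pairs),
        seed=int(seed),
    )


@dataclass(frozen=True)
class Verdict:
    """Outcome of judging one measurement against the guidance values."""

    gmafd: float
    passed: bool
    strain_in_range: dict[str, bool]
    out_of_range: tuple[str, ...] = field(default=())


def judge_measurement(
    measured: Composition, formulated: Composition, acc: AcceptanceResult
) -> Verdict:
    """Compare a measured profile to the formulated one under guidance values."""
    from .compositional_stats import gmafd as _gmafd

    m = measured.aligned_values(acc.labels)
    f = formulated.aligned_values(acc.labels)
    g = float(_gmafd(m, f))
    flags = {}
    for i, lab in enumerate(acc.labels):
        low, high = acc.strain_ranges[lab]
        flags[lab] = bool(low <= m[i] <= high)
    out = tuple(lab for lab, ok in flags.items() if not ok)
    return Verdict(gmafd=g, passed=g <= acc.allowable_gmafd, strain_in_range=flags, out_of_range=out)
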