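"""Switching statistics on the inter-ring torsion lambda.

A "switch" in intramolecular aromatic ring organization is a frame-to-frame
change of the wrapped torsion of at least the threshold (default 20
degrees, inclusive).  Per-molecule switch counts are averaged across the
population to give ``x_bar``; the homogeneity parameter ``eta`` is the
ratio of the largest to the smallest ``x_bar`` across a sequence's amide
states (eta ~ 1 means side-chain torsional exploration is independent of
the backbone amide configuration).

Two conventions for the frame-to-frame change are provided:

``literal``
    |lam[i+1] - lam[i]| on the wrapped [0, 360) values — the procedure as
    stated, which counts a spurious switch when the torsion drifts across
    the 0/360 seam.
``circular``
    min(d, 360 - d), the true angular distance, immune to the seam.

The default is ``literal``; every summary records the convention used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ringdyn.errors import InsufficientDataError

__all__ = [
    "SwitchSummary",
    "BootstrapResult",
    "HomogeneityReport",
    "delta_lambda",
    "count_switches",
    "mean_switches",
    "bootstrap_x_bar",
    "bootstrap_x_bar_steps",
    "compute_eta",
    "bootstrap_eta",
    "write_summary",
]

DEFAULT_THRESHOLD = 20.0
DEFAULT_N_RESAMPLES = 1000


@dataclass
class SwitchSummary:
    """Per-population switch counts for one amide state."""

    per_molecule_switches: list[int]
    x_bar: float
    threshold: float = DEFAULT_THRESHOLD
    convention: str = "literal"
    label: object | None = None

    def __post_init__(self):
        counts = self.per_molecule_switches
        if counts and not (min(counts) <= self.x_bar <= max(counts)):
            raise ValueError("x_bar outside per-molecule extremes")


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the population mean x_bar."""

    resampled_x_bars: np.ndarray
    mean: float
    sd: float
    n_resamples: int
    seed: int

    def interval(self, level: float = 0.99) -> tuple[float, float]:
        """Central percentile interval of the bootstrap distribution."""
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.resampled_x_bars, [alpha, 1.0 - alpha])
        return float(lo), float(hi)


@dataclass
class HomogeneityReport:
    """eta = max(x_bar) / min(x_bar) across amide states."""

    x_bar_by_state: dict
    x_bar_max: float
    x_bar_min: float
    eta: float
    degenerate: bool = False  # True when x_bar_min == 0 (eta = +inf)


def delta_lambda(lam: Sequence[float], convention: str = "literal") -> np.ndarray:
    """Frame-to-frame torsion change, length ``n_frames - 1``, degrees >= 0.

    ``literal`` takes |lam[i+1] - lam[i]| on the wrapped values; ``circular``
    folds that through min(d, 360 - d).
    """
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 1:
        raise ValueError("delta_lambda expects a 1D per-frame series")
    if len(lam) < 2:
        raise InsufficientDataError(
            f"need at least 2 frames for switching analysis, got {len(lam)}"
        )
    d = np.abs(np.diff(lam))
    if convention == "literal":
        return d
    if convention == "circular":
        return np.minimum(d, 360.0 - d)
    raise ValueError(f"unknown convention {convention!r}; use 'literal' or 'circular'")


def count_switches(dlam: Sequence[float], threshold: float = DEFAULT_THRESHOLD) -> int:
    """Number of steps with delta-lambda >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return int(np.count_nonzero(np.asarray(dlam, dtype=float) >= threshold))


def mean_switches(
    lambda_series: Sequence[Sequence[float]],
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "literal",
    label=None,
) -> SwitchSummary:
    """Population mean switches per molecule, x_bar.

    ``lambda_series`` holds one wrapped lambda series per molecule (or
    objects with a ``.lam`` attribute, e.g. :class:`DescriptorSeries`).
    """
    series = [getattr(s, "lam", s) for s in lambda_series]
    if len(series) == 0:
        raise InsufficientDataError("need at least one molecule")
    counts = [
        count_switches(delta_lambda(lam, convention=convention), threshold=threshold)
        for lam in series
    ]
    return SwitchSummary(
        per_molecule_switches=counts,
        x_bar=float(np.mean(counts)),
        threshold=threshold,
        convention=convention,
        label=label,
    )


def bootstrap_x_bar(
    per_molecule_switches: Sequence[int],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap x_bar by resampling molecules with replacement.

    The resampling unit is the per-molecule switch count, because x_bar is
    defined as a mean over molecules.  Deterministic given ``seed``.
    """
    counts = np.asarray(per_molecule_switches, dtype=float)
    if counts.size < 2:
        raise InsufficientDataError("bootstrap needs at least 2 molecules")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, counts.size, size=(n_resamples, counts.size))
    means = counts[idx].mean(axis=1)
    return BootstrapResult(
        resampled_x_bars=means,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        n_resamples=n_resamples,
        seed=seed,
    )


def bootstrap_x_bar_steps(
    lambda_series: Sequence[Sequence[float]],
    threshold: float = DEFAULT_THRESHOLD,
    convention: str = "literal",
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> BootstrapResult:
    """Alternative bootstrap resampling frame-level delta-lambda values.

    For each replicate, every molecule's per-step delta-lambda series is
    resampled with replacement, switches recounted, and the molecule mean
    taken.  Provided because "bootstrapping the delta-lambda values" can be
    read at either the molecule or the frame level; molecule-level
    (:func:`bootstrap_x_bar`) is the default elsewhere.
    """
    series = [getattr(s, "lam", s) for s in lambda_series]
    if len(series) < 2:
        raise InsufficientDataError("bootstrap needs at least 2 molecules")
    dlams = [delta_lambda(lam, convention=convention) for lam in series]
    rng = np.random.default_rng(seed)
    means = np.empty(n_resamples)
    exceed = [(d >= threshold).astype(float) for d in dlams]
    for r in range(n_resamples):
        per_mol = [
            e[rng.integers(0, e.size, size=e.size)].sum() for e in exceed
        ]
        means[r] = np.mean(per_mol)
    return BootstrapResult(
        resampled_x_bars=means,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        n_resamples=n_resamples,
        seed=seed,
    )


def compute_eta(x_bar_by_state: Mapping) -> HomogeneityReport:
    """Homogeneity parameter across amide states.

    eta = x_bar_max / x_bar_min over the per-state population means; equals
    1.0 exactly when all states sample lambda switches at the same mean
    rate.  A zero minimum yields eta = +inf with a warning (degenerate but
    representable) rather than an exception.
    """
    if len(x_bar_by_state) < 2:
        raise InsufficientDataError(
            f"eta needs >= 2 amide states, got {len(x_bar_by_state)}"
        )
    values = {k: float(getattr(v, "x_bar", v)) for k, v in x_bar_by_state.items()}
    x_max = max(values.values())
    x_min = min(values.values())
    if x_min < 0:
        raise ValueError("switch means cannot be negative")
    if x_min == 0.0:
        warnings.warn(
            "minimum x_bar is 0; eta is infinite for this state family",
            stacklevel=2,
        )
        return HomogeneityReport(values, x_max, x_min, float("inf"), degenerate=True)
    return HomogeneityReport(values, x_max, x_min, x_max / x_min)


def bootstrap_eta(
    counts_by_state: Mapping[object, Sequence[int]],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap distribution of eta.

    Each replicate resamples every state's per-molecule switch counts with
    replacement (independently across states, split from one seed) and
    recomputes max/min of the state means.  Replicates in which some state
    mean is zero give +inf entries.
    """
    if len(counts_by_state) < 2:
        raise InsufficientDataError("eta bootstrap needs >= 2 states")
    rng = np.random.default_rng(seed)
    states = list(counts_by_state)
    arrays = [np.asarray(counts_by_state[s], dtype=float) for s in states]
    for s, a in zip(states, arrays):
        if a.size < 2:
            raise InsufficientDataError(f"state {s}: bootstrap needs >= 2 molecules")
    means = np.empty((len(states), n_resamples))
    for i, a in enumerate(arrays):
        idx = rng.integers(0, a.size, size=(n_resamples, a.size))
        means[i] = a[idx].mean(axis=1)
    x_max = means.max(axis=0)
    x_min = means.min(axis=0)
    with np.errstate(divide="ignore"):
        return np.where(x_min > 0, x_max / np.where(x_min > 0, x_min, 1.0), np.inf)


def write_summary(
    summaries: Mapping[str, SwitchSummary],
    bootstraps: Mapping[str, BootstrapResult],
    report: HomogeneityReport,
    path_tsv,
    path_json,
) -> None:
    """Export per-state switch statistics as TSV plus a JSON report."""
    rows = []
    for state, summ in summaries.items():
        boot = bootstraps.get(state)
        rows.append(
            {
                "state": state,
                "x_bar": summ.x_bar,
                "bootstrap_mean": boot.mean if boot else np.nan,
                "bootstrap_sd": boot.sd if boot else np.nan,
                "threshold": summ.threshold,
                "convention": summ.convention,
                "per_molecule_counts": ",".join(map(str, summ.per_molecule_switches)),
            }
        )
    pd.DataFrame(rows).to_csv(Path(path_tsv), sep="\t", index=False)
    payload = {
        "x_bar_by_state": report.x_bar_by_state,
        "x_bar_max": report.x_bar_max,
        "x_bar_min": report.x_bar_min,
        "eta": report.eta if np.isfinite(report.eta) else "inf",
        "degenerate": report.degenerate,
        "bootstrap": {
            state: {
                "mean": b.mean,
                "sd": b.sd,
                "n_resamples": b.n_resamples,
                "seed": b.seed,
            }
            for state, b in bootstraps.items()
        },
    }
    Path(path_json).write_text(json.dumps(payload, indent=2))
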