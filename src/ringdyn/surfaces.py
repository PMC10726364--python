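"""2D rho–lambda occupancy surfaces.

Raw occupancy histograms of every (rho, lambda) combination across all
frames and molecules of an ensemble, with a sampled/unsampled bin mask and
a quantitative histogram-intersection overlap between surfaces.  No
free-energy transform and no density smoothing: the surface is the count
matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ringdyn.errors import InsufficientDataError, UsageError

__all__ = [
    "RhoLambdaSurface",
    "build_surface",
    "surface_overlap",
    "signed_lambda_view",
    "surface_to_tsv",
    "surface_to_dense",
    "render_surface",
]

DEFAULT_N_BINS = 60
DEFAULT_RHO_RANGE = (0.0, 2.0)


@dataclass
class RhoLambdaSurface:
    """Occupancy histogram over (rho, lambda).

    ``counts[i, j]`` is the number of frame-molecule points whose rho falls
    in ``rho_edges[i:i+2]`` and lambda in ``lam_edges[j:j+2]``.  Points
    outside the rho range are tallied in ``out_of_range``, never dropped
    silently: ``total + out_of_range`` equals the number of input points.
    """

    counts: np.ndarray
    rho_edges: np.ndarray
    lam_edges: np.ndarray
    out_of_range: int = 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def mask(self) -> np.ndarray:
        """True where a bin has been sampled at least once."""
        return self.counts > 0


def build_surface(
    series,
    n_bins: int = DEFAULT_N_BINS,
    rho_range: tuple[float, float] = DEFAULT_RHO_RANGE,
) -> RhoLambdaSurface:
    """Histogram every (rho, lambda) pair of every molecule and frame.

    ``series`` is a list of :class:`DescriptorSeries` (or any objects with
    ``rho``/``lam`` arrays).  ``n_bins`` bins per axis (60 by default);
    lambda is binned on [0, 360).  Point conservation holds exactly:
    in-range total + out-of-range = frames x molecules.
    """
    if not series:
        raise InsufficientDataError("need at least one descriptor series")
    rho = np.concatenate([np.asarray(s.rho, float).ravel() for s in series])
    lam = np.concatenate([np.asarray(s.lam, float).ravel() for s in series])
    if rho.size == 0:
        raise InsufficientDataError("descriptor series are empty")
    counts, rho_edges, lam_edges = np.histogram2d(
        rho, lam, bins=n_bins, range=[list(rho_range), [0.0, 360.0]]
    )
    counts = counts.astype(np.int64)
    return RhoLambdaSurface(
        counts=counts,
        rho_edges=rho_edges,
        lam_edges=lam_edges,
        out_of_range=int(rho.size - counts.sum()),
    )


def surface_overlap(a: RhoLambdaSurface, b: RhoLambdaSurface) -> float:
    """Histogram intersection of two count-normalized surfaces, in [0, 1].

    sum_b min(a_hat, b_hat) over bins; 1.0 for identical occupancy
    patterns, 0.0 for disjoint support.  Symmetric and invariant to scaling
    both surfaces' counts.
    """
    if a.counts.shape != b.counts.shape or not (
        np.allclose(a.rho_edges, b.rho_edges) and np.allclose(a.lam_edges, b.lam_edges)
    ):
        raise UsageError("surfaces must share identical binning for overlap")
    if a.total == 0 or b.total == 0:
        raise InsufficientDataError("cannot compare an empty surface")
    pa = a.counts / a.total
    pb = b.counts / b.total
    return float(np.minimum(pa, pb).sum())


def signed_lambda_view(surface: RhoLambdaSurface) -> RhoLambdaSurface:
    """Display-only remap of the lambda axis from [0, 360) to (-180, 180].

    Requires an even number of lambda bins so the seam falls on an edge.
    """
    n = surface.counts.shape[1]
    if n % 2:
        raise UsageError("signed lambda view needs an even number of lambda bins")
    half = n // 2
    counts = np.concatenate([surface.counts[:, half:], surface.counts[:, :half]], axis=1)
    lam_edges = np.concatenate(
        [surface.lam_edges[half:-1] - 360.0, surface.lam_edges[: half + 1]]
    )
    return RhoLambdaSurface(
        counts=counts,
        rho_edges=surface.rho_edges.copy(),
        lam_edges=lam_edges,
        out_of_range=surface.out_of_range,
    )


def surface_to_tsv(surface: RhoLambdaSurface, path) -> None:
    """Export (rho_center, lam_center, count) triples as TSV."""
    rc = 0.5 * (surface.rho_edges[:-1] + surface.rho_edges[1:])
    lc = 0.5 * (surface.lam_edges[:-1] + surface.lam_edges[1:])
    rr, ll = np.meshgrid(rc, lc, indexing="ij")
    pd.DataFrame(
        {
            "rho_center": rr.ravel(),
            "lam_center": ll.ravel(),
            "count": surface.counts.ravel(),
        }
    ).to_csv(Path(path), sep="\t", index=False)


def surface_to_dense(surface: RhoLambdaSurface, path) -> None:
    """Export the raw count matrix as whitespace-delimited text."""
    header = (
        f"rho-lambda occupancy counts; rows = rho bins "
        f"[{surface.rho_edges[0]}, {surface.rho_edges[-1]}], "
        f"cols = lambda bins [{surface.lam_edges[0]}, {surface.lam_edges[-1]}] deg; "
        f"out_of_range={surface.out_of_range}"
    )
    np.savetxt(Path(path), surface.counts, fmt="%d", header=header)


def render_surface(surface: RhoLambdaSurface, path, title: str = "", signed: bool = True):
    """Render the occupancy surface; unsampled bins drawn on a beige field."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surf = signed_lambda_view(surface) if signed else surface
    masked = np.ma.masked_where(~surf.mask, surf.counts)
    fig, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("#f5f0dc")  # beige = unsampled
    mesh = ax.pcolormesh(surf.lam_edges, surf.rho_edges, masked, cmap=cmap)
    ax.set_xlabel(r"$\lambda$ (degrees)")
    ax.set_ylabel(r"$\rho$")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="occupancy")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
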