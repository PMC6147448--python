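"""Classical (Torgerson) metric multidimensional scaling.

Double-centers -d^2/2, eigendecomposes, and scales the top eigenvectors by
the square roots of their eigenvalues.  Deterministic, so recoverable
configurations (distances Euclidean-embeddable in the requested dimension)
are reproduced exactly up to rotation/reflection; the sign convention fixes
reflections by orienting each axis so that its largest-magnitude coordinate
is positive.  Negative eigenvalue mass (non-Euclidean input) is reported as
a diagnostic rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .popgen import DistanceMatrix


@dataclass
class MDSResult:
    labels: list[str]
    coordinates: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    goodness: float = 0.0
    negative_mass: float = 0.0


def classical_mds(m: DistanceMatrix, dims: int = 2) -> MDSResult:
    """Embed a distance matrix into ``dims`` coordinates.

    Requires at least 3 populations.  If fewer than ``dims`` positive
    eigenvalues exist, the remaining axes are zero-padded with a warning.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("classical MDS needs at least 3 populations")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    d2 = np.asarray(m.values, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = 1e-12 * max(1.0, float(np.max(np.abs(evals))))
    pos = np.where(evals > tol, evals, 0.0)
    n_pos = int(np.sum(pos > 0))
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding to {dims} axes "
            "with zeros"
        )
    coords = evecs[:, :dims] * np.sqrt(pos[:dims])

    # orient each axis so its largest-magnitude coordinate is positive
    for k in range(dims):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col

    total_pos = float(np.sum(pos))
    goodness = float(np.sum(pos[:dims]) / total_pos) if total_pos > 0 else 1.0
    neg_mass = float(np.sum(np.abs(evals[evals < 0])))
    return MDSResult(
        labels=list(m.labels),
        coordinates=coords,
        eigenvalues=evals,
        goodness=goodness,
        negative_mass=neg_mass,
    )


def mds_report(
    result: MDSResult,
    tsv_path: str | Path,
    plot_path: str | Path | None = None,
) -> None:
    """Write a coordinate TSV and, optionally, a labelled scatter plot."""
    import pandas as pd

    dims = result.coordinates.shape[1]
    df = pd.DataFrame(
        result.coordinates,
        columns=[f"dim{k + 1}" for k in range(dims)],
    )
    df.insert(0, "label", result.labels)
    df.to_csv(tsv_path, sep="\t", index=False)

    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        x = result.coordinates[:, 0]
        y = result.coordinates[:, 1] if dims > 1 else np.zeros_like(x)
        ax.scatter(x, y)
        for xi, yi, lab in zip(x, y, result.labels):
            ax.annotate(lab, (xi, yi), textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel(f"dim 1 ({100 * result.goodness:.0f}% of positive mass in shown axes)")
        ax.set_ylabel("dim 2")
        ax.axhline(0, lw=0.4, color="grey")
        ax.axvline(0, lw=0.4, color="grey")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
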