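"""Haplotype sharing between two series.

Two lineages are "identical" when their canonical certain-substitution sets
match (uncertain calls and indels are ignored, consistently with the
sequence-distance defaults).  Two normalizations are reported because the
literature uses both: the fraction of A's *individuals* whose haplotype
occurs in B (the headline statistic here) and the fraction of A's
*distinct haplotypes* occurring in B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HVRIHaplotype, SeriesTable


def _key(h: HVRIHaplotype) -> frozenset[tuple[int, str]]:
    return frozenset((v.position, v.derived) for v in h.substitutions())


@dataclass(frozen=True)
class SharingResult:
    shared_haplotypes: frozenset
    n_shared_haplotypes: int
    fraction_individuals_a_in_b: float  # percent, 0-100
    fraction_haplotypes_a_in_b: float  # percent, 0-100
    missing_haplotypes_a_not_in_b: int


def sharing(pop_a: SeriesTable, pop_b: SeriesTable) -> SharingResult:
    """Sharing of A's lineages with B, at individual and haplotype level."""
    if not len(pop_a) or not len(pop_b):
        raise ValueError("sharing requires two non-empty populations")
    keys_a = [_key(r.hvr1) for r in pop_a]
    set_a = set(keys_a)
    set_b = {_key(r.hvr1) for r in pop_b}
    shared = set_a & set_b
    n_ind = sum(1 for k in keys_a if k in set_b)
    return SharingResult(
        shared_haplotypes=frozenset(shared),
        n_shared_haplotypes=len(shared),
        fraction_individuals_a_in_b=100.0 * n_ind / len(pop_a),
        fraction_haplotypes_a_in_b=100.0 * len(shared) / len(set_a),
        missing_haplotypes_a_not_in_b=len(set_a - set_b),
    )


def sharing_matrix(
    pops: list[SeriesTable], labels: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Row A, column B = % of A's individuals with a haplotype present in B.

    The diagonal is 100 by construction; the matrix is not symmetric in
    general.
    """
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    if labels is None:
        labels = [getattr(p, "name", f"pop{i}") for i, p in enumerate(pops)]
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 100.0
            else:
                out[i, j] = sharing(pops[i], pops[j]).fraction_individuals_a_in_b
    return list(labels), out
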