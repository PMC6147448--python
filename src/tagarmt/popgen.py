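"""Frequency spectra, diversity counts, and pairwise F_ST.

Two F_ST estimators are provided, mirroring the two ways ancient-series
comparisons are normally run:

* ``fst_sequences`` — from HVRI sequences, F_ST = (pi_B - pi_W) / pi_B with
  pi_W the unweighted mean of the two within-population mean pairwise
  differences and pi_B the between-population mean pairwise difference.
* ``fst_frequencies`` — from haplogroup frequency spectra, the single-locus
  multi-allelic form (H_T - H_S) / H_T with H = 1 - sum(freq^2), H_S the
  unweighted mean within-population gene diversity and H_T computed from the
  mean allele frequencies.

Significance comes from a Monte-Carlo permutation test that reshuffles
individuals between the two populations preserving sample sizes; the p-value
uses the add-one estimator p = (1 + #{permuted >= observed}) / (n + 1).
Negative raw estimates are clamped to zero before Slatkin linearization
F_ST / (1 - F_ST).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .haplogroups import MotifTable, macro_cluster
from .io import HVRIHaplotype, SeriesTable, format_haplotype


@dataclass
class FrequencySpectrum:
    """Counts of haplotypes (canonical text) or haplogroup labels."""

    counts: dict[str, int]
    total: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("spectrum counts must be >= 1")
        observed = sum(self.counts.values())
        if self.total == 0:
            self.total = observed
        elif self.total != observed:
            raise ValueError("total does not match sum of counts")

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    def frequencies(self) -> dict[str, float]:
        return {k: c / self.total for k, c in self.counts.items()}

    def modal(self) -> tuple[str, int]:
        return max(self.counts.items(), key=lambda kv: (kv[1], kv[0]))


@dataclass(frozen=True)
class FstResult:
    fst: float
    linearized: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v


def haplotype_spectrum(table: SeriesTable) -> FrequencySpectrum:
    """Haplotype frequency spectrum keyed by canonical haplotype text."""
    if not len(table):
        raise ValueError("empty series table")
    counts = Counter(format_haplotype(r.hvr1) for r in table)
    return FrequencySpectrum(dict(counts))


def haplogroup_spectrum(table: SeriesTable) -> FrequencySpectrum:
    if not len(table):
        raise ValueError("empty series table")
    for r in table:
        if not r.haplogroup_label or r.haplogroup_label == "unassigned":
            raise ValueError(f"record {r.sample_id} has no haplogroup label")
    return FrequencySpectrum(dict(Counter(r.haplogroup_label for r in table)))


def macro_fractions(
    table: SeriesTable, motifs: MotifTable | None = None
) -> tuple[float, float]:
    """(West, East) fractions of a fully labelled series."""
    if not len(table):
        raise ValueError("empty series table")
    n_east = 0
    for r in table:
        if not r.haplogroup_label or r.haplogroup_label == "unassigned":
            raise ValueError(f"record {r.sample_id} is unassigned")
        if macro_cluster(r.haplogroup_label, motifs) == "East":
            n_east += 1
    return 1 - n_east / len(table), n_east / len(table)


def haplogroup_frequency(
    table: SeriesTable, labels: set[str] | Sequence[str], motifs: MotifTable
) -> float:
    """Fraction of records whose haplogroup is in ``labels`` or nested below.

    Nesting follows the motif table's parent links, so querying ``U4`` also
    counts ``U4a3`` carriers.  Labels unknown to the table raise.
    """
    wanted = set(labels) if not isinstance(labels, str) else {labels}
    for lab in wanted:
        if lab not in motifs:
            raise ValueError(f"unknown haplogroup label {lab!r}")
    n = 0
    for r in table:
        if not r.haplogroup_label or r.haplogroup_label == "unassigned":
            raise ValueError(f"record {r.sample_id} is unassigned")
        lineage = (
            set(motifs.lineage(r.haplogroup_label))
            if r.haplogroup_label in motifs
            else {r.haplogroup_label}
        )
        if lineage & wanted:
            n += 1
    if not len(table):
        raise ValueError("empty series table")
    return n / len(table)


def pairwise_sequence_distance(
    h1: HVRIHaplotype,
    h2: HVRIHaplotype,
    include_uncertain: bool = False,
    include_indels: bool = False,
) -> int:
    """Number of HVRI positions at which the two haplotypes differ.

    Differences are counted on the implied sequences: a position carried by
    only one haplotype differs from the reference state, and a position
    substituted to different bases in both differs once.  Uncertain calls
    and indels are excluded by default.
    """
    s1 = {v.position: v.derived for v in h1.substitutions(include_uncertain)}
    s2 = {v.position: v.derived for v in h2.substitutions(include_uncertain)}
    d = sum(1 for p in set(s1) | set(s2) if s1.get(p) != s2.get(p))
    if include_indels:
        k1 = {v.key for v in h1.variants if v.kind != "substitution"}
        k2 = {v.key for v in h2.variants if v.kind != "substitution"}
        d += len(k1 ^ k2)
    return d


def _mean_within(haps: Sequence[HVRIHaplotype], **kw) -> float:
    pairs = list(itertools.combinations(haps, 2))
    if not pairs:
        return 0.0
    return float(
        np.mean([pairwise_sequence_distance(a, b, **kw) for a, b in pairs])
    )


def _mean_between(
    a: Sequence[HVRIHaplotype], b: Sequence[HVRIHaplotype], **kw
) -> float:
    return float(
        np.mean(
            [pairwise_sequence_distance(x, y, **kw) for x in a for y in b]
        )
    )


def _fst_from_haplotype_lists(
    a: Sequence[HVRIHaplotype], b: Sequence[HVRIHaplotype], **kw
) -> float:
    pi_w = 0.5 * (_mean_within(a, **kw) + _mean_within(b, **kw))
    pi_b = _mean_between(a, b, **kw)
    if pi_b == 0:
        return 0.0
    return float(np.clip((pi_b - pi_w) / pi_b, 0.0, 1.0))


def slatkin_linearized(fst: float) -> float:
    """Slatkin's distance transform F_ST / (1 - F_ST)."""
    if not 0 <= fst < 1:
        if fst == 1.0:
            return float("inf")
        raise ValueError("F_ST must lie in [0, 1]")
    return fst / (1 - fst)


def fst_sequences(
    pop_a: SeriesTable,
    pop_b: SeriesTable,
    n_permutations: int = 0,
    seed: int | None = None,
    include_uncertain: bool = False,
    include_indels: bool = False,
) -> FstResult:
    """Sequence-based pairwise F_ST with optional permutation p-value."""
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 records")
    kw = dict(include_uncertain=include_uncertain, include_indels=include_indels)
    a, b = pop_a.haplotypes(), pop_b.haplotypes()
    fst = _fst_from_haplotype_lists(a, b, **kw)
    p = None
    if n_permutations:
        p = permutation_test(
            a, b, lambda x, y: _fst_from_haplotype_lists(x, y, **kw),
            n=n_permutations, seed=seed, observed=fst,
        )
    return FstResult(fst, slatkin_linearized(fst), p, n_permutations, seed)


def _gene_diversity(freqs: np.ndarray) -> float:
    return float(1.0 - np.sum(freqs**2))


def _fst_from_spectra(
    fa: Mapping[str, float], fb: Mapping[str, float]
) -> float:
    labels = sorted(set(fa) | set(fb))
    pa = np.array([fa.get(k, 0.0) for k in labels])
    pb = np.array([fb.get(k, 0.0) for k in labels])
    h_s = 0.5 * (_gene_diversity(pa) + _gene_diversity(pb))
    h_t = _gene_diversity((pa + pb) / 2)
    if h_t == 0:
        warnings.warn("both populations monomorphic for the same label")
        return 0.0
    return float(np.clip((h_t - h_s) / h_t, 0.0, 1.0))


def fst_frequencies(
    spec_a: FrequencySpectrum,
    spec_b: FrequencySpectrum,
    n_permutations: int = 0,
    seed: int | None = None,
) -> FstResult:
    """Haplogroup-frequency-based pairwise F_ST (single locus, multi-allelic)."""
    fst = _fst_from_spectra(spec_a.frequencies(), spec_b.frequencies())
    p = None
    if n_permutations:
        # permute label assignments of pooled individuals
        items_a = [k for k, c in spec_a.counts.items() for _ in range(c)]
        items_b = [k for k, c in spec_b.counts.items() for _ in range(c)]

        def stat(xs: Sequence[str], ys: Sequence[str]) -> float:
            sa = FrequencySpectrum(dict(Counter(xs)))
            sb = FrequencySpectrum(dict(Counter(ys)))
            return _fst_from_spectra(sa.frequencies(), sb.frequencies())

        p = permutation_test(
            items_a, items_b, stat, n=n_permutations, seed=seed, observed=fst
        )
    return FstResult(fst, slatkin_linearized(fst), p, n_permutations, seed)


def permutation_test(
    pop_a: Sequence,
    pop_b: Sequence,
    statistic: Callable[[Sequence, Sequence], float],
    n: int = 100,
    seed: int | None = None,
    observed: float | None = None,
) -> float:
    """Monte-Carlo label permutation preserving sample sizes.

    Returns p = (1 + #{permuted statistic >= observed}) / (n + 1), so the
    smallest attainable p at the default n = 100 interchanges is 1/101.
    """
    if n < 1:
        raise ValueError("need at least one permutation")
    if observed is None:
        observed = statistic(pop_a, pop_b)
    rng = np.random.default_rng(seed)
    pooled = list(pop_a) + list(pop_b)
    na = len(pop_a)
    hits = 0
    for _ in range(n):
        idx = rng.permutation(len(pooled))
        xa = [pooled[i] for i in idx[:na]]
        xb = [pooled[i] for i in idx[na:]]
        if statistic(xa, xb) >= observed:
            hits += 1
    return (1 + hits) / (n + 1)


def build_distance_matrix(
    pops: Sequence[SeriesTable] | Sequence[FrequencySpectrum],
    statistic: str = "sequences",
    linearize: bool = False,
    labels: Sequence[str] | None = None,
    **kwargs,
) -> DistanceMatrix:
    """Pairwise F_ST matrix over populations (optionally Slatkin-linearized)."""
    n = len(pops)
    if n < 2:
        raise ValueError("need at least 2 populations")
    if labels is None:
        labels = [
            getattr(p, "name", f"pop{i}") for i, p in enumerate(pops)
        ]
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            if statistic == "sequences":
                res = fst_sequences(pops[i], pops[j], **kwargs)
            elif statistic == "frequencies":
                res = fst_frequencies(pops[i], pops[j], **kwargs)
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
        except ValueError as exc:
            raise ValueError(
                f"pair ({labels[i]}, {labels[j]}): {exc}"
            ) from exc
        vals[i, j] = vals[j, i] = res.linearized if linearize else res.fst
    return DistanceMatrix(list(labels), vals)
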