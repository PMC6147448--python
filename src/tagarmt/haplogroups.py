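"""Rule-based mtDNA haplogroup assignment and West/East macro-clustering.

A :class:`MotifRule` pairs mandatory coding-region diagnostic SNPs with the
HVRI motif expected on that background.  Assignment finds every rule whose
coding markers *and* motif are all present in a sample and keeps the deepest
one (then highest score, then lexicographically smallest label).  Paragroup
rules carry star labels (``HV*``, ``U*``) and match samples whose nested
child motifs are absent.

The bundled table is the minimal rule set consistent with the haplogroups
observed in the bundled Iron Age series; it is not a complete mtDNA
phylogeny.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io import (
    CodingCall,
    HVRIHaplotype,
    SampleRecord,
    SeriesTable,
    VariantCall,
    parse_coding_string,
)

UNASSIGNED = "unassigned"

#: top-level haplogroup roots and their Eurasian macro-cluster
MACRO_OF_ROOT = {
    "A": "East",
    "C": "East",
    "D": "East",
    "F": "East",
    "G": "East",
    "H": "West",
    "HV": "West",
    "I": "West",
    "J": "West",
    "K": "West",
    "T": "West",
    "U": "West",
    "V": "West",
    "W": "West",
    "X": "West",
}


@dataclass(frozen=True)
class MotifRule:
    label: str
    parent: str | None
    coding: frozenset[CodingCall]
    hvr1: frozenset[VariantCall]
    macro: str

    def matches(self, sample: SampleRecord) -> bool:
        """All coding markers and all motif variants present in the sample."""
        if not self.coding <= sample.coding:
            return False
        observed = {(v.position, v.derived) for v in sample.hvr1.substitutions(True)}
        return all((m.position, m.derived) in observed for m in self.hvr1)

    def score_against(self, sample: SampleRecord) -> float:
        expected = len(self.coding) + len(self.hvr1)
        if expected == 0:
            return 0.0
        observed = {(v.position, v.derived) for v in sample.hvr1.substitutions(True)}
        hit = sum(c in sample.coding for c in self.coding)
        hit += sum((m.position, m.derived) in observed for m in self.hvr1)
        return hit / expected


@dataclass
class MotifTable:
    rules: list[MotifRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate rule labels in motif table")
        by_label = {r.label: r for r in self.rules}
        for r in self.rules:
            if r.parent is not None:
                if r.parent not in by_label:
                    raise ValueError(f"rule {r.label}: unknown parent {r.parent}")
                if not by_label[r.parent].coding <= r.coding:
                    raise ValueError(
                        f"rule {r.label}: coding markers do not include "
                        f"parent {r.parent}'s markers"
                    )
        # cycle check: depth computation terminates iff the forest is acyclic
        for r in self.rules:
            seen = set()
            cur: MotifRule | None = r
            while cur is not None:
                if cur.label in seen:
                    raise ValueError(f"parent cycle through {cur.label}")
                seen.add(cur.label)
                cur = by_label.get(cur.parent) if cur.parent else None
        self._by_label = by_label

    def __getitem__(self, label: str) -> MotifRule:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def labels(self) -> list[str]:
        return [r.label for r in self.rules]

    def depth(self, label: str) -> int:
        d, cur = 0, self._by_label[label]
        while cur.parent is not None:
            d += 1
            cur = self._by_label[cur.parent]
        return d

    def lineage(self, label: str) -> list[str]:
        """Labels from the rule up to its root, inclusive."""
        out, cur = [], self._by_label[label]
        while True:
            out.append(cur.label)
            if cur.parent is None:
                return out
            cur = self._by_label[cur.parent]

    def root(self, label: str) -> str:
        return self.lineage(label)[-1]


@dataclass(frozen=True)
class Assignment:
    label: str
    score: float
    matched_markers: int
    tie_broken: bool = False


def _parse_motif_variant(tok: str) -> VariantCall:
    m = re.fullmatch(r"(\d+)([ACGT])", tok)
    if not m:
        raise ValueError(f"malformed motif token {tok!r}")
    return VariantCall(int(m.group(1)), m.group(2))


def load_motif_table(path: str | Path | None = None) -> MotifTable:
    """Load a motif table from JSON; default is the bundled table."""
    if path is None:
        src = resources.files("tagarmt.data").joinpath("motifs.json")
        data = json.loads(src.read_text())
    else:
        data = json.loads(Path(path).read_text())
    rules = [
        MotifRule(
            label=r["label"],
            parent=r.get("parent"),
            coding=parse_coding_string(",".join(r["coding"])),
            hvr1=frozenset(_parse_motif_variant(t) for t in r["hvr1"]),
            macro=r["macro"],
        )
        for r in data["rules"]
    ]
    return MotifTable(rules)


def default_motif_table() -> MotifTable:
    return load_motif_table(None)


def assign_haplogroup(sample: SampleRecord, table: MotifTable) -> Assignment:
    """Deepest fully-matching rule; ties broken by score, then label."""
    candidates = [r for r in table.rules if r.matches(sample)]
    if not candidates:
        return Assignment(UNASSIGNED, 0.0, 0)
    ranked = sorted(
        candidates,
        key=lambda r: (-table.depth(r.label), -r.score_against(sample), r.label),
    )
    best = ranked[0]
    tie = (
        len(ranked) > 1
        and table.depth(ranked[1].label) == table.depth(best.label)
        and ranked[1].score_against(sample) == best.score_against(sample)
    )
    return Assignment(
        best.label,
        best.score_against(sample),
        len(best.coding) + len(best.hvr1),
        tie_broken=tie,
    )


def macro_cluster(label: str, table: MotifTable | None = None) -> str:
    """West/East Eurasian macro-cluster of a haplogroup label.

    Labels present in the table inherit their root rule's cluster; unknown
    labels fall back to the longest known top-level root prefix.
    """
    if table is not None:
        stripped = label.rstrip("*")
        for cand in (label, stripped):
            if cand in table:
                return table[table.root(cand)].macro
    base = label.rstrip("*")
    for root in sorted(MACRO_OF_ROOT, key=len, reverse=True):
        if base.startswith(root):
            return MACRO_OF_ROOT[root]
    raise ValueError(
        f"cannot resolve macro-cluster of {label!r}; known roots: "
        f"{sorted(MACRO_OF_ROOT)}"
    )


def call_series(
    table: SeriesTable, motifs: MotifTable
) -> tuple[SeriesTable, dict[str, object]]:
    """Annotate every record; report concordance with pre-existing labels."""
    called, mismatches, n_unassigned = [], [], 0
    n_compared = 0
    for rec in table:
        a = assign_haplogroup(rec, motifs)
        if a.label == UNASSIGNED:
            n_unassigned += 1
        if rec.haplogroup_label:
            n_compared += 1
            if rec.haplogroup_label != a.label:
                mismatches.append((rec.sample_id, rec.haplogroup_label, a.label))
        called.append(rec.with_label(a.label))
    report = {
        "n_records": len(table),
        "n_compared": n_compared,
        "n_concordant": n_compared - len(mismatches),
        "mismatches": mismatches,
        "n_unassigned": n_unassigned,
    }
    return SeriesTable(called, name=table.name), report
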