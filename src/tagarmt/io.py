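"""Reading, validating and writing HVRI haplotype tables.

Haplotypes are stored relative to the rCRS (revised Cambridge Reference
Sequence) over the hypervariable-region-I window 15997-16409, in the
hyphen-separated notation used in the ancient-DNA literature:
``16126C-16163G-16186T-16189C-16294T``.  A token names the 1-based rCRS
position followed by the derived state; ``<pos>ins<base>`` is an insertion
after that position, ``<pos>del`` a deletion, and a parenthesized token an
uncertain call.  The bare string ``rCRS`` denotes the reference haplotype
(empty variant set).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

HVR1_START = 15997
HVR1_END = 16409

#: chronological stage implied by each burial-group code
STAGE_OF_CODE = {
    "Bain": "Early",
    "P": "Early",
    "Bidj": "Early",
    "S": "Middle",
    "T": "Late",
}

NUCLEOTIDES = frozenset("ACGT")


class HaplotypeParseError(ValueError):
    """Raised for malformed rCRS-relative haplotype notation."""


@dataclass(frozen=True, order=True)
class VariantCall:
    """One rCRS-relative change inside the HVRI window."""

    position: int
    derived: str
    kind: str = "substitution"  # substitution | insertion | deletion
    uncertain: bool = False

    def __post_init__(self) -> None:
        if not (HVR1_START <= self.position <= HVR1_END):
            raise HaplotypeParseError(
                f"position {self.position} outside HVRI window "
                f"{HVR1_START}-{HVR1_END}"
            )
        if self.kind == "substitution" and self.derived not in NUCLEOTIDES:
            raise HaplotypeParseError(
                f"substitution state {self.derived!r} at {self.position} "
                "is not one of A/C/G/T"
            )
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise HaplotypeParseError(f"unknown variant kind {self.kind!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.kind)

    def token(self) -> str:
        if self.kind == "substitution":
            core = f"{self.position}{self.derived}"
        elif self.kind == "insertion":
            core = f"{self.position}ins{self.derived}"
        else:
            core = f"{self.position}del"
        return f"({core})" if self.uncertain else core


@dataclass(frozen=True, order=True)
class CodingCall:
    """Observed state at a diagnostic position outside the HVRI window."""

    position: int
    state: str

    def __post_init__(self) -> None:
        if HVR1_START <= self.position <= HVR1_END:
            raise HaplotypeParseError(
                f"coding-region call at {self.position} lies inside the "
                "HVRI window; encode it as a VariantCall"
            )
        if self.state not in NUCLEOTIDES:
            raise HaplotypeParseError(
                f"coding state {self.state!r} at {self.position} invalid"
            )

    def token(self) -> str:
        return f"{self.position}{self.state}"


@dataclass(frozen=True)
class HVRIHaplotype:
    """A set of rCRS-relative variants; the empty set is the reference."""

    variants: frozenset[VariantCall] = frozenset()

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            dup = sorted(k for k in keys if keys.count(k) > 1)
            raise HaplotypeParseError(f"duplicate variant at {dup[0]}")

    def substitutions(self, include_uncertain: bool = False) -> frozenset[VariantCall]:
        """Certain substitutions — the default basis for distance/sharing."""
        return frozenset(
            v
            for v in self.variants
            if v.kind == "substitution" and (include_uncertain or not v.uncertain)
        )

    def positions(self) -> frozenset[int]:
        return frozenset(v.position for v in self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, item: VariantCall) -> bool:
        return item in self.variants


def parse_variant_token(token: str) -> VariantCall:
    """Parse one variant token, e.g. ``16126C``, ``(16193insC)``, ``16166del``."""
    raw = token.strip()
    uncertain = raw.startswith("(") and raw.endswith(")")
    body = raw[1:-1] if uncertain else raw
    if ("(" in body) or (")" in body) or not body:
        raise HaplotypeParseError(f"malformed variant token {token!r}")
    try:
        if "ins" in body:
            pos_s, inserted = body.split("ins", 1)
            if not inserted or set(inserted) - NUCLEOTIDES:
                raise ValueError
            return VariantCall(int(pos_s), inserted, "insertion", uncertain)
        if body.endswith("del"):
            return VariantCall(int(body[:-3]), "", "deletion", uncertain)
        pos_s, state = body[:-1], body[-1].upper()
        return VariantCall(int(pos_s), state, "substitution", uncertain)
    except (ValueError, HaplotypeParseError) as exc:
        if isinstance(exc, HaplotypeParseError):
            raise HaplotypeParseError(f"{exc} (token {token!r})") from None
        raise HaplotypeParseError(f"malformed variant token {token!r}") from None


def parse_haplotype_string(text: str) -> HVRIHaplotype:
    """Parse a hyphen-separated haplotype string (or ``rCRS``)."""
    text = text.strip()
    if not text:
        raise HaplotypeParseError("empty haplotype string")
    if text == "rCRS":
        return HVRIHaplotype()
    variants = [parse_variant_token(tok) for tok in text.split("-")]
    keys = [v.key for v in variants]
    for k in set(keys):
        if keys.count(k) > 1:
            raise HaplotypeParseError(
                f"duplicate variant at position {k[0]} ({k[1]}) in {text!r}"
            )
    return HVRIHaplotype(frozenset(variants))


def format_haplotype(h: HVRIHaplotype) -> str:
    """Canonical text form: ascending position, ``rCRS`` for the empty set."""
    if not h.variants:
        return "rCRS"
    order = {"substitution": 0, "insertion": 1, "deletion": 2}
    toks = sorted(h.variants, key=lambda v: (v.position, order[v.kind]))
    return "-".join(v.token() for v in toks)


def parse_coding_string(text: str) -> frozenset[CodingCall]:
    """Parse the comma-separated coding-SNP column, e.g. ``10398G,10400T``."""
    text = text.strip()
    if not text or text == "-":
        return frozenset()
    calls = []
    for tok in text.split(","):
        tok = tok.strip()
        if len(tok) < 2:
            raise HaplotypeParseError(f"malformed coding token {tok!r}")
        try:
            calls.append(CodingCall(int(tok[:-1]), tok[-1].upper()))
        except ValueError:
            raise HaplotypeParseError(f"malformed coding token {tok!r}") from None
    return frozenset(calls)


def format_coding(calls: Iterable[CodingCall]) -> str:
    return ",".join(c.token() for c in sorted(calls))


@dataclass(frozen=True)
class SampleRecord:
    """One individual: haplotype, coding calls, stage and haplogroup label."""

    sample_id: str
    stage_code: str
    hvr1: HVRIHaplotype
    coding: frozenset[CodingCall] = frozenset()
    haplogroup_label: str = ""

    def __post_init__(self) -> None:
        if self.stage_code not in STAGE_OF_CODE:
            raise ValueError(
                f"unknown stage code {self.stage_code!r} for sample "
                f"{self.sample_id}; expected one of {sorted(STAGE_OF_CODE)}"
            )

    @property
    def stage(self) -> str:
        return STAGE_OF_CODE[self.stage_code]

    def with_label(self, label: str) -> "SampleRecord":
        return replace(self, haplogroup_label=label)


@dataclass
class SeriesTable:
    """An ordered series of samples, e.g. one population or one stage."""

    records: list[SampleRecord] = field(default_factory=list)
    name: str = "series"

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def subset(self, stage: str, name: str | None = None) -> "SeriesTable":
        """Records belonging to one chronological stage."""
        return SeriesTable(
            [r for r in self.records if r.stage == stage],
            name=name or f"{self.name}:{stage}",
        )

    def stages(self) -> dict[str, "SeriesTable"]:
        out: dict[str, SeriesTable] = {}
        for stage in ("Early", "Middle", "Late"):
            sub = self.subset(stage)
            if len(sub):
                out[stage] = sub
        return out

    def haplotypes(self) -> list[HVRIHaplotype]:
        return [r.hvr1 for r in self.records]


def load_bundled_series() -> SeriesTable:
    """The bundled Iron Age Tagar sample table (79 individuals)."""
    from importlib import resources

    with resources.as_file(
        resources.files("tagarmt.data").joinpath("tagar_series.tsv")
    ) as p:
        return read_series_table(p, name="Tagar")


def read_series_table(path: str | Path, name: str | None = None) -> SeriesTable:
    """Read a sample TSV with columns sample_id, stage_code, hvr1, coding, haplogroup."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "stage_code", "hvr1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                stage_code=row["stage_code"],
                hvr1=parse_haplotype_string(row["hvr1"]),
                coding=parse_coding_string(row.get("coding", "")),
                haplogroup_label=row.get("haplogroup", "").strip(),
            )
        )
    if not records:
        warnings.warn(f"{path}: empty sample table", stacklevel=2)
        logger.warning("%s: empty sample table", path)
    return SeriesTable(records, name=name or path.stem)


def write_series_table(table: SeriesTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in table],
            "stage_code": [r.stage_code for r in table],
            "hvr1": [format_haplotype(r.hvr1) for r in table],
            "coding": [format_coding(r.coding) for r in table],
            "haplogroup": [r.haplogroup_label for r in table],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def apply_to_reference(
    h: HVRIHaplotype, ref_seq: str, ref_start: int = HVR1_START
) -> str:
    """Apply a haplotype to a reference HVRI segment and return the sequence.

    ``ref_seq`` must cover every variant position; ``ref_start`` is the rCRS
    coordinate of its first base.  Substitutions replace the base at their
    coordinate, insertions insert after it, deletions remove it.
    """
    ref_end = ref_start + len(ref_seq) - 1
    for v in h.variants:
        if not (ref_start <= v.position <= ref_end):
            raise ValueError(
                f"variant position {v.position} outside reference window "
                f"{ref_start}-{ref_end}"
            )
    out = list(ref_seq.upper())
    # apply right-to-left so earlier indices stay valid under indels
    order = {"deletion": 0, "substitution": 1, "insertion": 2}
    for v in sorted(h.variants, key=lambda v: (-v.position, order[v.kind])):
        i = v.position - ref_start
        if v.kind == "substitution":
            out[i] = v.derived
        elif v.kind == "insertion":
            out[i + 1 : i + 1] = list(v.derived)
        else:
            del out[i]
    return "".join(out)


def export_fasta(
    table: SeriesTable,
    ref_seq: str,
    path: str | Path,
    ref_start: int = HVR1_START,
) -> int:
    """Write one FASTA record per sample; returns the number written."""
    recs = [
        SeqRecord(
            Seq(apply_to_reference(r.hvr1, ref_seq, ref_start)),
            id=r.sample_id,
            description=f"HVRI {format_haplotype(r.hvr1)}",
        )
        for r in table
    ]
    return SeqIO.write(recs, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> str:
    """First sequence of a FASTA file, as an uppercase string."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()
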