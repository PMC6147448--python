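"""End-to-end reproduction of the series' headline descriptive statistics.

``compute_statistics`` runs the whole pipeline on a sample table — haplogroup
calling, spectra, macro-cluster fractions, stage-wise haplogroup
frequencies, haplotype sharing between stages, and binomial detectability —
and returns a flat dict.  ``run_reproduction`` compares that dict against
the declarative expected-value table bundled with the package and reports
pass/fail per statistic.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from . import popgen, sharing
from .detectability import min_detectable_frequency
from .haplogroups import MotifTable, call_series, default_motif_table, macro_cluster
from .io import SeriesTable, load_bundled_series, read_series_table

SCHEMA_VERSION = 1


def load_targets(path: str | Path | None = None) -> list[dict]:
    if path is None:
        src = resources.files("tagarmt.data").joinpath("reproduction_targets.json")
        data = json.loads(src.read_text())
    else:
        data = json.loads(Path(path).read_text())
    return data["targets"]


def compute_statistics(
    table: SeriesTable, motifs: MotifTable | None = None
) -> dict[str, float]:
    """All headline statistics of a stage-structured series, as one flat dict."""
    motifs = motifs or default_motif_table()
    called, concordance = call_series(table, motifs)

    spectrum = popgen.haplotype_spectrum(called)
    _, modal_count = spectrum.modal()
    west, east = popgen.macro_fractions(called, motifs)

    stages = called.stages()
    stats: dict[str, float] = {
        "n_samples": len(called),
        "n_distinct_haplotypes": spectrum.n_distinct,
        "n_singleton_haplotypes": spectrum.n_singletons,
        "modal_haplotype_count": modal_count,
        "pct_west_overall": 100 * west,
        "pct_east_overall": 100 * east,
        "pct_t1": 100 * popgen.haplogroup_frequency(called, {"T1"}, motifs),
        "pct_u4": 100 * popgen.haplogroup_frequency(called, {"U4"}, motifs),
        "pct_a8": 100 * popgen.haplogroup_frequency(called, {"A8"}, motifs),
        "caller_concordant": concordance["n_concordant"],
    }
    for stage, sub in stages.items():
        key = stage.lower()
        stats[f"n_{key}"] = len(sub)
        stats[f"pct_east_{key}"] = 100 * popgen.macro_fractions(sub, motifs)[1]
        stats[f"pct_cd_{key}"] = 100 * popgen.haplogroup_frequency(
            sub, {"C", "D"}, motifs
        )
    if "Late" in stages:
        late = stages["Late"]
        stats["late_west_count"] = sum(
            1 for r in late if macro_cluster(r.haplogroup_label, motifs) == "West"
        )
    if "Early" in stages and "Middle" in stages:
        early, middle = stages["Early"], stages["Middle"]
        m_in_e = sharing.sharing(middle, early)
        e_in_m = sharing.sharing(early, middle)
        early_spec = popgen.haplotype_spectrum(early)
        stats["pct_middle_individuals_in_early"] = (
            m_in_e.fraction_individuals_a_in_b
        )
        stats["early_distinct_haplotypes"] = early_spec.n_distinct
        stats["early_haplotypes_missing_from_middle"] = (
            e_in_m.missing_haplotypes_a_not_in_b
        )
        stats["pct_early_individuals_missing_from_middle"] = (
            100.0 - e_in_m.fraction_individuals_a_in_b
        )
    for n in (16, 24, 46, 79):
        stats[f"min_detectable_freq_n{n}"] = min_detectable_frequency(n)
    return stats


def run_reproduction(
    fixture_path: str | Path | None = None,
    motif_path: str | Path | None = None,
    targets_path: str | Path | None = None,
) -> dict:
    """Recompute every expected statistic and compare within tolerance."""
    from .haplogroups import load_motif_table

    table = (
        load_bundled_series()
        if fixture_path is None
        else read_series_table(fixture_path)
    )
    motifs = load_motif_table(motif_path)
    stats = compute_statistics(table, motifs)

    checks = []
    n_failed = 0
    for t in load_targets(targets_path):
        key = t["key"]
        computed = stats.get(key)
        if computed is None:
            ok = False
        else:
            ok = abs(computed - t["expected"]) <= t["tol"]
        if not ok:
            n_failed += 1
        checks.append(
            {
                "key": key,
                "description": t["description"],
                "expected": t["expected"],
                "computed": computed,
                "tolerance": t["tol"],
                "pass": ok,
            }
        )
    return {
        "schema_version": SCHEMA_VERSION,
        "series": table.name,
        "n_records": len(table),
        "statistics": stats,
        "checks": checks,
        "n_checks": len(checks),
        "n_failed": n_failed,
        "passed": n_failed == 0,
    }
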