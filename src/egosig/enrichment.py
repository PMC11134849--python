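"""Enrichment and overlap statistics for interpreting module outputs.

Over-representation is tested per gene set with a one-sided Fisher exact
test on the 2x2 table (foreground vs background, in set vs not), with
Bonferroni correction over the sets tested. Module similarity to reference
pathways uses the Szymkiewicz-Simpson overlap coefficient
|X n Y| / min(|X|, |Y|) and its complement distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from scipy.stats import fisher_exact

from .supernodes import ModulePartition


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    foreground_size: int
    set_size: int
    background_size: int
    p_value: float
    p_adjusted: float
    fold_enrichment: Optional[float]


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name, description, members per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            members = {f for f in fields[2:] if f}
            if members:
                sets[fields[0]] = members
    return sets


def fisher_test(
    overlap: int, fg_size: int, set_size: int, bg_size: int
) -> float:
    """One-sided (over-representation) Fisher exact p for one 2x2 table."""
    table = [
        [overlap, fg_size - overlap],
        [set_size - overlap, bg_size - fg_size - set_size + overlap],
    ]
    return float(fisher_exact(table, alternative="greater")[1])


def fold_enrichment(
    overlap: int, fg_size: int, set_size: int, bg_size: int
) -> Optional[float]:
    """Observed / expected overlap; None when the expectation is zero."""
    if bg_size <= 0 or fg_size <= 0:
        raise ValueError("background and foreground must be non-empty")
    expected = fg_size * set_size / bg_size
    if expected == 0:
        return None
    return overlap / expected


def fisher_enrichment(
    foreground: set[str],
    sets: dict[str, set[str]],
    background: set[str],
) -> list[EnrichmentResult]:
    """Per-set over-representation of the foreground within the background.

    Sets are intersected with the background before testing; p-values are
    Bonferroni-corrected over the number of sets tested and results sorted
    by adjusted p (ties by name).
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    n_tests = len(sets)
    results = []
    for name, members in sets.items():
        in_bg = members & background
        if not in_bg:
            continue
        overlap = len(foreground & in_bg)
        p = fisher_test(overlap, len(foreground), len(in_bg), len(background))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=overlap,
                foreground_size=len(foreground),
                set_size=len(in_bg),
                background_size=len(background),
                p_value=p,
                p_adjusted=min(1.0, p * n_tests),
                fold_enrichment=fold_enrichment(
                    overlap, len(foreground), len(in_bg), len(background)
                ),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.set_name))
    return results


def percentile_rank(results: list[EnrichmentResult], set_name: str) -> float:
    """Percentile position of a named set in the adjusted-p ranking
    (100 = best-ranked)."""
    names = [r.set_name for r in results]
    if set_name not in names:
        raise KeyError(set_name)
    rank = names.index(set_name)  # 0 = most significant
    return 100.0 * (len(names) - rank) / len(names)


def overlap_coefficient(x: set[str], y: set[str]) -> float:
    """Szymkiewicz-Simpson coefficient |X n Y| / min(|X|, |Y|)."""
    if not x or not y:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(x & y) / min(len(x), len(y))


def overlap_distance(x: set[str], y: set[str]) -> float:
    return 1.0 - overlap_coefficient(x, y)


def best_module_match(
    modules: ModulePartition, reference: set[str], min_size: int = 10
) -> Optional[tuple[dict, float]]:
    """Module (of >= min_size proteins) with maximal overlap coefficient
    against the reference set; ties go to the larger module, then to the
    lexicographically smaller id."""
    candidates = [m for m in modules.modules if len(m["proteins"]) >= min_size]
    if not candidates:
        warnings.warn(f"no module with >= {min_size} proteins")
        return None
    scored = [
        (overlap_coefficient(set(m["proteins"]), reference), len(m["proteins"]), m)
        for m in candidates
    ]
    scored.sort(key=lambda t: (-t[0], -t[1], str(t[2]["id"])))
    coeff, _, best = scored[0]
    return best, coeff
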