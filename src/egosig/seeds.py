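"""Phosphoproteomics seed handling: parsing, aggregation, layers, filters.

A phosphosite table (protein, position, residue, log2 fold change,
optional functional score) is collapsed to one value pair per protein and
direction by taking the maximum |LFC| and maximum functional score over
that protein's direction-consistent sites. Proteins are then partitioned
into up to three layers — tyrosine kinases, other kinases, non-kinase
substrates — filtered by per-layer percentile thresholds (or a top-N
alternative), and turned into restart probability vectors for the random
walk.

Increased and decreased phosphosites are handled separately end to end; a
protein with sites of both signs legitimately appears in both directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]

# a seed whose |LFC| equals the layer minimum still deserves restart mass;
# min-max scaling therefore maps onto [FLOOR, 1] rather than [0, 1]
SCALE_FLOOR = 0.01


class SchemaError(ValueError):
    """Input table is missing a mandatory column."""


@dataclass(frozen=True)
class PhosphoRecord:
    protein: str
    position: int
    lfc: float
    residue: Optional[str] = None
    fscore: Optional[float] = None


@dataclass
class SeedLayers:
    """Per-direction restart-weight maps for the three propagation layers."""

    direction: Direction
    tyr_kinases: dict[str, float] = field(default_factory=dict)
    other_kinases: dict[str, float] = field(default_factory=dict)
    substrates: dict[str, float] = field(default_factory=dict)

    def layers(self) -> dict[str, dict[str, float]]:
        return {
            "tyr_kinases": self.tyr_kinases,
            "other_kinases": self.other_kinases,
            "substrates": self.substrates,
        }

    def all_proteins(self) -> set[str]:
        return set(self.tyr_kinases) | set(self.other_kinases) | set(self.substrates)


_COLUMN_ALIASES = {
    "protein": {"protein", "accession", "uniprot", "acc"},
    "position": {"position", "pos", "site"},
    "residue": {"residue", "res", "aa"},
    "lfc": {"lfc", "log2fc", "logfc", "log2_fold_change", "fold_change"},
    "fscore": {"fscore", "functional_score", "func_score", "score"},
}


def _resolve_columns(columns) -> dict[str, str]:
    mapping: dict[str, str] = {}
    lowered = {c.lower().strip(): c for c in columns}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[canonical] = lowered[alias]
                break
    for required in ("protein", "position", "lfc"):
        if required not in mapping:
            raise SchemaError(f"phospho table lacks a {required!r} column")
    return mapping


def parse_phospho_table(path: str | Path) -> list[PhosphoRecord]:
    """Parse a TSV of phosphosites; rows with non-numeric LFC are skipped
    with a logged row number."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns)
    records: list[PhosphoRecord] = []
    for idx, row in df.iterrows():
        try:
            lfc = float(row[cols["lfc"]])
            pos = int(float(row[cols["position"]]))
        except (TypeError, ValueError):
            logger.warning("row %d: unparseable position/LFC, skipped", idx + 2)
            continue
        if not np.isfinite(lfc):
            logger.warning("row %d: non-finite LFC, skipped", idx + 2)
            continue
        fscore = None
        if "fscore" in cols and pd.notna(row[cols["fscore"]]) and str(
            row[cols["fscore"]]
        ).strip():
            fscore = float(row[cols["fscore"]])
        residue = None
        if "residue" in cols and pd.notna(row[cols["residue"]]):
            residue = str(row[cols["residue"]]).strip() or None
        records.append(
            PhosphoRecord(
                protein=str(row[cols["protein"]]).strip(),
                position=pos,
                lfc=lfc,
                residue=residue,
                fscore=fscore,
            )
        )
    return records


def aggregate_protein_scores(
    records: list[PhosphoRecord], direction: Direction
) -> dict[str, tuple[float, Optional[float]]]:
    """One (max |LFC|, max functional score) pair per protein and direction.

    ``up`` selects sites with positive LFC, ``down`` negative sites by
    magnitude. A protein with sites of both signs appears in both outputs.
    """
    out: dict[str, tuple[float, Optional[float]]] = {}
    for rec in records:
        if direction == "up" and rec.lfc <= 0:
            continue
        if direction == "down" and rec.lfc >= 0:
            continue
        mag = abs(rec.lfc)
        prev = out.get(rec.protein)
        if prev is None:
            out[rec.protein] = (mag, rec.fscore)
        else:
            prev_lfc, prev_fs = prev
            best_fs = prev_fs
            if rec.fscore is not None and (best_fs is None or rec.fscore > best_fs):
                best_fs = rec.fscore
            out[rec.protein] = (max(prev_lfc, mag), best_fs)
    return out


def partition_layers(
    proteins: set[str], tyr_kinases: set[str], kinases: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Split into (tyrosine kinases, other kinases, substrates).

    A protein listed as both kinase and tyrosine kinase lands in the
    tyrosine layer only.
    """
    tyr = proteins & tyr_kinases
    other = proteins & (kinases - tyr_kinases)
    subs = proteins - tyr - other
    if not tyr_kinases and not kinases:
        warnings.warn("empty kinase lists: every seed treated as substrate")
    return tyr, other, subs


def _percentile_threshold(values: list[float], pct: float) -> float:
    return float(np.percentile(np.asarray(values, dtype=float), pct))


def _filter_layer(
    layer: dict[str, tuple[float, Optional[float]]],
    pct: float,
    require_fscore: bool,
) -> dict[str, float]:
    """Strict '>' percentile filter on |LFC| and functional score.

    Percentiles (linear interpolation) are computed within the layer over
    the proteins carrying both values. Degenerate layers (<2 proteins, or
    identical values so the strict filter empties the layer) pass through
    unfiltered with a warning.
    """
    scored = {p: (l, f) for p, (l, f) in layer.items() if f is not None}
    if require_fscore:
        if len(scored) < len(layer):
            logger.info(
                "%d proteins without functional score excluded from a kinase layer",
                len(layer) - len(scored),
            )
    elif not scored and layer:
        # substrate table without functional scores: fall back to LFC alone
        warnings.warn("no functional scores in layer; filtering on |LFC| only")
        scored = dict(layer)
    if len(scored) < 2:
        if layer and len(scored) < 2:
            warnings.warn("layer with <2 scoreable proteins passed through unfiltered")
        return {p: l for p, (l, _) in scored.items()}
    lfc_thr = _percentile_threshold([l for l, _ in scored.values()], pct)
    fs_vals = [f for _, f in scored.values() if f is not None]
    fs_thr = _percentile_threshold(fs_vals, pct) if fs_vals else None
    kept = {
        p: l
        for p, (l, f) in scored.items()
        if l > lfc_thr and (fs_thr is None or f is None or f > fs_thr)
    }
    if not kept:
        warnings.warn(
            "percentile filter removed every protein (identical values?); "
            "layer kept unfiltered"
        )
        kept = {p: l for p, (l, _) in scored.items()}
    return kept


def percentile_filter(
    direction: Direction,
    tyr: dict[str, tuple[float, Optional[float]]],
    other: dict[str, tuple[float, Optional[float]]],
    substrates: dict[str, tuple[float, Optional[float]]],
    kinase_percentile: float = 20.0,
    substrate_percentile: float = 80.0,
    top_n: Optional[int] = None,
) -> SeedLayers:
    """Percentile-based seed selection (or top-N alternative).

    Kinase layers keep proteins that carry a functional score and exceed
    the ``kinase_percentile`` (default 20th) of both |LFC| and score within
    their layer; substrates must exceed the ``substrate_percentile``
    (default 80th) of both. ``top_n`` instead keeps the N largest-|LFC|
    proteins of the whole direction, preserving the layer split.
    """
    if top_n is not None:
        pooled = sorted(
            [(p, l) for layer in (tyr, other, substrates) for p, (l, _) in layer.items()],
            key=lambda t: (-t[1], t[0]),
        )[:top_n]
        keep = {p for p, _ in pooled}
        return SeedLayers(
            direction=direction,
            tyr_kinases={p: l for p, (l, _) in tyr.items() if p in keep},
            other_kinases={p: l for p, (l, _) in other.items() if p in keep},
            substrates={p: l for p, (l, _) in substrates.items() if p in keep},
        )
    return SeedLayers(
        direction=direction,
        tyr_kinases=_filter_layer(tyr, kinase_percentile, require_fscore=True),
        other_kinases=_filter_layer(other, kinase_percentile, require_fscore=True),
        substrates=_filter_layer(substrates, substrate_percentile, require_fscore=False),
    )


def build_restart_vector(
    layer: dict[str, float], net: WeightedNetwork
) -> Optional[np.ndarray]:
    """Restart probability vector over the network's node order.

    Seed |LFC| values are min-max scaled within the layer onto
    ``[SCALE_FLOOR, 1]`` (so the weakest seed keeps nonzero restart mass)
    and normalized to sum 1; non-seed entries are 0. Seeds absent from the
    network are dropped with a warning; ``None`` if none remain.
    """
    nodes = net.nodes
    index = {n: i for i, n in enumerate(nodes)}
    present = {p: w for p, w in layer.items() if p in index}
    for p in set(layer) - set(present):
        warnings.warn(f"seed {p} absent from network, dropped")
    if not present:
        if layer:
            warnings.warn("all seeds of a layer absent from network; layer skipped")
        return None
    vals = np.array(list(present.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        scaled = SCALE_FLOOR + (1 - SCALE_FLOOR) * (vals - lo) / (hi - lo)
    else:
        scaled = np.ones_like(vals)
    scaled /= scaled.sum()
    vec = np.zeros(len(nodes))
    for (p, _), s in zip(present.items(), scaled):
        vec[index[p]] = s
    return vec


def collapse_layers(layers: SeedLayers, n_layers: int) -> SeedLayers:
    """Reduce the three-way partition to 1 or 2 layers.

    Two layers merge the kinase classes; one layer pools everything into
    the substrate slot.
    """
    if n_layers not in (1, 2, 3):
        raise ValueError("layer count must be 1, 2 or 3")
    if n_layers == 3:
        return layers
    if n_layers == 2:
        merged = {**layers.tyr_kinases, **layers.other_kinases}
        return SeedLayers(
            direction=layers.direction, other_kinases=merged,
            substrates=dict(layers.substrates),
        )
    pooled = {**layers.tyr_kinases, **layers.other_kinases, **layers.substrates}
    return SeedLayers(direction=layers.direction, substrates=pooled)
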