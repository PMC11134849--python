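"""Ontology handling: term DAG, information content, and simGIC similarity.

All three Gene Ontology namespaces (or the namespaces of any user-supplied
OBO file) are joined under a single *virtual root* so that every pair of
annotated proteins shares at least one term. Information content is measured
in bits from the annotation corpus itself:

    ic(t) = -log2( n(t) / N )

where ``n(t)`` is the number of proteins annotated (after ancestor closure)
to ``t`` and ``N`` the total number of annotated proteins. The virtual root
is annotated to everything, hence ``ic(root) = 0``.

simGIC between two proteins is the ratio of summed IC over the intersection
of their ancestor-closed term sets to that over the union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import obonet

VIRTUAL_ROOT = "VROOT"


class AnnotationError(ValueError):
    """A protein or term is missing from the ontology/annotation corpus."""


@dataclass
class OntologyAnnotation:
    """Term DAG with per-term IC and ancestor-closed protein annotations.

    Attributes
    ----------
    terms:
        All term identifiers, including :data:`VIRTUAL_ROOT`.
    parents:
        Child term -> set of parent terms (``is_a`` edges only). Roots of
        the individual namespaces point to the virtual root.
    ic:
        Term -> information content in bits (>= 0; 0 for the virtual root).
    annotations:
        Protein accession -> ancestor-closed set of terms (always contains
        the virtual root).
    """

    terms: set[str]
    parents: dict[str, set[str]]
    ic: dict[str, float]
    annotations: dict[str, set[str]]
    _simgic_cache: dict[frozenset, float] = field(
        default_factory=dict, repr=False, compare=False
    )

    def ancestors(self, term: str) -> set[str]:
        """Ancestor-closed set of ``term`` (itself included)."""
        if term not in self.terms:
            raise AnnotationError(f"term {term!r} not in ontology")
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        return out

    def annotated(self, protein: str) -> bool:
        return protein in self.annotations

    def simgic(self, a: str, b: str) -> float:
        """simGIC similarity of two annotated proteins, in [0, 1].

        Symmetric; pairs whose term union carries zero total IC (e.g. both
        annotated only to the virtual root) score 0. Results are memoized,
        which matters when re-weighting thousands of rewired edges.
        """
        for p in (a, b):
            if p not in self.annotations:
                raise AnnotationError(f"protein {p!r} has no annotations")
        key = frozenset((a, b))
        hit = self._simgic_cache.get(key)
        if hit is not None:
            return hit
        ta, tb = self.annotations[a], self.annotations[b]
        inter = sum(self.ic[t] for t in ta & tb)
        union = sum(self.ic[t] for t in ta | tb)
        val = inter / union if union > 0 else 0.0
        self._simgic_cache[key] = val
        return val


def _close_annotations(
    raw: dict[str, set[str]], parents: dict[str, set[str]], terms: set[str]
) -> dict[str, set[str]]:
    # memoized per-term closure keeps GAF loading linear-ish
    closure: dict[str, set[str]] = {}

    def close(term: str) -> set[str]:
        cached = closure.get(term)
        if cached is not None:
            return cached
        out = {term}
        for p in parents.get(term, ()):
            out |= close(p)
        closure[term] = out
        return out

    closed: dict[str, set[str]] = {}
    for prot, ts in raw.items():
        acc: set[str] = {VIRTUAL_ROOT}
        for t in ts:
            if t not in terms:
                raise AnnotationError(
                    f"protein {prot!r} annotated to unknown term {t!r}"
                )
            acc |= close(t)
        closed[prot] = acc
    return closed


def compute_information_content(
    annotation_raw: dict[str, set[str]],
    parents: dict[str, set[str]],
) -> OntologyAnnotation:
    """Build an :class:`OntologyAnnotation` from raw annotations and a DAG.

    Parameters
    ----------
    annotation_raw:
        Protein -> directly annotated terms (not yet ancestor-closed).
    parents:
        Term -> parent terms. Terms without parents are attached to the
        virtual root automatically.

    The corpus IC is computed on the ancestor-closed sets, so IC is
    monotone non-increasing from child to parent by construction.
    """
    terms = set(parents)
    for ps in parents.values():
        terms |= ps
    terms.add(VIRTUAL_ROOT)

    full_parents = {t: set(ps) for t, ps in parents.items()}
    for t in terms:
        if t == VIRTUAL_ROOT:
            continue
        if not full_parents.get(t):
            full_parents[t] = {VIRTUAL_ROOT}

    closed = _close_annotations(annotation_raw, full_parents, terms)
    n_total = len(closed)
    counts: dict[str, int] = {}
    for ts in closed.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    ic = {
        t: (-math.log2(counts[t] / n_total) if t in counts else 0.0)
        for t in terms
    }
    ic[VIRTUAL_ROOT] = 0.0
    return OntologyAnnotation(
        terms=terms, parents=full_parents, ic=ic, annotations=closed
    )


def load_obo(path: str | Path) -> dict[str, set[str]]:
    """Parse an OBO file into a term -> parents mapping (``is_a`` edges)."""
    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return parents


def load_annotations(path: str | Path) -> dict[str, set[str]]:
    """Load protein->term annotations from GAF 2.x or a 2-column TSV.

    GAF rows are recognised by their column count (>= 15, tab-separated,
    ``!`` comment lines skipped); columns 2 (object id) and 5 (term id)
    are used. Anything else is treated as ``protein<TAB>term`` pairs.
    """
    raw: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF
                prot, term = fields[1], fields[4]
            elif len(fields) >= 2:
                prot, term = fields[0], fields[1]
            else:
                continue
            raw.setdefault(prot, set()).add(term)
    if not raw:
        raise AnnotationError(f"no annotations parsed from {path}")
    return raw


def load_ontology_annotation(
    obo_path: str | Path, annotation_path: str | Path
) -> OntologyAnnotation:
    """Convenience loader: OBO + GAF/TSV -> :class:`OntologyAnnotation`."""
    parents = load_obo(obo_path)
    raw = load_annotations(annotation_path)
    return compute_information_content(raw, parents)
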