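"""Consensus cazyme-annotation filter and its recall/precision evaluation.

A CAZy hit on an ORF is retained only when at least one of the ORF's
PFAM/KEGG/COG annotations is carbohydrate-related; otherwise all of the
ORF's CAZy families are discarded.  Evaluation against a reference
annotation reports recall and accuracy (precision) per CAZy class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from bloomloci.datamodel_io import (
    FunctionSets,
    OrfRecord,
    base_family,
    cazy_class_of,
)

__all__ = [
    "FilterDecision",
    "AnnotationEvaluation",
    "filter_cazymes",
    "evaluate_annotation",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for percentages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class FilterDecision:
    orf_id: str
    kept: bool
    evidence_db: str  # pfam | kegg | cog | none
    families: tuple[str, ...]


@dataclass
class AnnotationEvaluation:
    """Counts and derived metrics for one CAZy class (or the overall pool)."""

    cazy_class: str
    n_ref: int
    n_pred: int
    tp: int

    @property
    def recall(self) -> float | None:
        """Percent of reference pairs recovered; None when n_ref == 0."""
        if self.n_ref == 0:
            return None
        return 100.0 * self.tp / self.n_ref

    @property
    def accuracy(self) -> float | None:
        """Precision as a percent (TP / predicted); None when n_pred == 0."""
        if self.n_pred == 0:
            return None
        return 100.0 * self.tp / self.n_pred

    @property
    def recall_pct(self) -> int | None:
        return None if self.recall is None else round_half_away(self.recall)

    @property
    def accuracy_pct(self) -> int | None:
        return None if self.accuracy is None else round_half_away(self.accuracy)


def filter_cazymes(
    orfs: Sequence[OrfRecord],
    sets: FunctionSets,
    keep_unannotated: bool = False,
    use_tigrfam: bool = False,
) -> tuple[list[OrfRecord], list[FilterDecision]]:
    """Apply the consensus rule; returns refined copies and a decision log.

    An ORF keeps all its CAZy families iff any PFAM/KEGG/COG annotation
    intersects the configured carbohydrate-related sets.  With
    ``keep_unannotated``, ORFs lacking any PFAM/KEGG/COG annotation are
    kept rather than dropped.  ``use_tigrfam`` additionally accepts
    TIGRFAM evidence against the PFAM carbohydrate set.
    """
    carb = sets.carb_related
    if not any(carb[db] for db in ("pfam", "kegg", "cog")):
        warnings.warn(
            "all carb_related sets are empty: every cazyme will be dropped",
            stacklevel=2,
        )
    filtered: list[OrfRecord] = []
    log: list[FilterDecision] = []
    for orf in orfs:
        if not orf.cazy_families:
            filtered.append(orf.copy())
            continue
        evidence = "none"
        if orf.pfam_ids & carb["pfam"]:
            evidence = "pfam"
        elif orf.kegg_ids & carb["kegg"]:
            evidence = "kegg"
        elif orf.cog_ids & carb["cog"]:
            evidence = "cog"
        elif use_tigrfam and orf.tigrfam_ids & carb["pfam"]:
            evidence = "tigrfam"
        kept = evidence != "none"
        if not kept and keep_unannotated and not (
            orf.pfam_ids or orf.kegg_ids or orf.cog_ids
        ):
            kept = True
            evidence = "unannotated"
        out = orf.copy()
        if not kept:
            out.cazy_families = set()
        filtered.append(out)
        log.append(
            FilterDecision(
                orf_id=orf.orf_id,
                kept=kept,
                evidence_db=evidence,
                families=tuple(sorted(orf.cazy_families)),
            )
        )
    return filtered, log


def _family_pairs(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    # subfamily suffixes are stripped: matching is at family level
    return {(orf_id, base_family(fam)) for orf_id, fam in pairs}


def evaluate_annotation(
    predicted: Iterable[tuple[str, str]],
    reference: Iterable[tuple[str, str]],
    by_class: bool = False,
) -> list[AnnotationEvaluation]:
    """Compare predicted vs reference (orf_id, family) pairs.

    tp = |predicted ∩ reference| after stripping subfamily suffixes.
    With ``by_class`` one row per CAZy class GH/GT/PL/CE; otherwise a
    single pooled row labelled ``all``.
    """
    pred = _family_pairs(predicted)
    ref = _family_pairs(reference)

    def build(label: str, p: set, r: set) -> AnnotationEvaluation:
        return AnnotationEvaluation(
            cazy_class=label, n_ref=len(r), n_pred=len(p), tp=len(p & r)
        )

    if not by_class:
        return [build("all", pred, ref)]
    rows = []
    for cls in ("GH", "GT", "PL", "CE"):
        p = {x for x in pred if cazy_class_of(x[1]) == cls}
        r = {x for x in ref if cazy_class_of(x[1]) == cls}
        rows.append(build(cls, p, r))
    return rows
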