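"""Rule-based polysaccharide-utilization-locus (PUL) detection.

A susC-susD tandem is an adjacent same-strand domain-flagged gene pair
with an intergenic gap below the clustering threshold.  The locus is
grown outward gene by gene: a neighbour joins while it keeps the tandem
strand and either lies within the gap threshold or is a (post-filter)
cazyme, which may exceed the gap.  A candidate is called a PUL when the
locus holds at least ``min_cazymes`` cazymes and no opposite-strand
cazyme overlaps the locus span.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from bloomloci.datamodel_io import (
    RANKS,
    FunctionSets,
    OrfRecord,
)

__all__ = [
    "DEFAULT_MAX_GAP",
    "DEFAULT_MIN_CAZYMES",
    "Tandem",
    "PulCandidate",
    "FunnelSummary",
    "tag_sus_genes",
    "find_tandems",
    "extend_locus",
    "call_puls",
    "summarize_funnel",
    "detect_puls",
    "contig_taxonomy",
    "ascii_diagram",
    "intergenic_gap",
]

logger = logging.getLogger(__name__)

#: genes closer than this many bp are clustered (gap strictly below)
DEFAULT_MAX_GAP = 102
DEFAULT_MIN_CAZYMES = 3

FUNNEL_STAGES = (
    "tandem_only", "small_contig", "big_contig", "enough_cazymes", "called_pul",
)


def intergenic_gap(left: OrfRecord, right: OrfRecord) -> int:
    """Bases strictly between two genes; overlaps are treated as 0."""
    return max(right.start - left.end - 1, 0)


@dataclass(frozen=True)
class Tandem:
    contig_id: str
    susc_orf: str
    susd_orf: str
    strand: str


@dataclass
class PulCandidate:
    contig_id: str
    tandem: Tandem
    strand: str
    locus_genes: list[tuple[str, str]]  # (orf_id, role) ordered by coordinate
    gene_index: dict[str, OrfRecord] = field(repr=False, default_factory=dict)
    funnel_stage: str = "tandem_only"
    rejection_reason: str | None = None
    taxonomy: dict[str, str] = field(default_factory=dict)

    @property
    def cazyme_count(self) -> int:
        return sum(1 for _, role in self.locus_genes if role == "cazyme")

    @property
    def span(self) -> tuple[int, int]:
        genes = [self.gene_index[i] for i, _ in self.locus_genes]
        return min(g.start for g in genes), max(g.end for g in genes)

    @property
    def cazy_families(self) -> list[str]:
        fams: set[str] = set()
        for orf_id, _ in self.locus_genes:
            fams |= self.gene_index[orf_id].cazy_families
        return sorted(fams)


def tag_sus_genes(
    orfs: Iterable[OrfRecord],
    sets: FunctionSets,
    prefer: str = "susC",
) -> dict[str, str]:
    """Map orf_id -> 'susC' / 'susD' from domain evidence.

    susC needs a PFAM or TIGRFAM hit in the susC domain set; susD a
    PFAM hit in the susD set.  Genes matching both are logged and
    assigned ``prefer``.
    """
    roles: dict[str, str] = {}
    for orf in orfs:
        is_c = bool((orf.pfam_ids | orf.tigrfam_ids) & sets.susc_domains)
        is_d = bool(orf.pfam_ids & sets.susd_domains)
        if is_c and is_d:
            logger.error(
                "%s matches both susC and susD domain sets; assigning %s",
                orf.orf_id, prefer,
            )
            roles[orf.orf_id] = prefer
        elif is_c:
            roles[orf.orf_id] = "susC"
        elif is_d:
            roles[orf.orf_id] = "susD"
    return roles


def _by_contig(orfs: Iterable[OrfRecord]) -> dict[str, list[OrfRecord]]:
    contigs: dict[str, list[OrfRecord]] = defaultdict(list)
    for orf in orfs:
        contigs[orf.contig_id].append(orf)
    for genes in contigs.values():
        genes.sort(key=lambda o: (o.start, o.end, o.orf_id))
    return contigs


def find_tandems(
    orfs: Iterable[OrfRecord],
    sets: FunctionSets,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Tandem]:
    """Adjacent same-strand susC/susD pairs with gap below the threshold.

    Either linear order (susC-susD or susD-susC) qualifies; a sus gene
    shared by two partners yields one tandem per pair.
    """
    roles = tag_sus_genes(orfs, sets)
    tandems: list[Tandem] = []
    for contig_id, genes in sorted(_by_contig(orfs).items()):
        for left, right in zip(genes, genes[1:]):
            pair = {roles.get(left.orf_id), roles.get(right.orf_id)}
            if pair != {"susC", "susD"}:
                continue
            if left.strand != right.strand:
                continue
            if intergenic_gap(left, right) >= max_gap:
                continue
            susc, susd = (
                (left, right) if roles[left.orf_id] == "susC" else (right, left)
            )
            tandems.append(
                Tandem(
                    contig_id=contig_id,
                    susc_orf=susc.orf_id,
                    susd_orf=susd.orf_id,
                    strand=left.strand,
                )
            )
    return tandems


def _role_of(orf: OrfRecord, sets: FunctionSets, sus_roles: dict[str, str]) -> str:
    if orf.orf_id in sus_roles:
        return sus_roles[orf.orf_id]
    if orf.cazy_families:
        return "cazyme"
    ids = orf.annotation_ids()
    if ids & sets.sulfatase_ids:
        return "sulfatase"
    if ids & sets.peptidase_ids:
        return "peptidase"
    if ids & sets.regulator_ids:
        return "regulator"
    return "other"


def extend_locus(
    contig_genes: Sequence[OrfRecord],
    tandem: Tandem,
    sets: FunctionSets,
    max_gap: int = DEFAULT_MAX_GAP,
    sus_roles: dict[str, str] | None = None,
) -> PulCandidate:
    """Grow the locus outward from the tandem under the gap/strand rule."""
    genes = sorted(contig_genes, key=lambda o: (o.start, o.end, o.orf_id))
    if sus_roles is None:
        sus_roles = tag_sus_genes(genes, sets)
    index = {o.orf_id: i for i, o in enumerate(genes)}
    i_c, i_d = index[tandem.susc_orf], index[tandem.susd_orf]
    lo, hi = min(i_c, i_d), max(i_c, i_d)

    def joins(member: OrfRecord, candidate: OrfRecord, downstream: bool) -> bool:
        if candidate.strand != tandem.strand:
            return False
        gap = (
            intergenic_gap(member, candidate)
            if downstream
            else intergenic_gap(candidate, member)
        )
        return gap < max_gap or bool(candidate.cazy_families)

    while hi + 1 < len(genes) and joins(genes[hi], genes[hi + 1], True):
        hi += 1
    while lo - 1 >= 0 and joins(genes[lo], genes[lo - 1], False):
        lo -= 1

    locus = genes[lo:hi + 1]
    return PulCandidate(
        contig_id=tandem.contig_id,
        tandem=tandem,
        strand=tandem.strand,
        locus_genes=[(o.orf_id, _role_of(o, sets, sus_roles)) for o in locus],
        gene_index={o.orf_id: o for o in genes},
    )


def contig_taxonomy(contig_genes: Sequence[OrfRecord]) -> dict[str, str]:
    """Majority vote per rank over gene lineages; ties -> unclassified."""
    taxonomy: dict[str, str] = {}
    for rank in RANKS:
        votes = Counter(
            o.taxonomy[rank] for o in contig_genes if o.taxonomy.get(rank, "")
        )
        if not votes:
            continue
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            continue
        taxonomy[rank] = ranked[0][0]
    return taxonomy


def call_puls(
    candidates: Sequence[PulCandidate],
    orfs: Iterable[OrfRecord],
    min_cazymes: int = DEFAULT_MIN_CAZYMES,
) -> list[PulCandidate]:
    """Finalize funnel stages and call status, in place.

    Stages: small_contig (contig lacks room for ``min_cazymes`` extra
    genes beside the pair), big_contig, enough_cazymes (contig carries
    >= ``min_cazymes`` cazymes), called_pul (locus carries them AND no
    opposite-strand cazyme overlaps the locus span).
    """
    contigs = _by_contig(orfs)
    for cand in candidates:
        genes = contigs[cand.contig_id]
        cand.taxonomy = contig_taxonomy(genes)
        pair = {cand.tandem.susc_orf, cand.tandem.susd_orf}
        n_other = sum(1 for g in genes if g.orf_id not in pair)
        if n_other < min_cazymes:
            cand.funnel_stage = "small_contig"
            cand.rejection_reason = "small_contig"
            continue
        n_contig_cazymes = sum(1 for g in genes if g.cazy_families)
        if n_contig_cazymes < min_cazymes:
            cand.funnel_stage = "big_contig"
            cand.rejection_reason = "fewer_than_3_cazymes_in_contig"
            continue
        cand.funnel_stage = "enough_cazymes"
        if cand.cazyme_count < min_cazymes:
            cand.rejection_reason = "fewer_than_3_cazymes_in_locus"
            continue
        lo, hi = cand.span
        veto = any(
            g.cazy_families
            and g.strand != cand.strand
            and g.start <= hi
            and g.end >= lo
            for g in genes
        )
        if veto:
            cand.rejection_reason = "opposite_strand_cazyme"
            continue
        cand.funnel_stage = "called_pul"
        cand.rejection_reason = None
    return list(candidates)


@dataclass
class FunnelSummary:
    """Stage counts plus per-phylum tandem counts."""

    n_tandems: int
    n_small_contig: int
    n_big_contig: int
    n_enough_cazymes: int
    n_called: int
    per_phylum: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "tandems": self.n_tandems,
            "small_contig": self.n_small_contig,
            "big_contig": self.n_big_contig,
            "enough_cazymes": self.n_enough_cazymes,
            "called_pul": self.n_called,
            "per_phylum": dict(self.per_phylum),
        }


def summarize_funnel(candidates: Sequence[PulCandidate]) -> FunnelSummary:
    """Cumulative stage counts; each stage includes later ones (monotone)."""
    stage_rank = {s: i for i, s in enumerate(FUNNEL_STAGES)}
    ranks = [stage_rank[c.funnel_stage] for c in candidates]
    at_least = lambda s: sum(1 for r in ranks if r >= stage_rank[s])
    per_phylum: Counter = Counter(
        c.taxonomy.get("phylum") or "unclassified" for c in candidates
    )
    return FunnelSummary(
        n_tandems=len(candidates),
        n_small_contig=sum(1 for c in candidates if c.funnel_stage == "small_contig"),
        n_big_contig=at_least("big_contig"),
        n_enough_cazymes=at_least("enough_cazymes"),
        n_called=at_least("called_pul"),
        per_phylum=dict(per_phylum),
    )


def detect_puls(
    orfs: Sequence[OrfRecord],
    sets: FunctionSets,
    max_gap: int = DEFAULT_MAX_GAP,
    min_cazymes: int = DEFAULT_MIN_CAZYMES,
) -> tuple[list[PulCandidate], FunnelSummary]:
    """Full pipeline: tag, pair, extend, call, summarize."""
    contigs = _by_contig(orfs)
    sus_roles = tag_sus_genes(orfs, sets)
    tandems = find_tandems(orfs, sets, max_gap=max_gap)
    candidates = [
        extend_locus(contigs[t.contig_id], t, sets, max_gap=max_gap,
                     sus_roles=sus_roles)
        for t in tandems
    ]
    call_puls(candidates, orfs, min_cazymes=min_cazymes)
    return candidates, summarize_funnel(candidates)


_ROLE_GLYPH = {
    "susC": "C", "susD": "D", "cazyme": "Z",
    "sulfatase": "S", "peptidase": "P", "regulator": "R", "other": ".",
}


def ascii_diagram(pul: PulCandidate) -> str:
    """One-line role-labeled arrow diagram of the locus."""
    parts = []
    for orf_id, role in pul.locus_genes:
        gene = pul.gene_index[orf_id]
        glyph = _ROLE_GLYPH.get(role, "?")
        parts.append(f"{glyph}>" if gene.strand == "+" else f"<{glyph}")
    return " ".join(parts)
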