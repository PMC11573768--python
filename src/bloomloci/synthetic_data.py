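"""Synthetic community generator with planted ground truth.

Produces ORF/coverage/sample tables with the statistical structure the
analysis stages assume — single-copy marker genes, per-taxon function
copy numbers, bloom-correlated families, spurious cazyme annotations and
PUL gene layouts — together with a manifest recording every planted
expectation, so each stage can be tested against known truth.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from bloomloci.datamodel_io import (
    CAZY_FAMILY_RE,
    RANKS,
    FunctionSets,
    OrfRecord,
    Sample,
    SampleSeries,
    ValidationError,
    load_function_sets,
)

__all__ = [
    "GenomeModel",
    "BloomScenario",
    "PulGene",
    "PulLayout",
    "GroundTruthManifest",
    "SimulationResult",
    "default_chlorophyll",
    "simulate_community",
    "plant_correlated_family",
    "plant_pul_contigs",
    "plant_annotation_noise",
    "make_annotation_benchmark",
    "decoy_library",
]

_GENE_GAP = 100          # bp between simulated genes on a contig
_PUL_GENE_LENGTH = 1000  # bp, fixed length of planted PUL genes
_NONSENSE_PFAM = "PF99999"  # guaranteed outside every configured set

_SPURIOUS_FAMILY_POOL = (
    "GH13", "GH2", "GH3", "GT2", "GT4", "CE1", "PL7", "GH5", "GH16", "CBM6",
)


@dataclass
class GenomeModel:
    """A planted clade: lineage plus per-genome gene copy counts.

    Every configured USiCG is emitted with exactly one copy; entries in
    ``time_varying`` override ``function_copies`` with per-sample
    effective copy numbers (used for bloom-correlated families).
    """

    taxon: dict[str, str]
    function_copies: dict[str, int] = field(default_factory=dict)
    n_genomes: int = 1
    mean_gene_length: int = 900
    time_varying: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rank in self.taxon:
            if rank not in RANKS:
                raise ValidationError(f"unknown rank {rank!r}")
        for fn, copies in self.function_copies.items():
            if copies < 0:
                raise ValidationError(f"{fn}: copies must be >= 0")
        if self.mean_gene_length < 1:
            raise ValidationError("mean_gene_length must be positive")

    @property
    def key(self) -> str:
        """Most specific non-empty rank name; used to key abundances."""
        for rank in reversed(RANKS):
            if self.taxon.get(rank):
                return self.taxon[rank]
        raise ValidationError("genome taxon has no named rank")


def default_chlorophyll(n_samples: int, peak: float = 8.0) -> list[float]:
    """Low winter plateau for the first 3 samples, then a logistic rise."""
    chl = []
    for i in range(n_samples):
        if i < 3:
            chl.append(0.1)
        else:
            t = (i - 3) / max(n_samples - 4, 1)
            chl.append(0.1 + (peak - 0.1) / (1.0 + math.exp(-8.0 * (t - 0.5))))
    return chl


@dataclass
class BloomScenario:
    """Sampling design: chlorophyll trajectory and taxon abundances."""

    n_samples: int
    chlorophyll: list[float]
    abundances: dict[str, list[float]]
    noise_sd: float = 0.0
    seed: int = 0
    depth: float = 50.0
    read_length: int = 100
    noise_model: str = "gaussian"
    start_date: _dt.date = _dt.date(2021, 3, 1)
    interval_days: int = 10

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValidationError("need at least 3 samples")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if len(self.chlorophyll) != self.n_samples:
            raise ValidationError("chlorophyll length != n_samples")
        if any(c < 0 for c in self.chlorophyll):
            raise ValidationError("chlorophyll must be non-negative")
        for key, traj in self.abundances.items():
            if len(traj) != self.n_samples:
                raise ValidationError(f"{key}: abundance length != n_samples")
            if any(a < 0 for a in traj):
                raise ValidationError(f"{key}: abundances must be >= 0")
        for s in range(self.n_samples):
            total = sum(traj[s] for traj in self.abundances.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"sample index {s}: abundances sum to {total!r}, not 1"
                )

    def sample_series(self) -> SampleSeries:
        return SampleSeries(
            Sample(
                sample_id=f"S{i + 1:02d}",
                date=self.start_date + _dt.timedelta(days=i * self.interval_days),
                chlorophyll=self.chlorophyll[i],
            )
            for i in range(self.n_samples)
        )

    @classmethod
    def uniform(
        cls,
        taxon_keys: Sequence[str],
        n_samples: int = 12,
        seed: int = 0,
        noise_sd: float = 0.0,
        **kwargs,
    ) -> "BloomScenario":
        """Equal, constant abundances and the default chlorophyll curve."""
        share = 1.0 / len(taxon_keys)
        return cls(
            n_samples=n_samples,
            chlorophyll=default_chlorophyll(n_samples),
            abundances={k: [share] * n_samples for k in taxon_keys},
            noise_sd=noise_sd,
            seed=seed,
            **kwargs,
        )


@dataclass
class GroundTruthManifest:
    """Everything planted: regenerating with the same seed reproduces it."""

    seed: int
    params: dict
    copy_numbers: dict[str, dict[str, list[float]]]
    expected_coverage: dict[str, list[float]]
    true_cazyme_orfs: list[str] = field(default_factory=list)
    spurious_cazyme_orfs: list[str] = field(default_factory=list)
    correlated_families: dict[str, str] = field(default_factory=dict)
    pul_truth: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulationResult:
    orfs: list[OrfRecord]
    samples: SampleSeries
    manifest: GroundTruthManifest


def _annotation_kwargs(ident: str) -> dict[str, set[str]]:
    """Route an identifier to the annotation field its prefix implies."""
    if CAZY_FAMILY_RE.match(ident):
        return {"cazy_families": {ident}}
    if ident.startswith("PF"):
        return {"pfam_ids": {ident}}
    if ident.startswith("TIGR"):
        return {"tigrfam_ids": {ident}}
    if ident.startswith("COG"):
        return {"cog_ids": {ident}}
    if ident.startswith("K") and ident[1:].isdigit():
        return {"kegg_ids": {ident}}
    raise ValidationError(f"cannot route identifier {ident!r} to a database")


def _merge_annotation(kwargs: dict[str, set[str]], ident: str) -> None:
    for fld, vals in _annotation_kwargs(ident).items():
        kwargs.setdefault(fld, set()).update(vals)


def _noise_factor(rng: np.random.Generator, sd: float, model: str) -> float:
    if sd == 0:
        return 1.0
    if model == "lognormal":
        # mean-one multiplicative lognormal
        return float(rng.lognormal(-0.5 * sd * sd, sd))
    eps = max(float(rng.normal(0.0, sd)), -0.99)
    return 1.0 + eps


def simulate_community(
    genomes: Sequence[GenomeModel],
    scenario: BloomScenario,
    sets: FunctionSets | None = None,
    carb_coannotate: bool = True,
) -> SimulationResult:
    """Emit ORFs with coverages following the planted community model.

    Per-gene coverage in sample *s* is ``abundance(s) * depth * copies *
    (1 + eps)`` with multiplicative noise truncated at -0.99; read
    counts are ``round(coverage * gene_length / read_length)``.  The
    manifest records the noiseless expectations.  Deterministic given
    ``scenario.seed``.
    """
    if not genomes:
        raise ValidationError("need at least one genome")
    if sets is None:
        sets = load_function_sets()
    keys = [g.key for g in genomes]
    if len(set(keys)) != len(keys):
        raise ValidationError("genome taxon keys must be unique")
    missing = set(keys) - set(scenario.abundances)
    if missing:
        raise ValidationError(f"no abundance trajectory for {sorted(missing)}")

    rng = np.random.default_rng(scenario.seed)
    samples = scenario.sample_series()
    sample_ids = samples.sample_ids
    carb_pfam = min(sets.carb_related["pfam"]) if sets.carb_related["pfam"] else None

    orfs: list[OrfRecord] = []
    copy_numbers: dict[str, dict[str, list[float]]] = {}
    expected_cov: dict[str, list[float]] = {}
    true_cazymes: list[str] = []

    for genome in genomes:
        key = genome.key
        abund = scenario.abundances[key]
        contig = f"sim|{key}|c1"
        cursor = 1
        counter = 0
        copy_numbers[key] = {}

        # (annotation ids, per-sample copies) for every gene to emit
        plan: list[tuple[list[str], list[float]]] = []
        for usicg in sorted(sets.usicg_ids):
            plan.append(([usicg], [1.0] * scenario.n_samples))
        for fn in sorted(set(genome.function_copies) | set(genome.time_varying)):
            if fn in genome.time_varying:
                eff = [float(v) for v in genome.time_varying[fn]]
                if len(eff) != scenario.n_samples:
                    raise ValidationError(f"{fn}: time_varying length mismatch")
                idents = [fn]
                if carb_coannotate and carb_pfam and CAZY_FAMILY_RE.match(fn):
                    idents.append(carb_pfam)
                plan.append((idents, eff))
                copy_numbers[key][fn] = eff
            else:
                copies = genome.function_copies[fn]
                copy_numbers[key][fn] = [float(copies)] * scenario.n_samples
                idents = [fn]
                if carb_coannotate and carb_pfam and CAZY_FAMILY_RE.match(fn):
                    idents.append(carb_pfam)
                for _ in range(copies):
                    plan.append((idents, [1.0] * scenario.n_samples))

        for idents, copies_per_sample in plan:
            counter += 1
            orf_id = f"{contig}|g{counter:04d}"
            length = genome.mean_gene_length
            ann: dict[str, set[str]] = {}
            for ident in idents:
                _merge_annotation(ann, ident)
            coverage: dict[str, float] = {}
            reads: dict[str, int] = {}
            expectation: list[float] = []
            for s, sid in enumerate(sample_ids):
                base = abund[s] * scenario.depth * copies_per_sample[s]
                cov = base * _noise_factor(rng, scenario.noise_sd, scenario.noise_model)
                coverage[sid] = cov
                reads[sid] = int(round(cov * length / scenario.read_length))
                expectation.append(base)
            orf = OrfRecord(
                orf_id=orf_id,
                contig_id=contig,
                start=cursor,
                end=cursor + length - 1,
                strand="+",
                taxonomy=dict(genome.taxon),
                coverage=coverage,
                reads=reads,
                **ann,
            )
            if orf.cazy_families:
                true_cazymes.append(orf_id)
            expected_cov[orf_id] = expectation
            orfs.append(orf)
            cursor += length + _GENE_GAP

    manifest = GroundTruthManifest(
        seed=scenario.seed,
        params={
            "n_samples": scenario.n_samples,
            "depth": scenario.depth,
            "noise_sd": scenario.noise_sd,
            "noise_model": scenario.noise_model,
            "read_length": scenario.read_length,
            "chlorophyll": list(scenario.chlorophyll),
            "abundances": {k: list(v) for k, v in scenario.abundances.items()},
        },
        copy_numbers=copy_numbers,
        expected_coverage=expected_cov,
        true_cazyme_orfs=true_cazymes,
    )
    for g in genomes:
        for fam in g.time_varying:
            manifest.correlated_families.setdefault(fam, "planted")
    return SimulationResult(orfs=orfs, samples=samples, manifest=manifest)


def plant_correlated_family(
    genomes: Sequence[GenomeModel],
    scenario: BloomScenario,
    family: str,
    direction: str,
    effect: float = 1.0,
    taxon_key: str | None = None,
    base_copies: float = 2.0,
) -> list[GenomeModel]:
    """Make a family's effective copies a monotone transform of chlorophyll.

    With ``direction='positive'`` effective copies rise with chlorophyll
    (rank-preserving), so the noiseless Spearman correlation is exactly
    +1; ``'negative'`` gives -1.  Mutates and returns the genome list.
    """
    if direction not in ("positive", "negative"):
        raise ValidationError(f"unknown direction {direction!r}")
    chl = np.asarray(scenario.chlorophyll, dtype=float)
    top = chl.max() if chl.max() > 0 else 1.0
    rel = chl / top
    if direction == "negative":
        rel = 1.0 - rel
    eff = [float(base_copies * (1.0 + effect * r)) for r in rel]
    planted = False
    for genome in genomes:
        if taxon_key is not None and genome.key != taxon_key:
            continue
        if family in genome.time_varying:
            raise ValidationError(f"{family} already planted in {genome.key}")
        genome.time_varying[family] = eff
        planted = True
    if not planted:
        raise ValidationError(f"no genome matches taxon_key {taxon_key!r}")
    return list(genomes)


# ---------------------------------------------------------------------------
# PUL layouts

@dataclass(frozen=True)
class PulGene:
    role: str  # susC | susD | cazyme | sulfatase | peptidase | regulator | other
    strand: str
    gap_to_previous: int = 50
    label: str | None = None  # cazy family or domain id override


@dataclass
class PulLayout:
    """Blueprint for one planted contig around a susC-susD tandem."""

    contig_id: str
    tandem_strand: str
    genes: list[PulGene]
    should_call: bool
    reason: str = ""
    expected_stage: str = ""

    def __post_init__(self) -> None:
        pairs = 0
        for a, b in zip(self.genes, self.genes[1:]):
            if {a.role, b.role} == {"susC", "susD"}:
                pairs += 1
        if pairs != 1:
            raise ValidationError(
                f"{self.contig_id}: exactly one adjacent susC-susD pair "
                f"required, found {pairs}"
            )
        for g in self.genes[1:]:
            if g.gap_to_previous < -50:
                raise ValidationError(
                    f"{self.contig_id}: gap {g.gap_to_previous} < -50"
                )


_ROLE_DEFAULT_LABEL = {
    "susC": "PF00593",
    "susD": "PF07980",
    "cazyme": "GH16",
}


def plant_pul_contigs(
    layouts: Sequence[PulLayout],
    sets: FunctionSets | None = None,
    taxonomy: dict[str, str] | None = None,
) -> tuple[list[OrfRecord], dict[str, dict]]:
    """Materialise layouts as ORFs with exact coordinates and a truth table.

    Gene length is fixed at 1000 bp; ``gap_to_previous`` is the count of
    bases strictly between consecutive genes (negative = overlap, down
    to -50).  Planted cazymes carry a carbohydrate-related PFAM id so
    they survive the consensus filter.
    """
    if sets is None:
        sets = load_function_sets()
    if taxonomy is None:
        taxonomy = {"superkingdom": "Bacteria", "phylum": "Bacteroidetes"}
    carb_pfam = min(sets.carb_related["pfam"]) if sets.carb_related["pfam"] else None
    role_ids = {
        "sulfatase": min(sets.sulfatase_ids) if sets.sulfatase_ids else _NONSENSE_PFAM,
        "peptidase": min(sets.peptidase_ids) if sets.peptidase_ids else _NONSENSE_PFAM,
        "regulator": min(sets.regulator_ids) if sets.regulator_ids else _NONSENSE_PFAM,
        "other": _NONSENSE_PFAM,
    }

    orfs: list[OrfRecord] = []
    truth: dict[str, dict] = {}
    for layout in layouts:
        cursor = 101
        for i, gene in enumerate(layout.genes):
            if i > 0:
                cursor = cursor + gene.gap_to_previous
            start = cursor
            end = start + _PUL_GENE_LENGTH - 1
            cursor = end + 1
            ann: dict[str, set[str]] = {}
            if gene.role in ("susC", "susD"):
                _merge_annotation(ann, gene.label or _ROLE_DEFAULT_LABEL[gene.role])
            elif gene.role == "cazyme":
                _merge_annotation(ann, gene.label or _ROLE_DEFAULT_LABEL["cazyme"])
                if carb_pfam:
                    _merge_annotation(ann, carb_pfam)
            else:
                _merge_annotation(ann, gene.label or role_ids[gene.role])
            orfs.append(
                OrfRecord(
                    orf_id=f"{layout.contig_id}|g{i + 1:02d}",
                    contig_id=layout.contig_id,
                    start=start,
                    end=end,
                    strand=gene.strand,
                    taxonomy=dict(taxonomy),
                    **ann,
                )
            )
        truth[layout.contig_id] = {
            "should_call": layout.should_call,
            "reason": layout.reason,
            "expected_stage": layout.expected_stage,
        }
    return orfs, truth


def decoy_library() -> list[PulLayout]:
    """Packaged true/decoy layouts exercising every branch of the caller."""

    def caz(strand="+", gap=50, fam="GH16"):
        return PulGene("cazyme", strand, gap, fam)

    fwd = "+"
    return [
        PulLayout(
            "pul|true_basic", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50),
             caz(fam="GH30"), caz(fam="GH92"), caz(fam="GH17")],
            should_call=True, expected_stage="called_pul",
        ),
        PulLayout(
            "pul|decoy_too_few_cazymes", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50),
             caz(fam="GH30"), caz(fam="GH92"), PulGene("other", fwd, 50)],
            should_call=False, reason="fewer_than_3_cazymes_in_contig",
            expected_stage="big_contig",
        ),
        PulLayout(
            "pul|decoy_opposite_strand", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50),
             caz("-", 50, "GH30"), caz("-", 50, "GH92"), caz("-", 50, "GH17")],
            should_call=False, reason="fewer_than_3_cazymes_in_locus",
            expected_stage="enough_cazymes",
        ),
        PulLayout(
            "pul|decoy_severed", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50),
             PulGene("other", fwd, 150),
             caz(fam="GH30"), caz(fam="GH92"), caz(fam="GH17")],
            should_call=False, reason="fewer_than_3_cazymes_in_locus",
            expected_stage="enough_cazymes",
        ),
        PulLayout(
            "pul|gap_exempt_cazyme", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50),
             caz(gap=500, fam="GH30"), caz(fam="GH92"), caz(fam="GH17")],
            should_call=True, expected_stage="called_pul",
        ),
        PulLayout(
            "pul|decoy_small_contig", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50)],
            should_call=False, reason="small_contig",
            expected_stage="small_contig",
        ),
        PulLayout(
            "pul|decoy_strand_veto", fwd,
            [PulGene("susC", fwd), PulGene("susD", fwd, 50),
             caz(fam="GH30"), caz(fam="GH92"), caz(fam="GH17"),
             caz("-", -50, "GH13")],
            should_call=False, reason="opposite_strand_cazyme",
            expected_stage="enough_cazymes",
        ),
    ]


# ---------------------------------------------------------------------------
# annotation noise

def plant_annotation_noise(
    orfs: list[OrfRecord],
    n_false_cazymes: int,
    p_true: float,
    p_false: float,
    sets: FunctionSets | None = None,
    seed: int = 0,
) -> tuple[list[OrfRecord], dict[str, list[str]]]:
    """Plant spurious cazyme labels and carbohydrate co-annotation evidence.

    ORFs already carrying CAZy families are the true cazymes; each keeps
    (gains) a carbohydrate-related co-annotation with probability
    ``p_true``.  ``n_false_cazymes`` non-cazyme ORFs get a spurious CAZy
    family and a carbohydrate co-annotation with probability ``p_false``.
    Mutates the records; returns them with a truth-label mapping.
    """
    if n_false_cazymes < 0:
        raise ValidationError("n_false_cazymes must be >= 0")
    if not (0 <= p_true <= 1 and 0 <= p_false <= 1):
        raise ValidationError("probabilities must lie in [0, 1]")
    if sets is None:
        sets = load_function_sets()
    if not sets.carb_related["pfam"]:
        raise ValidationError("carb_related.pfam must be non-empty to plant evidence")
    carb_pfam = min(sets.carb_related["pfam"])
    all_carb = {
        "pfam_ids": sets.carb_related["pfam"],
        "kegg_ids": sets.carb_related["kegg"],
        "cog_ids": sets.carb_related["cog"],
    }

    rng = np.random.default_rng(seed)
    true_ids = [o.orf_id for o in orfs if o.cazy_families]
    candidates = [o for o in orfs if not o.cazy_families]
    if n_false_cazymes > len(candidates):
        raise ValidationError(
            f"only {len(candidates)} non-cazyme ORFs available for "
            f"{n_false_cazymes} spurious labels"
        )

    def set_carb_evidence(orf: OrfRecord, present: bool) -> None:
        for fld, ids in all_carb.items():
            setattr(orf, fld, getattr(orf, fld) - ids)
        if present:
            orf.pfam_ids.add(carb_pfam)

    for orf in orfs:
        if orf.cazy_families:
            set_carb_evidence(orf, bool(rng.random() < p_true))

    chosen = rng.choice(len(candidates), size=n_false_cazymes, replace=False)
    spurious_ids: list[str] = []
    for idx in sorted(int(i) for i in chosen):
        orf = candidates[idx]
        fam = _SPURIOUS_FAMILY_POOL[int(rng.integers(len(_SPURIOUS_FAMILY_POOL)))]
        orf.cazy_families.add(fam)
        set_carb_evidence(orf, bool(rng.random() < p_false))
        spurious_ids.append(orf.orf_id)

    return orfs, {"true": true_ids, "spurious": spurious_ids}


def make_annotation_benchmark(
    n_true: int,
    n_false: int,
    p_true: float,
    p_false: float,
    sets: FunctionSets | None = None,
    seed: int = 0,
) -> tuple[list[OrfRecord], dict[str, list[str]]]:
    """Standalone ORF set for exercising the consensus filter at scale."""
    rng = np.random.default_rng(seed)
    orfs: list[OrfRecord] = []
    for i in range(n_true + n_false):
        ann: dict[str, set[str]] = {}
        if i < n_true:
            fam = _SPURIOUS_FAMILY_POOL[int(rng.integers(len(_SPURIOUS_FAMILY_POOL)))]
            ann["cazy_families"] = {fam}
        start = 1 + i * (_PUL_GENE_LENGTH + _GENE_GAP)
        orfs.append(
            OrfRecord(
                orf_id=f"bench|g{i + 1:05d}",
                contig_id=f"bench|c{i + 1:05d}",
                start=start,
                end=start + _PUL_GENE_LENGTH - 1,
                strand="+",
                **ann,
            )
        )
    return plant_annotation_noise(
        orfs, n_false, p_true, p_false, sets=sets, seed=seed + 1
    )


# ---------------------------------------------------------------------------
# one-call demo dataset

def demo_dataset(
    seed: int = 0,
    n_samples: int = 12,
    noise_sd: float = 0.05,
    sets: FunctionSets | None = None,
) -> SimulationResult:
    """A small bloom community with every kind of planted structure.

    Three clades with distinct cazyme repertoires, a Bacteroidetes
    abundance rise tracking the chlorophyll curve, one positively and
    one negatively chlorophyll-correlated GH family, and the full PUL
    decoy library on Bacteroidetes contigs.
    """
    if sets is None:
        sets = load_function_sets()
    genomes = [
        GenomeModel(
            taxon={"superkingdom": "Bacteria", "phylum": "Bacteroidetes",
                   "class": "Flavobacteriia"},
            function_copies={"GH16": 6, "GH92": 4, "GH17": 3, "GT2": 2,
                             "PL7": 2, "CE1": 1, "PF00884": 2},
        ),
        GenomeModel(
            taxon={"superkingdom": "Bacteria", "phylum": "Proteobacteria",
                   "class": "Gammaproteobacteria"},
            function_copies={"GH23": 3, "GH36": 2, "GT2": 3, "GT4": 2, "CE9": 1},
        ),
        GenomeModel(
            taxon={"superkingdom": "Archaea", "phylum": "Thaumarchaeota"},
            function_copies={"GT2": 4, "GT66": 3},
        ),
    ]
    chl = default_chlorophyll(n_samples)
    top = max(chl)
    bact = [0.15 + 0.45 * c / top for c in chl]
    arch = [0.15 - 0.10 * c / top for c in chl]
    prot = [1.0 - b - a for b, a in zip(bact, arch)]
    scenario = BloomScenario(
        n_samples=n_samples,
        chlorophyll=chl,
        abundances={
            "Flavobacteriia": bact,
            "Gammaproteobacteria": prot,
            "Thaumarchaeota": arch,
        },
        noise_sd=noise_sd,
        seed=seed,
    )
    plant_correlated_family(
        genomes, scenario, "GH30_1", "positive", effect=2.0,
        taxon_key="Flavobacteriia",
    )
    plant_correlated_family(
        genomes, scenario, "GH28", "negative", effect=2.0,
        taxon_key="Flavobacteriia",
    )
    result = simulate_community(genomes, scenario, sets=sets)
    result.manifest.correlated_families = {"GH30_1": "positive", "GH28": "negative"}

    pul_orfs, pul_truth = plant_pul_contigs(decoy_library(), sets=sets)
    depth = scenario.depth
    for orf in pul_orfs:
        for i, sid in enumerate(result.samples.sample_ids):
            cov = scenario.abundances["Flavobacteriia"][i] * depth
            orf.coverage[sid] = cov
            orf.reads[sid] = int(round(cov * orf.length / scenario.read_length))
    result.orfs.extend(pul_orfs)
    result.manifest.pul_truth = pul_truth
    return result
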