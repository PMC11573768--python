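"""Shared data model, TSV/YAML/GFF3 input-output and configuration.

All genomic coordinates in the package are 1-based inclusive; strand is
encoded ``+``/``-`` both in memory and on disk.  Set-valued annotation
columns are ``;``-separated in TSV files, with empty cells meaning empty
sets.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "RANKS",
    "CAZY_CLASSES",
    "CAZY_FAMILY_RE",
    "SchemaError",
    "ValidationError",
    "OrfRecord",
    "Sample",
    "SampleSeries",
    "FunctionSets",
    "lineage_matches",
    "parse_taxon_selector",
    "cazy_class_of",
    "base_family",
    "read_samples_table",
    "write_samples_table",
    "read_orf_table",
    "write_orf_table",
    "write_coverage_table",
    "attach_coverage",
    "load_function_sets",
    "write_pul_gff",
]

#: taxonomy ranks stored on every ORF, most to least inclusive
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus")

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

#: CAZy family labels: class prefix + family number + optional subfamily
CAZY_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(_\d+)?$")


class SchemaError(ValueError):
    """A table header does not match the documented schema."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


def cazy_class_of(family: str) -> str:
    """Return the CAZy class prefix of a family label (e.g. ``GH30_1`` -> ``GH``)."""
    m = CAZY_FAMILY_RE.match(family)
    if m is None:
        raise ValidationError(f"not a CAZy family label: {family!r}")
    return m.group(1)


def base_family(family: str) -> str:
    """Strip a subfamily suffix: ``GH30_1`` -> ``GH30``; plain labels unchanged."""
    m = CAZY_FAMILY_RE.match(family)
    if m is None:
        raise ValidationError(f"not a CAZy family label: {family!r}")
    return m.group(1) + m.group(2)


@dataclass
class OrfRecord:
    """One predicted gene with coordinates, taxonomy and annotations.

    ``coverage`` and ``reads`` map sample_id to fold coverage / read
    counts; they may be empty until a coverage table is attached.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    cazy_families: set[str] = field(default_factory=set)
    pfam_ids: set[str] = field(default_factory=set)
    kegg_ids: set[str] = field(default_factory=set)
    cog_ids: set[str] = field(default_factory=set)
    tigrfam_ids: set[str] = field(default_factory=set)
    coverage: dict[str, float] = field(default_factory=dict)
    reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValidationError(
                f"{self.orf_id}: coordinates must be positive (1-based), "
                f"got {self.start}..{self.end}"
            )
        if self.start > self.end:
            raise ValidationError(
                f"{self.orf_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.orf_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        for fam in self.cazy_families:
            if CAZY_FAMILY_RE.match(fam) is None:
                raise ValidationError(
                    f"{self.orf_id}: malformed CAZy family label {fam!r}"
                )
        for rank in self.taxonomy:
            if rank not in RANKS:
                raise ValidationError(
                    f"{self.orf_id}: unknown taxonomy rank {rank!r}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def annotation_ids(self) -> set[str]:
        """Union of all non-CAZy annotation identifiers."""
        return self.pfam_ids | self.kegg_ids | self.cog_ids | self.tigrfam_ids

    def copy(self) -> "OrfRecord":
        return replace(
            self,
            taxonomy=dict(self.taxonomy),
            cazy_families=set(self.cazy_families),
            pfam_ids=set(self.pfam_ids),
            kegg_ids=set(self.kegg_ids),
            cog_ids=set(self.cog_ids),
            tigrfam_ids=set(self.tigrfam_ids),
            coverage=dict(self.coverage),
            reads=dict(self.reads),
        )


@dataclass(frozen=True)
class Sample:
    sample_id: str
    date: _dt.date
    chlorophyll: float

    def __post_init__(self) -> None:
        if self.chlorophyll < 0:
            raise ValidationError(
                f"{self.sample_id}: chlorophyll must be non-negative"
            )


class SampleSeries:
    """Ordered samples with dates and chlorophyll a values (ug/L)."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples: list[Sample] = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_ids in series")
        dates = [s.date for s in self.samples]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValidationError("sample dates must be strictly increasing")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def chlorophyll(self) -> list[float]:
        return [s.chlorophyll for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSeries) and self.samples == other.samples


@dataclass
class FunctionSets:
    """Configured identifier sets driving annotation-aware operations."""

    usicg_ids: set[str]
    carb_related: dict[str, set[str]]
    susc_domains: set[str]
    susd_domains: set[str]
    sulfatase_ids: set[str] = field(default_factory=set)
    peptidase_ids: set[str] = field(default_factory=set)
    regulator_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.usicg_ids:
            raise ValidationError("usicg_ids must be non-empty")
        overlap = self.susc_domains & self.susd_domains
        if overlap:
            raise ValidationError(
                f"susC and susD domain sets overlap: {sorted(overlap)}"
            )
        for db in ("pfam", "kegg", "cog"):
            self.carb_related.setdefault(db, set())


# ---------------------------------------------------------------------------
# taxon selectors

def parse_taxon_selector(selector: str) -> tuple[str | None, str]:
    """Split a selector into (rank, name); rank is None for any-rank match.

    ``"phylum=Bacteroidetes"`` selects at a fixed rank; a bare name
    matches at any rank.
    """
    if "=" in selector:
        rank, name = selector.split("=", 1)
        rank = rank.strip().lower()
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r} in selector {selector!r}")
        return rank, name.strip()
    return None, selector.strip()


def lineage_matches(taxonomy: Mapping[str, str], selector: str) -> bool:
    """True if the lineage contains the selector name (at its rank if given)."""
    rank, name = parse_taxon_selector(selector)
    if rank is not None:
        return taxonomy.get(rank, "") == name
    return name in (v for v in taxonomy.values() if v)


# ---------------------------------------------------------------------------
# TSV schemas

_ORF_COLUMNS = [
    "orf_id", "contig_id", "start", "end", "strand",
    "tax_superkingdom", "tax_phylum", "tax_class", "tax_order",
    "tax_family", "tax_genus",
    "cazy", "pfam", "kegg", "cog", "tigrfam",
]

_SET_COLUMNS = {
    "cazy": "cazy_families",
    "pfam": "pfam_ids",
    "kegg": "kegg_ids",
    "cog": "cog_ids",
    "tigrfam": "tigrfam_ids",
}


def _split_set(cell: str) -> set[str]:
    cell = cell.strip()
    if not cell:
        return set()
    return {tok.strip() for tok in cell.split(";") if tok.strip()}


def _join_set(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def read_samples_table(path: str | Path) -> SampleSeries:
    """Read samples.tsv (columns sample_id, date, chlorophyll)."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "date", "chlorophyll"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(
                f"{path}: missing column(s) {sorted(missing)}"
            )
        samples = [
            Sample(
                sample_id=row["sample_id"],
                date=_dt.date.fromisoformat(row["date"]),
                chlorophyll=float(row["chlorophyll"]),
            )
            for row in reader
        ]
    return SampleSeries(samples)


def write_samples_table(samples: SampleSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "date", "chlorophyll"])
        for s in samples:
            w.writerow([s.sample_id, s.date.isoformat(), repr(s.chlorophyll)])


def read_orf_table(
    path: str | Path,
    samples: SampleSeries | None = None,
    coverage_path: str | Path | None = None,
) -> list[OrfRecord]:
    """Read orfs.tsv into validated records.

    When ``coverage_path`` is given the long-form coverage table is
    attached and every record is checked to carry coverage for every
    sample in ``samples``.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ORF_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        orfs: list[OrfRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                start = int(row["start"])
                end = int(row["end"])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            taxonomy = {
                rank: row[f"tax_{rank}"].strip()
                for rank in RANKS
                if row[f"tax_{rank}"].strip()
            }
            kwargs = {
                attr: _split_set(row[col]) for col, attr in _SET_COLUMNS.items()
            }
            try:
                orfs.append(
                    OrfRecord(
                        orf_id=row["orf_id"],
                        contig_id=row["contig_id"],
                        start=start,
                        end=end,
                        strand=row["strand"],
                        taxonomy=taxonomy,
                        **kwargs,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if coverage_path is not None:
        if samples is None:
            raise ValueError("samples required to attach coverage")
        attach_coverage(orfs, coverage_path, samples)
    return orfs


def write_orf_table(orfs: Sequence[OrfRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ORF_COLUMNS)
        for o in orfs:
            row = [o.orf_id, o.contig_id, o.start, o.end, o.strand]
            row += [o.taxonomy.get(rank, "") for rank in RANKS]
            row += [_join_set(getattr(o, attr)) for attr in _SET_COLUMNS.values()]
            w.writerow(row)


def write_coverage_table(orfs: Sequence[OrfRecord], path: str | Path) -> None:
    """Write the long-form coverage table (orf_id, sample_id, coverage, reads)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["orf_id", "sample_id", "coverage", "reads"])
        for o in orfs:
            for sample_id in sorted(o.coverage):
                w.writerow(
                    [o.orf_id, sample_id,
                     repr(o.coverage[sample_id]), o.reads.get(sample_id, 0)]
                )


def attach_coverage(
    orfs: Sequence[OrfRecord], path: str | Path, samples: SampleSeries
) -> None:
    """Attach coverage/reads from a long-form table, in place.

    Missing coverage for any (orf, sample) pair is an error — silent
    zeros would bias copy numbers downstream.
    """
    path = Path(path)
    known = set(samples.sample_ids)
    by_id = {o.orf_id: o for o in orfs}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"orf_id", "sample_id", "coverage", "reads"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["sample_id"]
            if sid not in known:
                raise ValidationError(
                    f"{path}:{lineno}: unknown sample {sid!r}; "
                    f"known sample_ids: {sorted(known)}"
                )
            orf = by_id.get(row["orf_id"])
            if orf is None:
                raise ValidationError(
                    f"{path}:{lineno}: unknown orf_id {row['orf_id']!r}"
                )
            cov = float(row["coverage"])
            if cov < 0:
                raise ValidationError(f"{path}:{lineno}: negative coverage")
            orf.coverage[sid] = cov
            orf.reads[sid] = int(row["reads"])
    for o in orfs:
        absent = known - set(o.coverage)
        if absent:
            raise ValidationError(
                f"{o.orf_id}: no coverage for sample(s) {sorted(absent)}"
            )


# ---------------------------------------------------------------------------
# function-set configuration

def load_function_sets(path: str | Path | None = None) -> FunctionSets:
    """Load a FunctionSets YAML; with no path, the packaged default.

    The packaged default's 11 USiCG identifiers are ribosomal/translation
    COG stand-ins and should be overridden when the real panel is known.
    """
    if path is None:
        ref = resources.files("bloomloci").joinpath("data/function_sets.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("function sets config must be a mapping")
    if not raw.get("usicg_ids"):
        raise ValidationError("function sets config must define usicg_ids")
    carb = raw.get("carb_related") or {}
    return FunctionSets(
        usicg_ids=set(raw["usicg_ids"]),
        carb_related={db: set(carb.get(db) or []) for db in ("pfam", "kegg", "cog")},
        susc_domains=set(raw.get("susc_domains") or []),
        susd_domains=set(raw.get("susd_domains") or []),
        sulfatase_ids=set(raw.get("sulfatase_ids") or []),
        peptidase_ids=set(raw.get("peptidase_ids") or []),
        regulator_ids=set(raw.get("regulator_ids") or []),
    )


# ---------------------------------------------------------------------------
# GFF3 export

def _gff_escape(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09")
    )


def write_pul_gff(puls: Sequence, path: str | Path) -> None:
    """Write PUL candidates as GFF3: one locus feature + one child per gene.

    Coordinates are passed through unchanged (both the data model and
    GFF3 are 1-based inclusive).
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for i, pul in enumerate(puls, start=1):
        pid = f"PUL{i:04d}"
        start, end = pul.span
        attrs = (
            f"ID={pid};contig={_gff_escape(pul.contig_id)};"
            f"n_cazymes={pul.cazyme_count};stage={pul.funnel_stage}"
        )
        lines.append(
            "\t".join(
                [pul.contig_id, "bloomloci",
                 "polysaccharide_utilization_locus",
                 str(start), str(end), ".", pul.strand, ".", attrs]
            )
        )
        for orf_id, role in pul.locus_genes:
            gene = pul.gene_index[orf_id]
            gattrs = (
                f"ID={pid}.{_gff_escape(orf_id)};Parent={pid};"
                f"Name={_gff_escape(orf_id)};role={role}"
            )
            lines.append(
                "\t".join(
                    [pul.contig_id, "bloomloci", "gene",
                     str(gene.start), str(gene.end), ".", gene.strand, ".",
                     gattrs]
                )
            )
    path.write_text("\n".join(lines) + "\n")
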