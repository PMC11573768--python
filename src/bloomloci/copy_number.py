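"""USiCG-normalized function copy numbers and taxon read percentages.

The copy number of a function within a taxon subset and sample is the
summed coverage of subset genes carrying the function divided by the
median coverage of the configured universal single-copy genes (USiCGs)
in the same subset/sample — i.e. the average number of gene copies per
genome equivalent.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from bloomloci.datamodel_io import (
    CAZY_CLASSES,
    CAZY_FAMILY_RE,
    FunctionSets,
    OrfRecord,
    ValidationError,
    base_family,
    lineage_matches,
    parse_taxon_selector,
)

__all__ = [
    "CopyNumberMatrix",
    "orf_carries_function",
    "usicg_median",
    "function_coverage",
    "copy_number",
    "compute_matrix",
    "taxon_read_percentage",
    "families_of_class",
]

_ROLE_FUNCTIONS = ("susC", "susD", "sulfatase", "peptidase")


def _subset(orfs: Iterable[OrfRecord], taxon: str | None) -> list[OrfRecord]:
    if taxon is None:
        return list(orfs)
    return [o for o in orfs if lineage_matches(o.taxonomy, taxon)]


def orf_carries_function(
    orf: OrfRecord, function: str, sets: FunctionSets | None = None
) -> bool:
    """Does this gene carry ``function``?

    ``function`` may be a CAZy class (``GH``: any family of the class),
    a CAZy family (``GH30`` also matches its subfamilies; ``GH30_1`` is
    exact), a role name (susC/susD/sulfatase/peptidase, resolved through
    ``sets``), or any raw annotation identifier.
    """
    if function in CAZY_CLASSES:
        return any(
            CAZY_FAMILY_RE.match(f).group(1) == function for f in orf.cazy_families
        )
    if function in _ROLE_FUNCTIONS:
        if sets is None:
            raise ValidationError(f"FunctionSets required to resolve {function!r}")
        ids = {
            "susC": sets.susc_domains,
            "susD": sets.susd_domains,
            "sulfatase": sets.sulfatase_ids,
            "peptidase": sets.peptidase_ids,
        }[function]
        return bool(orf.annotation_ids() & ids)
    if CAZY_FAMILY_RE.match(function):
        if "_" in function:
            return function in orf.cazy_families
        return any(base_family(f) == function for f in orf.cazy_families)
    return function in orf.annotation_ids()


def usicg_median(
    orfs: Iterable[OrfRecord],
    taxon: str | None,
    sample: str,
    sets: FunctionSets,
    skip_absent: bool = False,
) -> float:
    """Median over USiCG ids of each id's aggregate subset coverage.

    Per id: sum the coverage of subset genes annotated with it (0 when
    absent, unless ``skip_absent``).  An even id count averages the
    central pair.  A zero return signals an undefined denominator.
    """
    subset = _subset(orfs, taxon)
    if not subset:
        raise ValidationError(f"taxon subset {taxon!r} is empty")
    aggregates = []
    for usicg in sorted(sets.usicg_ids):
        total = sum(
            o.coverage[sample] for o in subset if usicg in o.annotation_ids()
        )
        aggregates.append(total)
    if skip_absent:
        aggregates = [a for a in aggregates if a > 0]
        if not aggregates:
            return 0.0
    return float(statistics.median(aggregates))


def function_coverage(
    orfs: Iterable[OrfRecord],
    taxon: str | None,
    function: str,
    sample: str,
    sets: FunctionSets | None = None,
) -> float:
    """Summed subset coverage of genes carrying the function (each once)."""
    return sum(
        o.coverage[sample]
        for o in _subset(orfs, taxon)
        if orf_carries_function(o, function, sets)
    )


def copy_number(
    orfs: Iterable[OrfRecord],
    taxon: str | None,
    function: str,
    sample: str,
    sets: FunctionSets,
    skip_absent_usicgs: bool = False,
) -> float | None:
    """Function coverage over USiCG median; None when the median is 0."""
    orfs = list(orfs)
    denom = usicg_median(orfs, taxon, sample, sets, skip_absent=skip_absent_usicgs)
    if denom == 0:
        return None
    return function_coverage(orfs, taxon, function, sample, sets) / denom


@dataclass
class CopyNumberMatrix:
    """Long-form taxon x function x sample copy-number table.

    ``table`` columns: taxon, function, sample, value, denominator,
    defined.  Undefined cells (zero USiCG median) keep value = NaN with
    defined = False; values otherwise satisfy value * denominator =
    numerator exactly.
    """

    table: pd.DataFrame

    def value(self, taxon: str, function: str, sample: str) -> float | None:
        t = self.table
        row = t[
            (t["taxon"] == taxon)
            & (t["function"] == function)
            & (t["sample"] == sample)
        ]
        if row.empty:
            raise KeyError((taxon, function, sample))
        if not bool(row["defined"].iloc[0]):
            return None
        return float(row["value"].iloc[0])

    def series(self, taxon: str, function: str) -> pd.Series:
        """Per-sample values (NaN where undefined), in table order."""
        t = self.table
        rows = t[(t["taxon"] == taxon) & (t["function"] == function)]
        if rows.empty:
            raise KeyError((taxon, function))
        return rows.set_index("sample")["value"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CopyNumberMatrix":
        df = pd.read_csv(path, sep="\t")
        df["defined"] = df["defined"].astype(bool)
        return cls(df)


def compute_matrix(
    orfs: Sequence[OrfRecord],
    samples,
    taxa: Sequence[str | None],
    functions: Sequence[str],
    sets: FunctionSets,
    skip_absent_usicgs: bool = False,
) -> CopyNumberMatrix:
    """Evaluate copy numbers over the full taxon x function x sample grid."""
    records = []
    for taxon in taxa:
        label = taxon if taxon is not None else "community"
        for sample in samples.sample_ids:
            denom = usicg_median(
                orfs, taxon, sample, sets, skip_absent=skip_absent_usicgs
            )
            for function in functions:
                if denom == 0:
                    records.append((label, function, sample, float("nan"), 0.0, False))
                else:
                    num = function_coverage(orfs, taxon, function, sample, sets)
                    records.append((label, function, sample, num / denom, denom, True))
    return CopyNumberMatrix(
        pd.DataFrame(
            records,
            columns=["taxon", "function", "sample", "value", "denominator", "defined"],
        )
    )


def taxon_read_percentage(
    orfs: Iterable[OrfRecord], taxon: str, sample: str
) -> float:
    """Percent of rank-classified reads assigned to the taxon.

    The selector must be rank-qualified (``phylum=Bacteroidetes``) or
    resolvable to a unique rank; reads of ORFs unclassified at that rank
    are excluded from the denominator.
    """
    orfs = list(orfs)
    rank, name = parse_taxon_selector(taxon)
    if rank is None:
        ranks = {
            r for o in orfs for r, v in o.taxonomy.items() if v == name
        }
        if len(ranks) != 1:
            raise ValidationError(
                f"cannot resolve rank for {name!r} (candidates: {sorted(ranks)}); "
                "use a rank-qualified selector"
            )
        rank = ranks.pop()
    classified = [o for o in orfs if o.taxonomy.get(rank, "")]
    denom = sum(o.reads[sample] for o in classified)
    if denom == 0:
        raise ValidationError(
            f"no reads classified at rank {rank!r} in sample {sample!r}"
        )
    num = sum(o.reads[sample] for o in classified if o.taxonomy[rank] == name)
    return 100.0 * num / denom


def families_of_class(
    orfs: Iterable[OrfRecord], cazy_class: str, taxon: str | None = None
) -> list[str]:
    """Sorted CAZy family/subfamily labels of a class present in the subset."""
    fams = {
        f
        for o in _subset(orfs, taxon)
        for f in o.cazy_families
        if CAZY_FAMILY_RE.match(f).group(1) == cazy_class
    }
    return sorted(fams)
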