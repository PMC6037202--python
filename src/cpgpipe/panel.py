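"""Gene-panel and cohort domain model.

The panel is a curated list of cancer-predisposition genes (CPGs), each
annotated with the flags that drive filtering decisions downstream:

* ``is_proto_oncogene`` — gain-of-function mechanism; protein-truncating
  variants in these genes are not expected to raise tumor risk.
* ``recessive_only`` — tumor predisposition only in the homozygous or
  compound-heterozygous state (e.g. *MUTYH*, *NTHL1*).
* ``characteristic_tumors`` — tumor categories classically associated with
  pathogenic variants in the gene, used for genotype-phenotype concordance.

Cohort phenotypes are per-individual lists of adjudicated primary-tumor
diagnoses (site/cell-of-origin category + age), from which eligibility for
a multiple-primary-tumor (MPT) series is decided: at least two primaries by
age 60 or at least three by age 70.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneRecord",
    "TumorDiagnosis",
    "Individual",
    "Panel",
    "mpt_eligible",
    "characteristic_tumor",
    "load_tumor_vocabulary",
    "load_characteristic_tumors",
    "read_panel",
    "write_panel",
    "read_cohort",
    "write_cohort",
]

MAX_AGE = 120.0


@dataclass(frozen=True)
class GeneRecord:
    """One panel gene with its mechanism flags and exon structure."""

    symbol: str
    is_proto_oncogene: bool = False
    recessive_only: bool = False
    characteristic_tumors: frozenset[str] = field(default_factory=frozenset)
    #: 0-based half-open (contig, start, end) intervals, all on one contig.
    exons: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        contigs = {e[0] for e in self.exons}
        if len(contigs) > 1:
            raise ValueError(f"{self.symbol}: exons span multiple contigs {contigs}")
        for _, start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.symbol}: empty exon interval [{start}, {end})")

    @property
    def contig(self) -> str | None:
        return self.exons[0][0] if self.exons else None

    @property
    def span(self) -> tuple[int, int] | None:
        """Transcribed span: hull of the exon intervals (0-based half-open)."""
        if not self.exons:
            return None
        return min(e[1] for e in self.exons), max(e[2] for e in self.exons)

    @property
    def canonical_cds_length(self) -> int:
        return sum(e - s for _, s, e in self.merged_exons())

    def merged_exons(self) -> list[tuple[str, int, int]]:
        """Exon intervals merged so that overlaps/adjacency collapse."""
        merged: list[tuple[str, int, int]] = []
        for contig, start, end in sorted(self.exons, key=lambda e: (e[1], e[2])):
            if merged and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (contig, prev[1], max(prev[2], end))
            else:
                merged.append((contig, start, end))
        return merged


@dataclass(frozen=True)
class TumorDiagnosis:
    """One adjudicated primary tumor: category label and age at diagnosis."""

    category: str
    age_at_diagnosis: float

    def __post_init__(self) -> None:
        if not 0 <= self.age_at_diagnosis <= MAX_AGE:
            raise ValueError(
                f"age_at_diagnosis must be in [0, {MAX_AGE}], "
                f"got {self.age_at_diagnosis}"
            )


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    sex: str  # "male" | "female"
    tumors: tuple[TumorDiagnosis, ...] = ()
    is_proband: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def tumor_categories(self) -> frozenset[str]:
        return frozenset(t.category for t in self.tumors)


@dataclass(frozen=True)
class Panel:
    """A gene panel plus the positional list of known pathogenic
    non-coding variants searched for outside consequence-based filtering."""

    genes: tuple[GeneRecord, ...]
    #: exact (contig, position [1-based], ref, alt) entries
    noncoding_pathogenic_positions: tuple[tuple[str, int, str, str], ...] = ()

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in panel: {dupes}")

    def __contains__(self, symbol: str) -> bool:
        return any(g.symbol == symbol for g in self.genes)

    def __getitem__(self, symbol: str) -> GeneRecord:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]


def mpt_eligible(tumors: Sequence[TumorDiagnosis]) -> bool:
    """Multiple-primary-tumor eligibility: >=2 primaries by age 60 or
    >=3 by age 70 ("by" inclusive of the boundary year)."""
    for t in tumors:
        if t.age_at_diagnosis < 0:
            raise ValueError(f"negative age at diagnosis: {t.age_at_diagnosis}")
    by60 = sum(1 for t in tumors if t.age_at_diagnosis <= 60)
    by70 = sum(1 for t in tumors if t.age_at_diagnosis <= 70)
    return by60 >= 2 or by70 >= 3


def characteristic_tumor(
    individual: Individual,
    gene: GeneRecord,
    vocabulary: Iterable[str] | None = None,
) -> bool:
    """True iff any of the individual's tumor categories is classically
    associated with pathogenic variants in ``gene``.

    When a controlled ``vocabulary`` is supplied, unknown category labels are
    rejected with the list of valid labels.
    """
    if vocabulary is not None:
        valid = set(vocabulary)
        unknown = individual.tumor_categories - valid
        if unknown:
            raise ValueError(
                f"unknown tumor categories {sorted(unknown)}; "
                f"valid labels: {sorted(valid)}"
            )
    return bool(individual.tumor_categories & gene.characteristic_tumors)


# ---------------------------------------------------------------------------
# Bundled configuration tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("cpgpipe") / "data" / name


def load_tumor_vocabulary(path: str | Path | None = None) -> dict[str, dict]:
    """Controlled tumor-category vocabulary.

    Returns ``{category: {"malignant": bool, "cns": bool}}``. The bundled
    default is a reduced vocabulary suitable for synthetic cohorts; real
    cohorts should supply their own table.
    """
    src = Path(path) if path is not None else _data_path("tumor_categories.tsv")
    out: dict[str, dict] = {}
    with (open(src) if isinstance(src, Path) else src.open()) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["category"]] = {
                "malignant": row["malignant"] == "1",
                "cns": row["cns"] == "1",
            }
    return out


def load_characteristic_tumors(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Gene -> characteristic tumor categories.

    The bundled default is a best-effort reconstruction from well-established
    gene-tumor associations (BRCA1/2-breast/ovary, FH-leiomyoma/RCC,
    MAX/SDHB-pheochromocytoma/paraganglioma, mismatch-repair-colorectal/
    endometrial, ...); it is configuration, editable per deployment.
    """
    src = Path(path) if path is not None else _data_path("characteristic_tumors.tsv")
    out: dict[str, frozenset[str]] = {}
    with (open(src) if isinstance(src, Path) else src.open()) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cats = row["characteristic_tumors"].strip()
            out[row["symbol"]] = frozenset(cats.split(";")) if cats else frozenset()
    return out


# ---------------------------------------------------------------------------
# On-disk representation (panel TSV + exon BED; cohort phenotype TSV)
# ---------------------------------------------------------------------------

def write_panel(panel: Panel, tsv_path: str | Path, bed_path: str | Path) -> None:
    tsv_path, bed_path = Path(tsv_path), Path(bed_path)
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["symbol", "proto_oncogene", "recessive_only", "characteristic_tumors"])
        for g in panel.genes:
            w.writerow([
                g.symbol,
                int(g.is_proto_oncogene),
                int(g.recessive_only),
                ";".join(sorted(g.characteristic_tumors)),
            ])
    with open(bed_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for g in panel.genes:
            for contig, start, end in g.exons:
                w.writerow([contig, start, end, g.symbol])


def read_panel(
    tsv_path: str | Path,
    bed_path: str | Path,
    noncoding_positions: Sequence[tuple[str, int, str, str]] = (),
) -> Panel:
    exons: dict[str, list[tuple[str, int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end, symbol = line.rstrip("\n").split("\t")[:4]
            exons.setdefault(symbol, []).append((contig, int(start), int(end)))
    genes = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            cats = row["characteristic_tumors"].strip()
            genes.append(GeneRecord(
                symbol=row["symbol"],
                is_proto_oncogene=row["proto_oncogene"] == "1",
                recessive_only=row["recessive_only"] == "1",
                characteristic_tumors=frozenset(cats.split(";")) if cats else frozenset(),
                exons=tuple(sorted(exons.get(row["symbol"], []), key=lambda e: e[1])),
            ))
    return Panel(genes=tuple(genes),
                 noncoding_pathogenic_positions=tuple(noncoding_positions))


def write_cohort(individuals: Sequence[Individual], path: str | Path) -> None:
    """One row per tumor; tumor-free individuals get a row with empty
    tumor fields so they round-trip."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["individual_id", "family_id", "sex", "is_proband",
                    "tumor_category", "age_at_diagnosis"])
        for ind in individuals:
            if not ind.tumors:
                w.writerow([ind.individual_id, ind.family_id, ind.sex,
                            int(ind.is_proband), "", ""])
            for t in ind.tumors:
                w.writerow([ind.individual_id, ind.family_id, ind.sex,
                            int(ind.is_proband), t.category,
                            f"{t.age_at_diagnosis:g}"])


def read_cohort(path: str | Path) -> list[Individual]:
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            iid = row["individual_id"]
            if iid not in rows:
                rows[iid] = {
                    "family_id": row["family_id"],
                    "sex": row["sex"],
                    "is_proband": row["is_proband"] == "1",
                    "tumors": [],
                }
                order.append(iid)
            if row["tumor_category"]:
                rows[iid]["tumors"].append(TumorDiagnosis(
                    category=row["tumor_category"],
                    age_at_diagnosis=float(row["age_at_diagnosis"]),
                ))
    return [
        Individual(
            individual_id=iid,
            family_id=rows[iid]["family_id"],
            sex=rows[iid]["sex"],
            tumors=tuple(rows[iid]["tumors"]),
            is_proband=rows[iid]["is_proband"],
        )
        for iid in order
    ]
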