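"""Cohort I/O and region-to-GO annotation.

Clonal mosaicism calls arrive as per-sample genomic segments (chromosome,
start, end). Each sample's functional profile is the union of GO
annotations of every gene whose interval overlaps one of its segments by
at least one base pair — the file-based equivalent of annotating abnormal
regions through a genome-mart lookup.

On-disk coordinates are BED dialect (0-based, half-open) by default; pass
``one_based=True`` for 1-based inclusive tables and they are converted on
load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from intervaltree import IntervalTree

from .ontology import OntologyDAG, SubGO

logger = logging.getLogger(__name__)

LABELS = ("case", "ctrl")


class CohortError(ValueError):
    """Malformed cohort input (bad labels, coordinates, unknown samples)."""


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise CohortError("empty chromosome name")
        if self.start >= self.end:
            raise CohortError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class SampleRecord:
    """One cohort member: phenotype, mosaic regions, derived annotations."""

    sample_id: str
    label: str
    sex: str = "unknown"
    age: float = float("nan")
    regions: list[Region] = field(default_factory=list)
    term_set: frozenset[str] = frozenset()
    genes: frozenset[str] = frozenset()


class GeneTrack:
    """Gene intervals indexed for overlap queries; first symbol wins on
    duplicates (extras are logged and dropped)."""

    def __init__(self, frame: pd.DataFrame):
        dups = frame["symbol"].duplicated()
        if dups.any():
            logger.warning("dropping %d duplicate gene symbols: %s",
                           dups.sum(), sorted(frame.loc[dups, "symbol"].unique()))
            frame = frame[~dups]
        bad = frame["start"] >= frame["end"]
        if bad.any():
            raise CohortError(f"invalid gene intervals for {list(frame.loc[bad, 'symbol'])}")
        self.frame = frame.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            self._trees[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], sub["symbol"])
            )

    @classmethod
    def from_bed(cls, path, one_based: bool = False) -> "GeneTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "symbol"],
                         dtype={"chrom": str, "symbol": str})
        if one_based:
            df["start"] -= 1
        return cls(df)

    def genes_overlapping(self, region: Region) -> set[str]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(region.start, region.end)}

    @property
    def symbols(self) -> set[str]:
        return set(self.frame["symbol"])


def read_gene2go(path, dag: OntologyDAG | None = None) -> dict[str, set[str]]:
    """Gene -> GO-term map from a 2-column TSV or a GAF 2.x file.

    GAF input is detected by its ``!gaf-version`` header or 15+ columns;
    columns 3 (symbol) and 5 (GO id) are used and ``NOT``-qualified rows
    dropped. Terms absent from ``dag`` are dropped with a warning.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        rows = [line.rstrip("\n") for line in fh]
    is_gaf = any(r.startswith("!gaf-version") for r in rows[:5])
    if not is_gaf and rows:
        first = next((r for r in rows if r and not r.startswith(("!", "#"))), "")
        is_gaf = len(first.split("\t")) >= 15
    for row in rows:
        if not row or row.startswith(("!", "#")):
            continue
        cols = row.split("\t")
        if is_gaf:
            if "NOT" in cols[3].split("|"):
                continue
            gene, term = cols[2], cols[4]
        else:
            gene, term = cols[0], cols[1]
        mapping.setdefault(gene, set()).add(term)
    if dag is not None:
        unknown = {t for ts in mapping.values() for t in ts} - dag.terms
        if unknown:
            logger.warning("dropping %d GO ids absent from the ontology", len(unknown))
            mapping = {g: ts - unknown for g, ts in mapping.items()}
            mapping = {g: ts for g, ts in mapping.items() if ts}
    return mapping


def read_cohort(regions_path, phenotype_path, one_based: bool = False) -> list[SampleRecord]:
    """Build one :class:`SampleRecord` per phenotype row.

    The phenotype table is a headered TSV (sample_id, label, sex, age); the
    regions file is BED3+1 (chrom, start, end, sample_id). Samples with no
    regions are retained with an empty region list; region rows naming an
    unknown sample are an error.
    """
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "label", "sex", "age"}
    if not required.issubset(pheno.columns):
        raise CohortError(f"phenotype table needs columns {sorted(required)}")
    bad_labels = set(pheno["label"]) - set(LABELS)
    if bad_labels:
        raise CohortError(f"unknown label values {sorted(bad_labels)}; expected {LABELS}")
    if pheno["sample_id"].duplicated().any():
        raise CohortError("duplicate sample_id in phenotype table")

    regions = pd.read_csv(regions_path, sep="\t", header=None, comment="#",
                          names=["chrom", "start", "end", "sample_id"],
                          dtype={"chrom": str, "sample_id": str})
    by_sample: dict[str, list[Region]] = {sid: [] for sid in pheno["sample_id"]}
    for i, row in enumerate(regions.itertuples(index=False), start=1):
        try:
            start = int(row.start) - (1 if one_based else 0)
            end = int(row.end)
        except (TypeError, ValueError):
            raise CohortError(f"malformed coordinates at regions line {i}") from None
        if start >= end:
            raise CohortError(
                f"regions line {i}: end <= start for {row.chrom}:{row.start}-{row.end}"
            )
        if row.sample_id not in by_sample:
            raise CohortError(
                f"regions line {i}: sample {row.sample_id!r} absent from phenotype table"
            )
        by_sample[row.sample_id].append(Region(str(row.chrom), start, end))

    cohort = []
    for row in pheno.itertuples(index=False):
        regs = by_sample[row.sample_id]
        if not regs:
            logger.info("sample %s has no mosaic regions", row.sample_id)
        cohort.append(SampleRecord(
            sample_id=row.sample_id, label=row.label, sex=str(row.sex),
            age=float(row.age), regions=regs,
        ))
    return cohort


def annotate_sample(
    record: SampleRecord,
    gene_track: GeneTrack,
    gene2go: dict[str, set[str]],
    dag: OntologyDAG,
) -> SampleRecord:
    """Derive the sample's gene list and GO term set from its regions."""
    genes: set[str] = set()
    for region in record.regions:
        genes |= gene_track.genes_overlapping(region)
    terms: set[str] = set()
    unannotated = 0
    for g in sorted(genes):
        anns = gene2go.get(g)
        if not anns:
            unannotated += 1
            continue
        terms |= anns & dag.terms
    if unannotated:
        logger.debug("sample %s: %d overlapped genes carry no GO annotation",
                     record.sample_id, unannotated)
    return replace(record, genes=frozenset(genes), term_set=frozenset(terms))


def annotate_cohort(cohort, gene_track, gene2go, dag) -> list[SampleRecord]:
    return [annotate_sample(r, gene_track, gene2go, dag) for r in cohort]


def restrict_term_set(term_set, subgo: SubGO) -> frozenset[str]:
    """Terms of the sample that fall inside the sub-GO."""
    return frozenset(term_set) & subgo.nodes


def event_frequency_summary(
    cohort: list[SampleRecord],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Mosaic-event rate per 1000 Mb, by chromosome and case/ctrl group."""
    counts: dict[tuple[str, str], int] = {}
    for rec in cohort:
        for region in rec.regions:
            if region.chrom not in chrom_lengths:
                raise CohortError(f"chromosome {region.chrom!r} missing from length table")
            key = (region.chrom, rec.label)
            counts[key] = counts.get(key, 0) + 1
    chroms = sorted(chrom_lengths)
    data = {
        label: [counts.get((c, label), 0) / (chrom_lengths[c] / 1e9) for c in chroms]
        for label in LABELS
    }
    return pd.DataFrame(data, index=pd.Index(chroms, name="chrom"))
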