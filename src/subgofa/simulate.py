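"""Seeded synthetic fixtures: ontology, gene annotation, mosaicism cohorts.

Everything the pipeline reads can be generated here, so the whole test
surface works without any downloaded ontology release or public cohort.
The generators emulate the shape of a real study: a single-namespace
random DAG, genes tiled along chromosomes, leaf-biased GO annotation (so
low-frequency terms exist — the regime the method targets), case samples
whose mosaic regions are enriched for genes under a planted sub-GO root,
and controls drawn from a larger pool by sex- and age-matched sampling.

Every generator is a pure function of (config, seed): outputs are
byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ontology import OntologyDAG, enumerate_subgos
from .regions import GeneTrack, Region, SampleRecord, annotate_cohort

logger = logging.getLogger(__name__)


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study.

    Cohort sizes mirror a 100-case / 100-control design capped at 200
    samples, with controls matched from a 723-sample non-disease pool;
    case demographics follow a lung-cancer-like group (age 67.25 +/- 9.5,
    52.1% male). ``effect`` is the fraction of cases whose regions are
    forced to cover at least one gene annotated under ``planted_root``.
    """

    seed: int = 0
    n_terms: int = 150
    max_parents: int = 3
    n_genes: int = 300
    terms_per_gene: tuple[int, int] = (1, 3)
    n_chromosomes: int = 4
    chrom_length_bp: int = 60_000_000
    n_case: int = 100
    n_ctrl_pool: int = 723
    n_ctrl_sampled: int = 100
    regions_per_sample: tuple[int, int] = (1, 5)
    region_length_bp: tuple[int, int] = (500_000, 5_000_000)
    planted_root: str | None = None  # None: chosen automatically
    planted_genes_range: tuple[int, int] = (6, 40)
    planted_genes_target: int = 20
    planted_max_genes_per_term: int | None = None
    effect: float = 1.0
    # optional cap on case concentration: when set, the number of
    # signal-carrying cases is ~this many per planted gene (never more than
    # effect * n_case), so each rare term keeps a bounded carrier count
    cases_per_planted_gene: float | None = None
    age_mean_case: float = 67.25
    age_sd_case: float = 9.5
    age_mean_ctrl: float = 65.0
    age_sd_ctrl: float = 10.0
    male_frac_case: float = 0.521
    male_frac_ctrl: float = 0.5

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("need at least 2 terms")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")


def low_frequency_config(seed: int = 0) -> FixtureConfig:
    """A sparser fixture where the planted signal is spread so thinly that
    each individual term stays rare (carried by <= ~10% of samples) while
    the planted sub-GO as a whole still separates cases from controls.

    The planted root is constrained to a branch of rare terms (each
    annotating at most three genes) and the signal-carrying cases are
    scattered across the branch at a bounded ~2 cases per gene, so no
    single term accumulates enough carriers for a per-term Fisher test
    while the sub-GO-level similarity signal — the union of carriers of
    any branch term against non-carriers — stays strong.
    """
    return FixtureConfig(
        seed=seed,
        n_terms=900,
        n_genes=400,
        terms_per_gene=(1, 3),
        regions_per_sample=(1, 3),
        region_length_bp=(250_000, 1_500_000),
        planted_genes_range=(12, 60),
        planted_genes_target=30,
        planted_max_genes_per_term=3,
        cases_per_planted_gene=2.0,
    )


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_ontology(config: FixtureConfig) -> OntologyDAG:
    """Random single-namespace DAG: term i draws 1..max_parents parents
    uniformly from terms 0..i-1, so term 0 is the root and acyclicity is
    guaranteed by construction."""
    rng = np.random.default_rng(config.seed)
    terms = [_term_id(i) for i in range(config.n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, config.n_terms):
        k = int(rng.integers(1, config.max_parents + 1))
        k = min(k, i)
        chosen = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[int(j)] for j in chosen}
    return OntologyDAG(
        terms=set(terms),
        names={t: f"synthetic term {i}" for i, t in enumerate(terms)},
        namespace={t: "biological_process" for t in terms},
        parents=parents,
    )


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialise as OBO 1.2 that round-trips through :func:`parse_obo`."""
    lines = ["format-version: 1.2", "default-namespace: biological_process", ""]
    for t in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: {dag.names[t]}")
        lines.append(f"namespace: {dag.namespace[t]}")
        for p in sorted(dag.parents[t]):
            lines.append(f"is_a: {p} ! {dag.names[p]}")
        lines.append("")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines))


@dataclass
class Annotation:
    gene_track: GeneTrack
    gene2go: dict[str, set[str]]
    chrom_lengths: dict[str, int]


def generate_annotation(dag: OntologyDAG, config: FixtureConfig) -> Annotation:
    """Genes tiled non-overlapping along chromosomes with jittered spacing;
    each gene draws direct annotations biased toward leaves
    (weight 1/(1 + #descendants))."""
    rng = np.random.default_rng(config.seed + 1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length_bp for c in chroms}

    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gene_i = 0
    for chrom, m in zip(chroms, per_chrom):
        if m == 0:
            continue
        slot = config.chrom_length_bp // (m + 1)
        max_len = max(1000, int(slot * 0.4))
        for j in range(m):
            length = int(rng.integers(min(20_000, max_len), max_len + 1))
            jitter = int(rng.integers(0, max(1, slot // 4)))
            start = (j + 1) * slot + jitter - slot // 2
            rows.append((chrom, start, start + length, f"G{gene_i + 1:04d}"))
            gene_i += 1
    track = GeneTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"]))

    terms = sorted(dag.terms)
    weights = np.array([1.0 / (1 + len(dag.descendants(t, include_self=False))) for t in terms])
    weights /= weights.sum()
    lo, hi = config.terms_per_gene
    gene2go: dict[str, set[str]] = {}
    for _, _, _, symbol in rows:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False, p=weights)
        gene2go[symbol] = {terms[int(i)] for i in chosen}
    return Annotation(gene_track=track, gene2go=gene2go, chrom_lengths=chrom_lengths)


def choose_planted_root(
    dag: OntologyDAG,
    gene2go: dict[str, set[str]],
    min_genes: int = 6,
    max_genes: int = 40,
    target_genes: int = 20,
    max_genes_per_term: int | None = None,
) -> str:
    """Deterministically pick a mid-sized sub-GO root to carry the signal.

    Candidates are non-root terms with at least two children whose node set
    intersects the annotations of ``min_genes``..``max_genes`` genes; the
    one closest to ``target_genes`` wins (ties to the smallest id). With
    ``max_genes_per_term`` the branch must consist of rare terms only —
    every member term annotating at most that many genes — which is how the
    low-frequency fixture keeps each individual term below the radar of a
    per-term test.
    """
    gene_count: dict[str, int] = {}
    for ts in gene2go.values():
        for t in ts:
            gene_count[t] = gene_count.get(t, 0) + 1
    best = None
    for term in sorted(dag.terms):
        if not dag.parents[term] or len(dag.children(term)) < 2:
            continue
        nodes = dag.descendants(term)
        n_genes = sum(1 for ts in gene2go.values() if ts & nodes)
        used_terms = {t for ts in gene2go.values() for t in ts & nodes}
        if not (min_genes <= n_genes <= max_genes) or len(used_terms) < 3:
            continue
        if max_genes_per_term is not None and any(
            gene_count.get(t, 0) > max_genes_per_term for t in used_terms
        ):
            continue
        score = (abs(n_genes - target_genes), term)
        if best is None or score < best[0]:
            best = (score, term)
    if best is None:
        raise ValueError("no suitable planted root; regenerate with another seed")
    return best[1]


@dataclass
class CohortFixture:
    """In-memory cohort plus everything needed to write it to disk."""

    cases: list[SampleRecord]
    ctrl_pool: list[SampleRecord]
    controls: list[SampleRecord]
    planted_root: str

    @property
    def cohort(self) -> list[SampleRecord]:
        return self.cases + self.controls


def _random_region(rng, config: FixtureConfig) -> Region:
    chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
    lo, hi = config.region_length_bp
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, max(1, config.chrom_length_bp - length)))
    return Region(chrom, start, start + length)


def _planted_region(rng, config, gene_row) -> Region:
    lo, hi = config.region_length_bp
    length = int(rng.integers(lo, hi + 1))
    center = (int(gene_row.start) + int(gene_row.end)) // 2
    start = max(0, min(center - length // 2, config.chrom_length_bp - length))
    return Region(str(gene_row.chrom), start, start + length)


def generate_cohort(
    dag: OntologyDAG,
    annotation: Annotation,
    config: FixtureConfig,
) -> CohortFixture:
    """Cases with a planted functional signal plus matched controls.

    Controls in the pool draw all regions uniformly. A fraction ``effect``
    of cases has its first region centred on a random gene annotated under
    the planted sub-GO root; all other regions are uniform background. The
    final control arm is a sex- and age-matched sample of
    ``n_ctrl_sampled`` pool members, echoing a matched case-control
    design.
    """
    rng = np.random.default_rng(config.seed + 2)
    lo_g, hi_g = config.planted_genes_range
    planted_root = config.planted_root or choose_planted_root(
        dag, annotation.gene2go,
        min_genes=lo_g, max_genes=hi_g,
        target_genes=config.planted_genes_target,
        max_genes_per_term=config.planted_max_genes_per_term,
    )
    planted_nodes = dag.descendants(planted_root)
    planted_genes = sorted(
        g for g, ts in annotation.gene2go.items() if ts & planted_nodes
    )
    if not planted_genes:
        raise ValueError(f"no gene annotated under planted root {planted_root}")
    gene_rows = {r.symbol: r for r in annotation.gene_track.frame.itertuples(index=False)}

    lo_r, hi_r = config.regions_per_sample
    n_signal = None
    if config.cases_per_planted_gene is not None:
        n_signal = min(
            config.n_case,
            round(config.cases_per_planted_gene * len(planted_genes)),
            round(config.effect * config.n_case),
        )
    cases = []
    for i in range(config.n_case):
        n_reg = int(rng.integers(lo_r, hi_r + 1))
        regions = [_random_region(rng, config) for _ in range(n_reg)]
        carries_signal = (
            i < n_signal if n_signal is not None else rng.random() < config.effect
        )
        if carries_signal:
            gene = planted_genes[int(rng.integers(0, len(planted_genes)))]
            regions[0] = _planted_region(rng, config, gene_rows[gene])
        age = float(np.round(rng.normal(config.age_mean_case, config.age_sd_case), 1))
        sex = "M" if rng.random() < config.male_frac_case else "F"
        cases.append(SampleRecord(
            sample_id=f"case{i + 1:04d}", label="case", sex=sex, age=age, regions=regions,
        ))

    pool = []
    for i in range(config.n_ctrl_pool):
        n_reg = int(rng.integers(lo_r, hi_r + 1))
        regions = [_random_region(rng, config) for _ in range(n_reg)]
        age = float(np.round(rng.normal(config.age_mean_ctrl, config.age_sd_ctrl), 1))
        sex = "M" if rng.random() < config.male_frac_ctrl else "F"
        pool.append(SampleRecord(
            sample_id=f"ctrl{i + 1:04d}", label="ctrl", sex=sex, age=age, regions=regions,
        ))

    controls = matched_control_sample(pool, cases, config.n_ctrl_sampled, seed=config.seed + 3)
    return CohortFixture(cases=cases, ctrl_pool=pool, controls=controls,
                         planted_root=planted_root)


def matched_control_sample(
    pool: list[SampleRecord],
    cases: list[SampleRecord],
    n: int,
    seed: int,
) -> list[SampleRecord]:
    """Draw ``n`` controls matching the cases' sex x age-decade mix.

    Per-bin quotas are proportional to the case distribution with
    largest-remainder rounding. When a bin is short, the draw falls back to
    the nearest non-empty age decade (same sex first, then the other sex),
    with a warning. Raises when the pool is exhausted outright.
    """
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} cannot supply {n} controls")
    rng = np.random.default_rng(seed)

    def bin_of(rec: SampleRecord) -> tuple[str, int]:
        return (rec.sex, int(rec.age // 10))

    case_bins: dict[tuple[str, int], int] = {}
    for rec in cases:
        case_bins[bin_of(rec)] = case_bins.get(bin_of(rec), 0) + 1
    total = len(cases)
    raw = {b: n * c / total for b, c in case_bins.items()}
    quotas = {b: int(q) for b, q in raw.items()}
    leftover = n - sum(quotas.values())
    for b in sorted(raw, key=lambda b: (-(raw[b] - quotas[b]), b))[:leftover]:
        quotas[b] += 1

    available: dict[tuple[str, int], list[SampleRecord]] = {}
    for rec in sorted(pool, key=lambda r: r.sample_id):
        available.setdefault(bin_of(rec), []).append(rec)
    for b in sorted(available):
        recs = available[b]
        available[b] = [recs[i] for i in rng.permutation(len(recs))]

    chosen: list[SampleRecord] = []
    shortfall: dict[tuple[str, int], int] = {}
    for b in sorted(quotas):
        want = quotas[b]
        have = available.get(b, [])
        take = min(want, len(have))
        chosen.extend(have[:take])
        available[b] = have[take:]
        if take < want:
            shortfall[b] = want - take

    for (sex, decade), missing in sorted(shortfall.items()):
        logger.warning(
            "matched sampling: bin (%s, %d0s) short by %d, falling back to "
            "nearest bins", sex, decade, missing,
        )
        while missing > 0:
            candidates = [
                b for b, recs in available.items() if recs
            ]
            if not candidates:
                raise ValueError("control pool exhausted during matched sampling")
            candidates.sort(key=lambda b: (b[0] != sex, abs(b[1] - decade), b))
            src = candidates[0]
            chosen.append(available[src].pop(0))
            missing -= 1

    return sorted(chosen, key=lambda r: r.sample_id)


@dataclass
class Fixture:
    """A complete synthetic study, in memory."""

    config: FixtureConfig
    dag: OntologyDAG
    annotation: Annotation
    cohort_fixture: CohortFixture

    @property
    def planted_root(self) -> str:
        return self.cohort_fixture.planted_root

    def annotated_cohort(self) -> list[SampleRecord]:
        return annotate_cohort(
            self.cohort_fixture.cohort,
            self.annotation.gene_track,
            self.annotation.gene2go,
            self.dag,
        )


def generate_fixture(config: FixtureConfig | None = None) -> Fixture:
    config = config or FixtureConfig()
    dag = generate_ontology(config)
    annotation = generate_annotation(dag, config)
    cohort = generate_cohort(dag, annotation, config)
    return Fixture(config=config, dag=dag, annotation=annotation, cohort_fixture=cohort)


# ---------------------------------------------------------------- writers

def write_gene_track(annotation: Annotation, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in annotation.gene_track.frame.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.symbol}\n")


def write_gene2go(annotation: Annotation, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for gene in sorted(annotation.gene2go):
            for term in sorted(annotation.gene2go[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_chrom_lengths(annotation: Annotation, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"{chrom}\t{annotation.chrom_lengths[chrom]}\n")


def write_regions(cohort: list[SampleRecord], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in cohort:
            for region in rec.regions:
                fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{rec.sample_id}\n")


def write_phenotypes(cohort: list[SampleRecord], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\tlabel\tsex\tage\n")
        for rec in cohort:
            fh.write(f"{rec.sample_id}\t{rec.label}\t{rec.sex}\t{rec.age}\n")


def write_fixture(fixture: Fixture, outdir) -> dict[str, str]:
    """Write every pipeline input to ``outdir``; returns the path map."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "obo": os.path.join(outdir, "ontology.obo"),
        "genes": os.path.join(outdir, "genes.bed"),
        "gene2go": os.path.join(outdir, "gene2go.tsv"),
        "chrom_lengths": os.path.join(outdir, "chrom_lengths.tsv"),
        "regions": os.path.join(outdir, "regions.bed"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "meta": os.path.join(outdir, "fixture.json"),
    }
    write_obo(fixture.dag, paths["obo"])
    write_gene_track(fixture.annotation, paths["genes"])
    write_gene2go(fixture.annotation, paths["gene2go"])
    write_chrom_lengths(fixture.annotation, paths["chrom_lengths"])
    write_regions(fixture.cohort_fixture.cohort, paths["regions"])
    write_phenotypes(fixture.cohort_fixture.cohort, paths["phenotypes"])
    with open(paths["meta"], "w", newline="\n") as fh:
        json.dump({"planted_root": fixture.planted_root,
                   "seed": fixture.config.seed}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
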