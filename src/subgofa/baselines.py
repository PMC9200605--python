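"""Conventional per-feature tests and detection-ratio validation.

The comparators test each gene symbol (or each GO term) for differential
presence between cases and controls with a two-sided Fisher exact test and
BH-FDR across features. Validation scores every method by its detection
ratio: the fraction of the genes it selects at a threshold that appear in
a curated disease-gene list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import SubGOResult, significant_results
from .regions import SampleRecord
from .stats import bh_fdr, fisher_exact_2x2


@dataclass
class FeatureTestResult:
    """One feature's presence/absence association with case status."""

    feature: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows case/ctrl, cols present/absent
    p_value: float
    fdr: float = float("nan")


def _presence_tests(cohort: list[SampleRecord], feature_of) -> list[FeatureTestResult]:
    n_case = sum(1 for r in cohort if r.label == "case")
    n_ctrl = len(cohort) - n_case
    counts: dict[str, list[int]] = {}
    for rec in cohort:
        for f in feature_of(rec):
            cnt = counts.setdefault(f, [0, 0])
            cnt[0 if rec.label == "case" else 1] += 1
    results = []
    for feature in sorted(counts):
        ca, ct = counts[feature]
        table = ((ca, n_case - ca), (ct, n_ctrl - ct))
        results.append(FeatureTestResult(feature, table, fisher_exact_2x2(table).p_value))
    if results:
        for r, q in zip(results, bh_fdr([r.p_value for r in results])):
            r.fdr = float(q)
    results.sort(key=lambda r: (r.fdr, r.p_value, r.feature))
    return results


def fisher_per_gene(cohort: list[SampleRecord]) -> list[FeatureTestResult]:
    """Fisher test of per-sample gene presence, one test per observed gene."""
    return _presence_tests(cohort, lambda r: r.genes)


def fisher_per_term(cohort: list[SampleRecord]) -> list[FeatureTestResult]:
    """Fisher test of per-sample GO-term presence, one test per observed term."""
    return _presence_tests(cohort, lambda r: r.term_set)


def detection_ratio(selected_genes: set[str], disease_genes: set[str]) -> float | None:
    """|selected ∩ disease| / |selected|; None (NA) when nothing is selected.

    Matching is case-insensitive on gene symbols.
    """
    selected = {g.upper() for g in selected_genes}
    if not selected:
        return None
    disease = {g.upper() for g in disease_genes}
    return len(selected & disease) / len(selected)


def subgofa_selected_genes(
    results: list[SubGOResult],
    threshold: float,
    mode: str = "fdr",
) -> set[str]:
    """Union of observed genes annotated under any significant sub-GO root."""
    out: set[str] = set()
    for r in significant_results(results, threshold, mode):
        out |= r.genes_under_root
    return out


def gene_baseline_selected_genes(
    results: list[FeatureTestResult],
    threshold: float,
    mode: str = "fdr",
) -> set[str]:
    key = (lambda r: r.fdr) if mode == "fdr" else (lambda r: r.p_value)
    return {r.feature for r in results if key(r) <= threshold}


def term_baseline_selected_genes(
    results: list[FeatureTestResult],
    threshold: float,
    cohort: list[SampleRecord],
    gene2go: dict[str, set[str]],
    mode: str = "fdr",
) -> set[str]:
    """Observed genes carrying any term significant at the threshold."""
    key = (lambda r: r.fdr) if mode == "fdr" else (lambda r: r.p_value)
    hits = {r.feature for r in results if key(r) <= threshold}
    observed: set[str] = set()
    for rec in cohort:
        observed |= rec.genes
    return {g for g in observed if gene2go.get(g, set()) & hits}


def threshold_sweep(
    selectors: dict[str, "callable"],
    disease_genes: set[str],
    thresholds: list[float],
    mode: str = "fdr",
) -> pd.DataFrame:
    """Detection ratio per method per threshold, long format.

    ``selectors`` maps a method name to a callable ``threshold -> set of
    selected gene symbols`` (already fixed to ``mode``). Empty selections
    yield ratio NA, mirroring an all-rejected baseline.
    """
    disease = {g.upper() for g in disease_genes}
    rows = []
    for method, select in selectors.items():
        for thr in thresholds:
            genes = {g.upper() for g in select(thr)}
            ratio = detection_ratio(genes, disease)
            rows.append({
                "method": method,
                "mode": mode,
                "threshold": thr,
                "n_selected": len(genes),
                "n_hit": len(genes & disease),
                "ratio": np.nan if ratio is None else ratio,
            })
    return pd.DataFrame(rows)


def term_frequency_distribution(
    significant_terms: set[str],
    cohort: list[SampleRecord],
    bin_width: int = 20,
) -> tuple[pd.Series, pd.DataFrame]:
    """How many samples carry each significant term, plus binned counts.

    For the sub-GO method pass the member terms of the significant roots;
    for the per-term baseline pass the significant terms themselves. The
    fixed bin width of 20 samples echoes the low-frequency (0-20) versus
    common (20-40) contrast the method targets.
    """
    freqs = {}
    for term in sorted(significant_terms):
        freqs[term] = sum(1 for rec in cohort if term in rec.term_set)
    series = pd.Series(freqs, dtype=int, name="n_samples")
    if series.empty:
        return series, pd.DataFrame(columns=["bin_left", "bin_right", "count", "density"])
    top = max(int(series.max()) + 1, bin_width)
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(series.values, bins=edges)
    hist = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "density": counts / counts.sum(),
    })
    return series, hist


def subgo_member_terms(
    results: list[SubGOResult],
    threshold: float,
    dag,
    cohort: list[SampleRecord],
    mode: str = "fdr",
) -> set[str]:
    """Member terms of significant sub-GO roots that occur in the cohort."""
    observed: set[str] = set()
    for rec in cohort:
        observed |= rec.term_set
    out: set[str] = set()
    for r in significant_results(results, threshold, mode):
        out |= dag.descendants(r.root) & observed
    return out
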