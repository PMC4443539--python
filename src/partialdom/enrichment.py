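"""Taxonomic enrichment of bounded partials and annotation-quality contrasts.

If bounded partial domains arise from inaccurate gene models, they should be
over-represented among eukaryotic sequences (intron-containing genomes are the
ones whose predicted proteins get truncated).  Per family with enough bounded
partials, a 2x2 table contrasts bounded-partial-containing sequences against
sequences carrying the family but no <50% partial, split by the eukaryote
flag; Fisher's exact test (two-sided, probability ordering) with FDR control
across families summarizes the evidence.  A second contrast asks whether
bounded-partial proteins are depleted of reviewed entries and of entries with
a curated gene model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_core import Dataset, SequenceMeta
from .partial_classifier import BOUNDED, ClassificationSet

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact",
    "fdr_adjust",
    "family_enrichment",
    "reviewed_contrast",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows are group 1 / group 2, columns outcome yes / no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is empty (the test carries no
        information and p is reported as 1)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EnrichmentResult:
    family_id: str
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    q_value: float


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and sample odds ratio a*d/(b*c).

    Two-sided by probability ordering: the p-value sums the hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed one.  A degenerate margin gives p = 1.
    """
    if table.degenerate:
        return 1.0, table.odds_ratio
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0)), table.odds_ratio


def fdr_adjust(p_values, method: str = "bh") -> np.ndarray:
    """FDR-adjusted values: Benjamini-Hochberg (default) or Storey q-values.

    The Storey variant rescales BH by the estimated null fraction
    pi0 = #(p > 0.5) / (0.5 m), capped at 1; it is less conservative when many
    tests are non-null, at the cost of an estimated quantity.
    Order-preserving and bounded by 1 in both cases.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * p.size))
        pi0 = max(pi0, 1.0 / p.size)
        return np.minimum(bh * pi0, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def _sequence_partial_index(
    classifications: ClassificationSet,
) -> tuple[set[str], dict[str, set[str]]]:
    """Sequences carrying any <50% partial, and per-family bounded sequences."""
    any_partial: set[str] = set()
    bounded_by_family: dict[str, set[str]] = {}
    for c in classifications.classifications:
        any_partial.add(c.annotation.seq_id)
        if c.category == BOUNDED:
            bounded_by_family.setdefault(c.annotation.family_id, set()).add(
                c.annotation.seq_id
            )
    return any_partial, bounded_by_family


def family_enrichment(
    classifications: ClassificationSet,
    dataset: Dataset,
    min_bounded: int = 10,
    fdr_method: str = "bh",
    q_thresholds: tuple[float, float] = (0.05, 0.01),
) -> tuple[pd.DataFrame, dict]:
    """Per-family eukaryote enrichment of bounded partials.

    For each family with at least ``min_bounded`` bounded <50% partial
    domains, the 2x2 table is (bounded-partial sequences of the family vs
    sequences annotated with the family but free of <50% partials) x
    (eukaryote vs not).  Returns the per-family results table plus a summary
    with the number of families significant at each q threshold.
    """
    any_partial, bounded_by_family = _sequence_partial_index(classifications)

    bounded_domain_counts: dict[str, int] = {}
    for c in classifications.classifications:
        if c.category == BOUNDED:
            fam = c.annotation.family_id
            bounded_domain_counts[fam] = bounded_domain_counts.get(fam, 0) + 1

    family_sequences: dict[str, set[str]] = {}
    for ann in dataset.annotations:
        family_sequences.setdefault(ann.family_id, set()).add(ann.seq_id)

    rows = []
    for family_id in sorted(bounded_by_family):
        if bounded_domain_counts.get(family_id, 0) < min_bounded:
            continue
        bounded_seqs = bounded_by_family[family_id]
        comparison = family_sequences.get(family_id, set()) - any_partial
        euk = lambda sids: sum(dataset.sequences[s].is_eukaryote for s in sids)
        a = euk(bounded_seqs)
        b = len(bounded_seqs) - a
        c = euk(comparison)
        d = len(comparison) - c
        table = ContingencyTable2x2(a, b, c, d)
        p, orat = fisher_exact(table)
        rows.append(
            {
                "family_id": family_id,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": orat,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["family_id", "a", "b", "c", "d", "odds_ratio", "p_value"]
    )
    if len(df):
        df["q_value"] = fdr_adjust(df["p_value"].to_numpy(), method=fdr_method)
    else:
        df["q_value"] = pd.Series(dtype=float)
    summary = {
        "n_families_tested": int(len(df)),
        "min_bounded": min_bounded,
        "fdr_method": fdr_method,
    }
    for thr in q_thresholds:
        summary[f"n_significant_q<{thr}"] = int((df["q_value"] < thr).sum()) if len(df) else 0
    return df, summary


def reviewed_contrast(
    classifications: ClassificationSet,
    dataset: Dataset,
    taxa_filter=None,
) -> dict:
    """Reviewed and reviewed-with-gene-model contrasts for bounded partials.

    Rows: bounded-partial-containing sequences vs sequences free of <50%
    partials; columns: reviewed yes/no in the first table, reviewed-with-
    gene-model yes/no in the second.  ``taxa_filter`` optionally restricts to
    a subset of sequences (a predicate on :class:`SequenceMeta`, emulating the
    well-annotated-genomes restriction).
    """
    sample = next(iter(dataset.sequences.values()), None)
    if sample is None:
        raise ValueError("dataset has no sequences")

    any_partial, bounded_by_family = _sequence_partial_index(classifications)
    bounded_seqs: set[str] = set()
    for seqs in bounded_by_family.values():
        bounded_seqs |= seqs

    def keep(meta: SequenceMeta) -> bool:
        return taxa_filter(meta) if taxa_filter is not None else True

    annotated = {a.seq_id for a in dataset.annotations}
    group1 = [
        dataset.sequences[s]
        for s in sorted(bounded_seqs)
        if keep(dataset.sequences[s])
    ]
    group2 = [
        dataset.sequences[s]
        for s in sorted(annotated - any_partial)
        if keep(dataset.sequences[s])
    ]

    out = {}
    for name, flag in (
        ("reviewed", lambda m: m.reviewed),
        ("reviewed_gene_model", lambda m: m.reviewed and m.has_gene_model),
    ):
        a = sum(flag(m) for m in group1)
        b = len(group1) - a
        c = sum(flag(m) for m in group2)
        d = len(group2) - c
        table = ContingencyTable2x2(a, b, c, d)
        p, orat = fisher_exact(table)
        out[name] = {"table": table, "odds_ratio": orat, "p_value": p}
    return out
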