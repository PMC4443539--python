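"""Classification of <50% partial domains as split, bounded or unbounded.

A profile-HMM alignment can break one biological domain into several annotated
pieces ("split"); chains of same-family (or same-clan) annotations whose model
intervals progress consistently are detected first and their short members are
labeled split.  Remaining partials are judged by geometry: the full model is
projected around the annotation and the "free span" — the maximal stretch of
sequence around the partial delimited by the sequence termini and the nearest
non-homologous annotations — is compared against the model length.  Partials
with room for (almost) the whole model are "unbounded"; partials pinned by a
terminus or a foreign domain are "bounded".

Precedence: split is decided first; bounded/unbounded only among non-split
partials.  Clan co-membership counts as homology throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_core import (
    CoverageResult,
    Dataset,
    DomainAnnotation,
    FamilyModel,
    coverage,
    filter_annotations,
)

__all__ = [
    "ClassifierParams",
    "ProjectedInterval",
    "PartialClassification",
    "ClassificationSet",
    "build_chains",
    "classify_split",
    "project_full_model",
    "classify_bounded_unbounded",
    "classify_all",
    "set_putative",
    "classifications_to_frame",
]

SPLIT = "split"
BOUNDED = "bounded"
UNBOUNDED = "unbounded"
CATEGORIES = (SPLIT, BOUNDED, UNBOUNDED)


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable thresholds of the classifier.

    partial_threshold
        Fraction of model_length below which (strictly) an annotation is a
        partial; 0.5 by convention.
    chain_overlap_tolerance
        Maximum model-interval overlap, in match states, between consecutive
        members of a split chain.  Alignment boundaries are fuzzy, so pieces
        of one broken domain may re-align a few states twice.
    neighbor_overlap_tolerance
        Residues of overlap tolerated between the free span and a
        non-homologous neighboring annotation.
    slack
        An unbounded call requires a free span of at least
        ``(1 - slack) * model_length`` residues.
    """

    partial_threshold: float = 0.5
    chain_overlap_tolerance: int = 10
    neighbor_overlap_tolerance: int = 10
    slack: float = 0.1


@dataclass(frozen=True)
class ProjectedInterval:
    """The full family model projected onto the sequence around an annotation."""

    seq_id: str
    proj_start: int
    proj_end: int
    clipped_left: bool
    clipped_right: bool

    @property
    def length(self) -> int:
        return self.proj_end - self.proj_start + 1


@dataclass(frozen=True)
class PartialClassification:
    annotation: DomainAnnotation
    category: str
    covered_states: int
    fraction: float
    putative: bool = False
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.putative and self.category != UNBOUNDED:
            raise ValueError("putative flag only applies to unbounded partials")


@dataclass
class ClassificationSet:
    """All partial classifications for one dataset plus run parameters."""

    classifications: list[PartialClassification]
    params: ClassifierParams
    n_annotations: int
    n_sequences: int

    def by_category(self, category: str) -> list[PartialClassification]:
        return [c for c in self.classifications if c.category == category]

    def domain_tally(self) -> dict[str, int]:
        tally = {c: 0 for c in CATEGORIES}
        for cl in self.classifications:
            tally[cl.category] += 1
        tally["total"] = len(self.classifications)
        tally["putative"] = sum(c.putative for c in self.classifications)
        return tally

    def sequence_tally(self) -> dict[str, int]:
        per_cat: dict[str, set[str]] = {c: set() for c in CATEGORIES}
        all_seqs: set[str] = set()
        putative: set[str] = set()
        for cl in self.classifications:
            per_cat[cl.category].add(cl.annotation.seq_id)
            all_seqs.add(cl.annotation.seq_id)
            if cl.putative:
                putative.add(cl.annotation.seq_id)
        tally = {c: len(s) for c, s in per_cat.items()}
        tally["total"] = len(all_seqs)
        tally["putative"] = len(putative)
        return tally


def _same_group(
    a: DomainAnnotation, b: DomainAnnotation, clan_map: Mapping[str, str | None]
) -> bool:
    """Homologous for chaining: same family, or both in one (non-null) clan."""
    if a.family_id == b.family_id:
        return True
    ca, cb = clan_map.get(a.family_id), clan_map.get(b.family_id)
    return ca is not None and ca == cb


def _sort_key(a: DomainAnnotation) -> tuple:
    return (a.seq_start, a.seq_end, a.family_id, a.model_start, a.model_end)


def build_chains(
    annotations: Sequence[DomainAnnotation],
    clan_map: Mapping[str, str | None],
    overlap_tolerance: int = 10,
) -> list[list[DomainAnnotation]]:
    """Group annotations on one sequence into maximal split chains.

    Consecutive chain members (ordered by seq_start among annotations of the
    same family/clan group) must progress through the model: the downstream
    member's model_start may not precede the upstream member's model_start,
    and the model intervals may overlap by at most ``overlap_tolerance`` match
    states.  Annotations of other families between two chain members do not
    break the chain.  Result is independent of input order.
    """
    ordered = sorted(annotations, key=_sort_key)
    chains: list[list[DomainAnnotation]] = []
    for ann in ordered:
        attached = False
        for chain in chains:
            tail = chain[-1]
            if not _same_group(tail, ann, clan_map):
                continue
            if ann.model_start < tail.model_start:
                continue
            overlap = tail.model_end - ann.model_start + 1
            if overlap > overlap_tolerance:
                continue
            chain.append(ann)
            attached = True
            break
        if not attached:
            chains.append([ann])
    return chains


def classify_split(
    chains: Iterable[Sequence[DomainAnnotation]],
    coverages: Mapping[tuple, CoverageResult],
) -> dict[tuple, str]:
    """Label every <50% partial in a multi-member chain as split.

    Returns {annotation.key: chain_id} for the split-labeled partials.  A
    partial chained with a >=50% member is still split — the aligner broke one
    domain — but only the <50% members are partials.
    """
    labels: dict[tuple, str] = {}
    for i, chain in enumerate(chains):
        if len(chain) < 2:
            continue
        head = chain[0]
        chain_id = f"chain:{head.seq_id}:{head.family_id}:{i}"
        for ann in chain:
            cov = coverages.get(ann.key)
            if cov is not None and cov.is_partial_50:
                labels[ann.key] = chain_id
    return labels


def project_full_model(
    annotation: DomainAnnotation, family: FamilyModel, seq_length: int
) -> ProjectedInterval:
    """Project the full model onto the sequence around ``annotation``.

    The annotation is extended ``model_start - 1`` residues upstream and
    ``model_length - model_end`` downstream (one residue per unmatched match
    state), clipped to the sequence; clip flags record where a terminus binds.
    """
    start = annotation.seq_start - (annotation.model_start - 1)
    end = annotation.seq_end + (family.model_length - annotation.model_end)
    return ProjectedInterval(
        seq_id=annotation.seq_id,
        proj_start=max(1, start),
        proj_end=min(seq_length, end),
        clipped_left=start < 1,
        clipped_right=end > seq_length,
    )


def _free_span(
    partial: DomainAnnotation,
    other_annotations: Sequence[DomainAnnotation],
    clan_map: Mapping[str, str | None],
    seq_length: int,
    overlap_tolerance: int,
) -> tuple[int, int, str, str]:
    """Maximal interval around the partial delimited by termini and
    non-homologous annotations; returns (start, end, left_feature, right_feature).
    """
    left, right = 1, seq_length
    left_feat, right_feat = "terminus", "terminus"
    for other in other_annotations:
        if other.key == partial.key or _same_group(partial, other, clan_map):
            continue
        ref = f"{other.family_id}:{other.seq_start}-{other.seq_end}"
        if other.seq_end < partial.seq_start + overlap_tolerance and other.seq_start < partial.seq_start:
            # left neighbor (small overlaps with the partial tolerated)
            bound = other.seq_end + 1 - overlap_tolerance
            if bound > left:
                left, left_feat = bound, ref
        elif other.seq_start > partial.seq_end - overlap_tolerance and other.seq_end > partial.seq_end:
            # right neighbor
            bound = other.seq_start - 1 + overlap_tolerance
            if bound < right:
                right, right_feat = bound, ref
    left = max(1, min(left, partial.seq_start))
    right = min(seq_length, max(right, partial.seq_end))
    return left, right, left_feat, right_feat


def classify_bounded_unbounded(
    partial: DomainAnnotation,
    projection: ProjectedInterval,
    other_annotations: Sequence[DomainAnnotation],
    clan_map: Mapping[str, str | None],
    family: FamilyModel,
    seq_length: int,
    slack: float = 0.1,
    overlap_tolerance: int = 10,
) -> tuple[str, str]:
    """Decide bounded vs unbounded for a non-split partial.

    Unbounded iff the free span holds at least ``(1 - slack) * model_length``
    residues; otherwise bounded, with the delimiting features (terminus and/or
    the nearest non-homologous annotations) recorded as evidence.
    """
    left, right, left_feat, right_feat = _free_span(
        partial, other_annotations, clan_map, seq_length, overlap_tolerance
    )
    span = right - left + 1
    needed = (1.0 - slack) * family.model_length
    if span >= needed:
        return UNBOUNDED, (
            f"free_span={left}-{right}({span});"
            f"projection={projection.proj_start}-{projection.proj_end}"
        )
    return BOUNDED, f"free_span={left}-{right}({span});left={left_feat};right={right_feat}"


def classify_all(
    dataset: Dataset, params: ClassifierParams | None = None
) -> ClassificationSet:
    """Classify every <50% partial in the filtered dataset.

    Applies the fragment/in_full filters, computes coverage, detects split
    chains per sequence, and assigns bounded/unbounded to the remaining
    partials.  The three categories partition the partial set.
    """
    params = params or ClassifierParams()
    annotations = filter_annotations(dataset)
    clan_map = dataset.clan_map()

    coverages: dict[tuple, CoverageResult] = {}
    for ann in annotations:
        coverages[ann.key] = coverage(
            ann, dataset.family_of(ann), threshold=params.partial_threshold
        )

    by_seq: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_seq.setdefault(ann.seq_id, []).append(ann)

    results: list[PartialClassification] = []
    for seq_id in sorted(by_seq):
        seq_anns = sorted(by_seq[seq_id], key=_sort_key)
        seq_length = dataset.sequences[seq_id].length
        chains = build_chains(seq_anns, clan_map, params.chain_overlap_tolerance)
        split_labels = classify_split(chains, coverages)
        for ann in seq_anns:
            cov = coverages[ann.key]
            if not cov.is_partial_50:
                continue
            if ann.key in split_labels:
                results.append(
                    PartialClassification(
                        annotation=ann,
                        category=SPLIT,
                        covered_states=cov.covered_states,
                        fraction=cov.fraction,
                        evidence=split_labels[ann.key],
                    )
                )
                continue
            family = dataset.family_of(ann)
            projection = project_full_model(ann, family, seq_length)
            category, evidence = classify_bounded_unbounded(
                ann,
                projection,
                seq_anns,
                clan_map,
                family,
                seq_length,
                slack=params.slack,
                overlap_tolerance=params.neighbor_overlap_tolerance,
            )
            results.append(
                PartialClassification(
                    annotation=ann,
                    category=category,
                    covered_states=cov.covered_states,
                    fraction=cov.fraction,
                    evidence=evidence,
                )
            )
    return ClassificationSet(
        classifications=results,
        params=params,
        n_annotations=len(annotations),
        n_sequences=len({a.seq_id for a in annotations}),
    )


def set_putative(
    classification_set: ClassificationSet, putative_keys: set[tuple]
) -> ClassificationSet:
    """Return a copy with the putative flag set on the given unbounded partials."""
    updated = [
        replace(c, putative=True)
        if c.category == UNBOUNDED and c.annotation.key in putative_keys
        else c
        for c in classification_set.classifications
    ]
    return ClassificationSet(
        classifications=updated,
        params=classification_set.params,
        n_annotations=classification_set.n_annotations,
        n_sequences=classification_set.n_sequences,
    )


def classifications_to_frame(classification_set: ClassificationSet) -> pd.DataFrame:
    """Tabular view of the classification output (tab-separated on disk)."""
    rows = []
    for c in classification_set.classifications:
        a = c.annotation
        rows.append(
            {
                "seq_id": a.seq_id,
                "family_id": a.family_id,
                "seq_start": a.seq_start,
                "seq_end": a.seq_end,
                "model_start": a.model_start,
                "model_end": a.model_end,
                "covered_states": c.covered_states,
                "fraction": round(c.fraction, 6),
                "category": c.category,
                "putative": int(c.putative),
                "evidence": c.evidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "family_id",
            "seq_start",
            "seq_end",
            "model_start",
            "model_end",
            "covered_states",
            "fraction",
            "category",
            "putative",
            "evidence",
        ],
    )
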