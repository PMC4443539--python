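"""Core domain-annotation types, table I/O, coverage and the <50%-partial flag.

The data model mirrors a Pfam-style relational dump: a family table carrying
the profile model length in match states, a sequence metadata table, and a
domain-annotation table mapping model coordinates (match states) onto protein
sequence coordinates.  All coordinates are 1-based inclusive, the Pfam/UniProt
convention.

Coverage of an annotation is ``model_end - model_start + 1`` match states as a
fraction of the family ``model_length``; an annotation covering strictly less
than half the model is flagged as a <50% partial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyModel",
    "SequenceMeta",
    "DomainAnnotation",
    "CoverageResult",
    "Dataset",
    "SchemaError",
    "ReferentialIntegrityError",
    "CoordinateValidationError",
    "load_tables",
    "write_tables",
    "filter_annotations",
    "coverage",
    "coverage_distribution",
    "read_fasta",
    "write_fasta",
]

PARTIAL_THRESHOLD = 0.5

FAMILY_COLUMNS = ("family_id", "model_length", "clan_id")
SEQUENCE_COLUMNS = (
    "seq_id",
    "length",
    "is_fragment",
    "is_eukaryote",
    "reviewed",
    "has_gene_model",
)
ANNOTATION_COLUMNS = (
    "seq_id",
    "family_id",
    "seq_start",
    "seq_end",
    "model_start",
    "model_end",
    "in_full",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ReferentialIntegrityError(ValueError):
    """An annotation references a sequence or family that does not exist."""


class CoordinateValidationError(ValueError):
    """A coordinate invariant (1-based inclusive bounds) is violated."""


@dataclass(frozen=True)
class FamilyModel:
    """One domain family: profile model length in match states, optional clan."""

    family_id: str
    model_length: int
    clan_id: str | None = None

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise ValueError(f"model_length must be >= 1, got {self.model_length}")


@dataclass(frozen=True)
class SequenceMeta:
    """Metadata for one protein sequence record."""

    seq_id: str
    length: int
    is_fragment: bool = False
    is_eukaryote: bool = False
    reviewed: bool = False
    has_gene_model: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"sequence length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class DomainAnnotation:
    """One model-to-sequence mapping, 1-based inclusive in both systems."""

    seq_id: str
    family_id: str
    seq_start: int
    seq_end: int
    model_start: int
    model_end: int
    in_full: bool = True

    def validate(self, seq_length: int, model_length: int) -> None:
        """Check coordinate invariants against the owning sequence and family."""
        if not (1 <= self.seq_start <= self.seq_end <= seq_length):
            raise CoordinateValidationError(
                f"sequence coordinates {self.seq_start}-{self.seq_end} out of "
                f"bounds for {self.seq_id} (length {seq_length})"
            )
        if not (1 <= self.model_start <= self.model_end <= model_length):
            raise CoordinateValidationError(
                f"model coordinates {self.model_start}-{self.model_end} out of "
                f"bounds for {self.family_id} (model_length {model_length})"
            )

    @property
    def key(self) -> tuple[str, str, int, int, int, int]:
        return (
            self.seq_id,
            self.family_id,
            self.seq_start,
            self.seq_end,
            self.model_start,
            self.model_end,
        )


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of one annotation against its family model."""

    annotation: DomainAnnotation
    covered_states: int
    fraction: float
    is_partial_50: bool


@dataclass
class Dataset:
    """The three typed collections plus optional residues keyed by seq_id."""

    families: dict[str, FamilyModel]
    sequences: dict[str, SequenceMeta]
    annotations: list[DomainAnnotation]
    residues: dict[str, str] = field(default_factory=dict)

    def family_of(self, annotation: DomainAnnotation) -> FamilyModel:
        return self.families[annotation.family_id]

    def clan_map(self) -> dict[str, str | None]:
        return {f.family_id: f.clan_id for f in self.families.values()}

    def validate(self) -> None:
        """Cross-reference and coordinate validation of all annotations."""
        for i, ann in enumerate(self.annotations, start=1):
            if ann.seq_id not in self.sequences:
                raise ReferentialIntegrityError(
                    f"annotation row {i}: unknown seq_id {ann.seq_id!r}"
                )
            if ann.family_id not in self.families:
                raise ReferentialIntegrityError(
                    f"annotation row {i}: unknown family_id {ann.family_id!r}"
                )
            try:
                ann.validate(
                    self.sequences[ann.seq_id].length,
                    self.families[ann.family_id].model_length,
                )
            except CoordinateValidationError as exc:
                raise CoordinateValidationError(f"annotation row {i}: {exc}") from None


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s table: ignoring unknown column(s) %s", name, extra)


def _as_bool(series: pd.Series) -> pd.Series:
    # 0/1 serialization (relational-dump style); tolerate true/false text.
    return series.map(
        lambda v: bool(int(v)) if str(v).strip() in {"0", "1"} else str(v).strip().lower() == "true"
    )


def load_tables(
    family_table_path: str | Path,
    annotation_table_path: str | Path,
    sequence_table_path: str | Path,
) -> Dataset:
    """Load the three tab-separated tables into a validated :class:`Dataset`.

    Raises :class:`SchemaError` for missing columns,
    :class:`ReferentialIntegrityError` for dangling references, and
    :class:`CoordinateValidationError` (with the offending row number) for
    coordinate violations.
    """
    fam_df = pd.read_csv(family_table_path, sep="\t", dtype={"family_id": str, "clan_id": str})
    seq_df = pd.read_csv(sequence_table_path, sep="\t", dtype={"seq_id": str})
    ann_df = pd.read_csv(annotation_table_path, sep="\t", dtype={"seq_id": str, "family_id": str})

    _require_columns(fam_df, FAMILY_COLUMNS, "families")
    _require_columns(seq_df, SEQUENCE_COLUMNS, "sequences")
    _require_columns(ann_df, ANNOTATION_COLUMNS, "annotations")

    families: dict[str, FamilyModel] = {}
    for _, row in fam_df.iterrows():
        clan = row["clan_id"]
        clan_id = None if pd.isna(clan) or str(clan) == "" else str(clan)
        fam = FamilyModel(str(row["family_id"]), int(row["model_length"]), clan_id)
        if fam.family_id in families:
            raise ReferentialIntegrityError(f"duplicate family_id {fam.family_id!r}")
        families[fam.family_id] = fam

    sequences: dict[str, SequenceMeta] = {}
    if len(seq_df):
        for col in ("is_fragment", "is_eukaryote", "reviewed", "has_gene_model"):
            seq_df[col] = _as_bool(seq_df[col])
    for _, row in seq_df.iterrows():
        meta = SequenceMeta(
            str(row["seq_id"]),
            int(row["length"]),
            bool(row["is_fragment"]),
            bool(row["is_eukaryote"]),
            bool(row["reviewed"]),
            bool(row["has_gene_model"]),
        )
        if meta.seq_id in sequences:
            raise ReferentialIntegrityError(f"duplicate seq_id {meta.seq_id!r}")
        sequences[meta.seq_id] = meta

    annotations: list[DomainAnnotation] = []
    if len(ann_df):
        ann_df["in_full"] = _as_bool(ann_df["in_full"])
    for _, row in ann_df.iterrows():
        annotations.append(
            DomainAnnotation(
                str(row["seq_id"]),
                str(row["family_id"]),
                int(row["seq_start"]),
                int(row["seq_end"]),
                int(row["model_start"]),
                int(row["model_end"]),
                bool(row["in_full"]),
            )
        )

    ds = Dataset(families=families, sequences=sequences, annotations=annotations)
    ds.validate()
    return ds


def write_tables(
    dataset: Dataset,
    family_table_path: str | Path,
    annotation_table_path: str | Path,
    sequence_table_path: str | Path,
) -> None:
    """Serialize a dataset back to the three tab-separated tables (booleans as 0/1)."""
    fam_df = pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "model_length": f.model_length,
                "clan_id": "" if f.clan_id is None else f.clan_id,
            }
            for f in dataset.families.values()
        ],
        columns=list(FAMILY_COLUMNS),
    )
    seq_df = pd.DataFrame(
        [
            {
                "seq_id": s.seq_id,
                "length": s.length,
                "is_fragment": int(s.is_fragment),
                "is_eukaryote": int(s.is_eukaryote),
                "reviewed": int(s.reviewed),
                "has_gene_model": int(s.has_gene_model),
            }
            for s in dataset.sequences.values()
        ],
        columns=list(SEQUENCE_COLUMNS),
    )
    ann_df = pd.DataFrame(
        [
            {
                "seq_id": a.seq_id,
                "family_id": a.family_id,
                "seq_start": a.seq_start,
                "seq_end": a.seq_end,
                "model_start": a.model_start,
                "model_end": a.model_end,
                "in_full": int(a.in_full),
            }
            for a in dataset.annotations
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    fam_df.to_csv(family_table_path, sep="\t", index=False)
    seq_df.to_csv(sequence_table_path, sep="\t", index=False)
    ann_df.to_csv(annotation_table_path, sep="\t", index=False)


def filter_annotations(dataset: Dataset) -> list[DomainAnnotation]:
    """Annotations with ``in_full`` set, on sequences not flagged as fragments.

    Fragment records are incomplete proteins by construction, so any partial
    coverage there is uninformative; the ``in_full`` flag restricts to the
    curated full-significance set.  The operation is idempotent.
    """
    return [
        a
        for a in dataset.annotations
        if a.in_full and not dataset.sequences[a.seq_id].is_fragment
    ]


def coverage(
    annotation: DomainAnnotation,
    family: FamilyModel,
    threshold: float = PARTIAL_THRESHOLD,
) -> CoverageResult:
    """Coverage of ``annotation`` against ``family``'s model.

    ``covered_states = model_end - model_start + 1``; the partial flag is set
    when ``covered_states < threshold * model_length`` (strict inequality, so a
    domain covering exactly half the model is not a partial).
    """
    if annotation.family_id != family.family_id:
        raise ValueError(
            f"annotation family {annotation.family_id!r} does not match "
            f"family {family.family_id!r}"
        )
    covered = annotation.model_end - annotation.model_start + 1
    fraction = covered / family.model_length
    return CoverageResult(
        annotation=annotation,
        covered_states=covered,
        fraction=fraction,
        is_partial_50=covered < threshold * family.model_length,
    )


def coverage_distribution(
    coverages: Iterable[CoverageResult],
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Cumulative coverage distribution at domain and sequence level.

    Returns one row per bin upper edge (``bin_width, 2*bin_width, ..., 1.0``;
    right-closed, so a fraction lands in the first bin whose upper edge is
    >= the fraction) with cumulative counts and cumulative fractions of
    domains, and of sequences placed at the minimum fraction over their
    domains (a sequence with any short domain counts as short).

    Empty input returns an empty frame rather than raising.
    """
    covs = list(coverages)
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.round(np.arange(1, n_bins + 1) * bin_width, 9)
    if not covs:
        return pd.DataFrame(
            columns=[
                "bin_upper",
                "domains_cum",
                "domains_cum_fraction",
                "sequences_cum",
                "sequences_cum_fraction",
            ]
        )
    fractions = np.array([c.fraction for c in covs])
    seq_min: dict[str, float] = {}
    for c in covs:
        sid = c.annotation.seq_id
        if sid not in seq_min or c.fraction < seq_min[sid]:
            seq_min[sid] = c.fraction
    seq_fractions = np.array(list(seq_min.values()))

    # tolerate fp edge representation: a fraction equal to an edge belongs to it
    dom_cum = np.array([(fractions <= e + 1e-12).sum() for e in edges])
    seq_cum = np.array([(seq_fractions <= e + 1e-12).sum() for e in edges])
    return pd.DataFrame(
        {
            "bin_upper": edges,
            "domains_cum": dom_cum,
            "domains_cum_fraction": dom_cum / len(fractions),
            "sequences_cum": seq_cum,
            "sequences_cum_fraction": seq_cum / len(seq_fractions),
        }
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {seq_id: residues}; first header token is the id."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id.split()[0]] = str(rec.seq).upper()
    return records


def write_fasta(residues: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id in residues:
            fh.write(f">{seq_id}\n")
            seq = residues[seq_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
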