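"""Synthetic Pfam-style datasets with planted ground truth.

The generator emulates the structure of a curated profile-HMM annotation dump:
domain families with models of 200-500 match states, member proteins built as
linker + (mutated) domain + linker, multi-domain architectures with decoy
families, and planted annotation artifacts of every kind the classifier must
recognize:

``split``
    one full domain annotated as consecutive pieces whose model intervals
    overlap by a few match states;
``bounded`` (terminus or neighbor mode)
    a <50% tail of the domain on a protein too short — or too hemmed in by
    non-homologous domains — to hold the full model;
``unbounded``
    a full domain present in the residues but annotated over only a fraction
    of the model, with room all around;
``degraded`` (putative candidates)
    an unbounded-looking annotation whose unannotated complement has been
    replaced by unrelated residues — a genuinely mobile sub-domain, which the
    search stage should flag as putative.

Member domains are mutated copies of a family consensus: substitutions are
uniform over the 19 alternative residues at a per-position rate chosen so the
expected *pairwise* identity between members matches the configured target;
rare short indels are tracked exactly so every planted coordinate is exact.
Identical config + seed reproduces byte-identical tables and FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_core import Dataset, DomainAnnotation, FamilyModel, SequenceMeta

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "MemberRecord",
    "FamilyBundle",
    "SimulationResult",
    "generate_family",
    "plant_split",
    "assign_taxa",
    "simulate_dataset",
    "AMINO_ACIDS",
    "BACKGROUND_FREQS",
]

AMINO_ACIDS = np.array(list("ARNDCQEGHILKMFPSTWYV"))

# Robinson-Robinson style background frequencies (the composition underlying
# the BLOSUM62 matrix), renormalized.
BACKGROUND_FREQS = np.array(
    [
        0.078, 0.051, 0.045, 0.054, 0.019, 0.043, 0.063, 0.074, 0.022, 0.051,
        0.091, 0.057, 0.022, 0.039, 0.052, 0.071, 0.058, 0.013, 0.032, 0.064,
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

COMPLETE = "complete"
SPLIT = "split"
BOUNDED = "bounded"
UNBOUNDED = "unbounded"
PUTATIVE = "putative"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; identical config + seed is reproducible.

    Planted counts are per family and must not exceed ``members_per_family``;
    the remaining members carry one complete full-model annotation.
    """

    seed: int = 0
    n_families: int = 4
    model_length_range: tuple[int, int] = (200, 500)
    members_per_family: int = 30
    identity: float = 0.6
    linker_length_range: tuple[int, int] = (20, 200)
    indel_rate: float = 0.005
    n_split: int = 2
    split_pieces: int = 2
    split_overlap: int = 3
    n_bounded_terminus: int = 2
    n_bounded_neighbor: int = 2
    n_unbounded: int = 2
    n_degraded: int = 0
    keep_fraction: float = 0.45
    n_decoy_families: int = 2
    decoy_model_length_range: tuple[int, int] = (100, 200)
    n_enriched_families: int = 0
    enrichment_odds_ratio: float = 1.0
    eukaryote_base_rate: float = 0.5
    reviewed_rate_nonpartial: float = 0.3
    reviewed_rate_bounded: float = 0.025
    gene_model_rate_reviewed: float = 0.93
    gene_model_rate_unreviewed: float = 0.25
    with_residues: bool = True

    def planted_per_family(self) -> int:
        return (
            self.n_split
            + self.n_bounded_terminus
            + self.n_bounded_neighbor
            + self.n_unbounded
            + self.n_degraded
        )

    def validate(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if self.planted_per_family() > self.members_per_family:
            raise ValueError("planted counts exceed members_per_family")
        if not (0.0 < self.keep_fraction <= 1.0):
            raise ValueError("keep_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted annotation."""

    seq_id: str
    family_id: str
    seq_start: int
    seq_end: int
    model_start: int
    model_end: int
    true_category: str
    provenance: str = ""

    @property
    def key(self) -> tuple:
        return (
            self.seq_id,
            self.family_id,
            self.seq_start,
            self.seq_end,
            self.model_start,
            self.model_end,
        )


@dataclass
class MemberRecord:
    seq_id: str
    length: int
    residues: str | None
    annotations: list[DomainAnnotation]
    truths: list[TruthRecord]


@dataclass
class FamilyBundle:
    family: FamilyModel
    consensus: str | None
    members: list[MemberRecord]


@dataclass
class SimulationResult:
    dataset: Dataset
    truth: pd.DataFrame
    config: SimulationConfig

    def truth_by_key(self) -> dict[tuple, str]:
        return {
            (
                r.seq_id,
                r.family_id,
                int(r.seq_start),
                int(r.seq_end),
                int(r.model_start),
                int(r.model_end),
            ): r.true_category
            for r in self.truth.itertuples()
        }


# ---------------------------------------------------------------------------
# residue-level machinery


def _substitution_rate(identity: float) -> float:
    """Per-member substitution rate giving the target expected pairwise identity.

    Two members agree at a position if neither mutated, or both mutated to the
    same of the 19 alternatives: t = (1-p)^2 + p^2/19; solved for p.
    """
    c = 1.0 / 19.0
    disc = 1.0 - (1.0 + c) * (1.0 - identity)
    return (1.0 - np.sqrt(max(disc, 0.0))) / (1.0 + c)


def _random_residues(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(AMINO_ACIDS, size=n, p=BACKGROUND_FREQS))


def _mutate_domain(
    consensus: str,
    p_sub: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """Mutated copy of the consensus plus offsets of each model state.

    ``offsets[k-1]`` is the 0-based position of model state k in the returned
    string, or -1 if that state was deleted.  Insertions (geometric length,
    mean 2) land between states; deletions drop single states.
    """
    L = len(consensus)
    chars: list[str] = []
    offsets = np.full(L, -1, dtype=np.int64)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    sub_mask = rng.random(L) < p_sub
    del_mask = rng.random(L) < indel_rate / 2.0
    ins_mask = rng.random(L) < indel_rate / 2.0
    for k in range(L):
        if not del_mask[k]:
            if sub_mask[k]:
                orig = aa_index[consensus[k]]
                new = (orig + 1 + int(rng.integers(19))) % 20
                chars.append(str(AMINO_ACIDS[new]))
            else:
                chars.append(consensus[k])
            offsets[k] = len(chars) - 1
        if ins_mask[k]:
            ins_len = int(rng.geometric(0.5))
            chars.append(_random_residues(rng, ins_len))
    return "".join(chars), offsets


def _first_offset(offsets: np.ndarray, k: int) -> int:
    """0-based offset of the first surviving state >= k (1-based)."""
    for j in range(k - 1, len(offsets)):
        if offsets[j] >= 0:
            return int(offsets[j])
    return len(offsets) - 1


def _last_offset(offsets: np.ndarray, k: int) -> int:
    """0-based offset of the last surviving state <= k (1-based)."""
    for j in range(k - 1, -1, -1):
        if offsets[j] >= 0:
            return int(offsets[j])
    return 0


def _split_fractions(n_pieces: int) -> list[float]:
    """Model cut fractions for an n-piece split.

    Two pieces are cut at 2/3 rather than 1/2 so the short piece falls below
    half the model (an even cut leaves both halves at exactly 50%, which is
    not a partial under the strict threshold); three or more pieces are cut
    evenly.
    """
    if n_pieces == 2:
        return [0.0, 2.0 / 3.0, 1.0]
    return [i / n_pieces for i in range(n_pieces + 1)]


def plant_split(
    annotation: DomainAnnotation, n_pieces: int, overlap: int
) -> list[DomainAnnotation]:
    """Split one annotation into ``n_pieces`` with overlapping model intervals.

    Model cut points are evenly spaced; each piece after the first starts
    ``overlap`` states before the previous piece's end, while the sequence
    intervals remain a disjoint, ordered partition of the original span.
    ``n_pieces=1`` returns the annotation unchanged; an overlap as long as a
    piece is rejected.
    """
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if n_pieces == 1:
        return [annotation]
    m_span = annotation.model_end - annotation.model_start + 1
    s_span = annotation.seq_end - annotation.seq_start + 1
    fracs = _split_fractions(n_pieces)
    min_piece = min(
        int(round(b * m_span)) - int(round(a * m_span))
        for a, b in zip(fracs[:-1], fracs[1:])
    )
    if overlap >= min_piece:
        raise ValueError(f"overlap {overlap} is not smaller than a piece")
    m_cuts = [annotation.model_start - 1 + int(round(f * m_span)) for f in fracs]
    s_cuts = [annotation.seq_start - 1 + int(round(f * s_span)) for f in fracs]
    pieces = []
    for i in range(n_pieces):
        m_start = m_cuts[i] + 1 - (overlap if i > 0 else 0)
        pieces.append(
            DomainAnnotation(
                seq_id=annotation.seq_id,
                family_id=annotation.family_id,
                seq_start=s_cuts[i] + 1,
                seq_end=s_cuts[i + 1],
                model_start=m_start,
                model_end=m_cuts[i + 1],
                in_full=annotation.in_full,
            )
        )
    return pieces


# ---------------------------------------------------------------------------
# member construction (one function per planted category)


def _build_member(
    seq_id: str,
    family: FamilyModel,
    consensus: str | None,
    category: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    decoys: Sequence[tuple[FamilyModel, str | None]],
) -> MemberRecord:
    L = family.model_length
    p_sub = _substitution_rate(cfg.identity)
    lo, hi = cfg.linker_length_range
    nl_len = int(rng.integers(lo, hi + 1))
    cl_len = int(rng.integers(lo, hi + 1))

    if cfg.with_residues:
        dom, offsets = _mutate_domain(consensus, p_sub, cfg.indel_rate, rng)
    else:
        dom, offsets = None, np.arange(L, dtype=np.int64)
    dom_len = len(dom) if dom is not None else L

    def linker(n: int) -> str | None:
        return _random_residues(rng, n) if cfg.with_residues else None

    anns: list[DomainAnnotation] = []
    truths: list[TruthRecord] = []
    parts: list[str | None] = []

    def add(family_id, s0, s1, m0, m1, truth, prov=""):
        anns.append(DomainAnnotation(seq_id, family_id, s0, s1, m0, m1, True))
        truths.append(TruthRecord(seq_id, family_id, s0, s1, m0, m1, truth, prov))

    if category in (COMPLETE, SPLIT, UNBOUNDED, PUTATIVE):
        nl = linker(nl_len)
        cl = linker(cl_len)
        if category == COMPLETE:
            parts = [nl, dom, cl]
            add(family.family_id, nl_len + 1, nl_len + dom_len, 1, L, COMPLETE)
        elif category == SPLIT:
            # sequence cuts follow the model cuts so pieces stay consistent
            pieces = []
            m_cuts = [int(round(f * L)) for f in _split_fractions(cfg.split_pieces)]
            for i in range(cfg.split_pieces):
                m0 = m_cuts[i] + 1 - (cfg.split_overlap if i > 0 else 0)
                m1 = m_cuts[i + 1]
                s0 = nl_len + (_first_offset(offsets, m_cuts[i] + 1) + 1)
                s1 = nl_len + (
                    _last_offset(offsets, m_cuts[i + 1]) + 1
                    if i < cfg.split_pieces - 1
                    else dom_len
                )
                pieces.append((s0, s1, m0, m1))
            # make sequence spans a disjoint partition
            fixed = []
            prev_end = nl_len
            for j, (s0, s1, m0, m1) in enumerate(pieces):
                s0 = max(s0, prev_end + 1)
                if j == len(pieces) - 1:
                    s1 = nl_len + dom_len
                fixed.append((s0, s1, m0, m1))
                prev_end = s1
            parts = [nl, dom, cl]
            for s0, s1, m0, m1 in fixed:
                covered = m1 - m0 + 1
                truth = SPLIT if covered < 0.5 * L else COMPLETE
                add(family.family_id, s0, s1, m0, m1, truth, "planted_split")
        else:  # UNBOUNDED or PUTATIVE (degraded complement)
            k = max(1, int(round(cfg.keep_fraction * L)))
            if k >= 0.5 * L:
                k = int(np.floor(0.5 * L - 1))
            if category == UNBOUNDED:
                m0, m1 = L - k + 1, L
                s0 = nl_len + _first_offset(offsets, m0) + 1
                s1 = nl_len + dom_len
                parts = [nl, dom, cl]
                add(family.family_id, s0, s1, m0, m1, UNBOUNDED, "planted_unbounded")
            else:
                m0, m1 = 1, k
                cut = (
                    _first_offset(offsets, k + 1)
                    if cfg.with_residues
                    else k
                )
                if cfg.with_residues:
                    kept = dom[:cut]
                    degraded = _random_residues(rng, dom_len - cut)
                    parts = [nl, kept + degraded, cl]
                else:
                    parts = [nl, dom, cl]
                add(
                    family.family_id,
                    nl_len + 1,
                    nl_len + cut,
                    m0,
                    m1,
                    PUTATIVE,
                    "planted_degraded_half",
                )
    elif category == BOUNDED + ":terminus":
        k = max(1, int(round(0.4 * L)))
        m0 = L - k + 1
        cut = _first_offset(offsets, m0) if cfg.with_residues else m0 - 1
        tail_len = dom_len - cut
        nl2 = int(rng.integers(0, 6))
        budget = int(0.85 * L) - tail_len - nl2
        cl2 = max(0, min(budget, int(rng.integers(5, 16))))
        parts = [linker(nl2), dom[cut:] if cfg.with_residues else None, linker(cl2)]
        nl_len, dom_len, cl_len = nl2, tail_len, cl2
        add(
            family.family_id,
            nl2 + 1,
            nl2 + tail_len,
            m0,
            L,
            BOUNDED,
            "planted_bounded_terminus",
        )
    elif category == BOUNDED + ":neighbor":
        k = max(1, int(round(0.4 * L)))
        m0 = L - k + 1
        cut = _first_offset(offsets, m0) if cfg.with_residues else m0 - 1
        tail_len = dom_len - cut
        d1_fam, d1_cons = decoys[int(rng.integers(len(decoys)))]
        d2_fam, d2_cons = decoys[int(rng.integers(len(decoys)))]
        if cfg.with_residues:
            d1_dom, _ = _mutate_domain(d1_cons, p_sub, cfg.indel_rate, rng)
            d2_dom, _ = _mutate_domain(d2_cons, p_sub, cfg.indel_rate, rng)
            d1_len, d2_len = len(d1_dom), len(d2_dom)
        else:
            d1_dom = d2_dom = None
            d1_len, d2_len = d1_fam.model_length, d2_fam.model_length
        g1 = int(rng.integers(5, 16))
        g2 = int(rng.integers(5, 16))
        parts = [
            linker(nl_len),
            d1_dom,
            linker(g1),
            dom[cut:] if cfg.with_residues else None,
            linker(g2),
            d2_dom,
            linker(cl_len),
        ]
        p0 = nl_len
        add(d1_fam.family_id, p0 + 1, p0 + d1_len, 1, d1_fam.model_length, COMPLETE)
        p0 += d1_len + g1
        add(
            family.family_id,
            p0 + 1,
            p0 + tail_len,
            m0,
            L,
            BOUNDED,
            "planted_bounded_neighbor",
        )
        p0 += tail_len + g2
        add(d2_fam.family_id, p0 + 1, p0 + d2_len, 1, d2_fam.model_length, COMPLETE)
        dom_len = d1_len + g1 + tail_len + g2 + d2_len
    else:
        raise ValueError(f"unknown planted category {category!r}")

    total_len = (
        sum(len(p) for p in parts if p)
        if cfg.with_residues
        else nl_len + dom_len + cl_len
    )
    residues = "".join(p for p in parts if p) if cfg.with_residues else None
    return MemberRecord(
        seq_id=seq_id,
        length=total_len,
        residues=residues,
        annotations=anns,
        truths=truths,
    )


def generate_family(
    config: SimulationConfig,
    family_index: int,
    rng: np.random.Generator | None = None,
    decoys: Sequence[tuple[FamilyModel, str | None]] = (),
) -> FamilyBundle:
    """Generate one family: consensus, member proteins, planted annotations.

    The per-family planted counts of ``config`` are assigned to members in a
    seeded random order; remaining members are complete.  With
    ``with_residues=False`` only coordinates and tables are produced (fast
    path for classifier/enrichment simulations).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, family_index]))
    lo, hi = config.model_length_range
    L = int(rng.integers(lo, hi + 1))
    family = FamilyModel(f"FAM{family_index:05d}", L)
    consensus = _random_residues(rng, L) if config.with_residues else None
    if not decoys:
        decoys = _make_decoys(config, rng)

    categories = (
        [SPLIT] * config.n_split
        + [BOUNDED + ":terminus"] * config.n_bounded_terminus
        + [BOUNDED + ":neighbor"] * config.n_bounded_neighbor
        + [UNBOUNDED] * config.n_unbounded
        + [PUTATIVE] * config.n_degraded
        + [COMPLETE] * (config.members_per_family - config.planted_per_family())
    )
    categories = [categories[i] for i in rng.permutation(len(categories))]

    members = []
    for mi, cat in enumerate(categories):
        seq_id = f"F{family_index:03d}_M{mi:04d}"
        members.append(
            _build_member(seq_id, family, consensus, cat, config, rng, decoys)
        )
    return FamilyBundle(family=family, consensus=consensus, members=members)


def _make_decoys(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[FamilyModel, str | None]]:
    out = []
    lo, hi = config.decoy_model_length_range
    for di in range(max(1, config.n_decoy_families)):
        Ld = int(rng.integers(lo, hi + 1))
        fam = FamilyModel(f"DCY{di:05d}", Ld)
        cons = _random_residues(rng, Ld) if config.with_residues else None
        out.append((fam, cons))
    return out


def assign_taxa(
    bounded_seq_ids: Iterable[str],
    all_seq_ids: Iterable[str],
    odds_ratio: float,
    base_rate: float,
    seed: int,
) -> dict[str, bool]:
    """Eukaryote flags: bounded-partial sequences at ``odds_ratio`` times the
    base odds, everything else at ``base_rate``; ``odds_ratio=inf`` makes all
    bounded-partial sequences eukaryotic."""
    rng = np.random.default_rng(seed)
    bounded = set(bounded_seq_ids)
    base_odds = base_rate / (1.0 - base_rate)
    if np.isinf(odds_ratio):
        p_bounded = 1.0
    else:
        o = odds_ratio * base_odds
        p_bounded = o / (1.0 + o)
    flags = {}
    for seq_id in sorted(set(all_seq_ids)):
        p = p_bounded if seq_id in bounded else base_rate
        flags[seq_id] = bool(rng.random() < p)
    return flags


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Generate the full dataset: tables, optional residues, and truth records.

    The first ``n_enriched_families`` families are the taxon-enriched ones:
    their bounded-partial sequences receive eukaryote flags at
    ``enrichment_odds_ratio`` times the base odds.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    decoy_rng = np.random.default_rng(root.spawn(1)[0])
    # decoys are shared across families so neighbor plants reuse them
    decoys = _make_decoys(config, decoy_rng)

    families: dict[str, FamilyModel] = {f.family_id: f for f, _ in decoys}
    sequences: dict[str, SequenceMeta] = {}
    annotations: list[DomainAnnotation] = []
    residues: dict[str, str] = {}
    truth_rows: list[TruthRecord] = []
    member_lengths: dict[str, int] = {}
    enriched_bounded_seqs: set[str] = set()
    bounded_seqs: set[str] = set()

    for fi in range(config.n_families):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000 + fi]))
        bundle = generate_family(config, fi, rng=rng, decoys=decoys)
        families[bundle.family.family_id] = bundle.family
        enriched = fi < config.n_enriched_families
        for m in bundle.members:
            member_lengths[m.seq_id] = m.length
            annotations.extend(m.annotations)
            truth_rows.extend(m.truths)
            if config.with_residues:
                residues[m.seq_id] = m.residues
            if any(t.true_category == BOUNDED for t in m.truths):
                bounded_seqs.add(m.seq_id)
                if enriched:
                    enriched_bounded_seqs.add(m.seq_id)

    euk = assign_taxa(
        enriched_bounded_seqs,
        member_lengths.keys(),
        config.enrichment_odds_ratio,
        config.eukaryote_base_rate,
        seed=int(np.random.default_rng(root.spawn(2)[1]).integers(2**31)),
    )
    flag_rng = np.random.default_rng(root.spawn(3)[2])
    for seq_id in sorted(member_lengths):
        is_bounded = seq_id in bounded_seqs
        rev_rate = (
            config.reviewed_rate_bounded if is_bounded else config.reviewed_rate_nonpartial
        )
        reviewed = bool(flag_rng.random() < rev_rate)
        gm_rate = (
            config.gene_model_rate_reviewed if reviewed else config.gene_model_rate_unreviewed
        )
        has_gm = bool(flag_rng.random() < gm_rate)
        sequences[seq_id] = SequenceMeta(
            seq_id=seq_id,
            length=member_lengths[seq_id],
            is_fragment=False,
            is_eukaryote=euk[seq_id],
            reviewed=reviewed,
            has_gene_model=has_gm,
        )

    dataset = Dataset(
        families=families,
        sequences=sequences,
        annotations=annotations,
        residues=residues,
    )
    dataset.validate()
    truth = pd.DataFrame(
        [
            {
                "seq_id": t.seq_id,
                "family_id": t.family_id,
                "seq_start": t.seq_start,
                "seq_end": t.seq_end,
                "model_start": t.model_start,
                "model_end": t.model_end,
                "true_category": t.true_category,
                "provenance": t.provenance,
            }
            for t in truth_rows
        ],
        columns=[
            "seq_id",
            "family_id",
            "seq_start",
            "seq_end",
            "model_start",
            "model_end",
            "true_category",
            "provenance",
        ],
    )
    return SimulationResult(dataset=dataset, truth=truth, config=config)
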