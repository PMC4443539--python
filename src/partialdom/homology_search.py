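"""Extended-query local-alignment search with empirical E-value calibration.

Candidate unbounded partials are turned into extended queries (the full-model
projection, optionally padded), aligned against a protein database with
Smith-Waterman (BLOSUM62, affine gaps: a length-k gap costs ``open + k*extend``,
11 + k with the defaults), and scored statistically by fitting an extreme-value
(Gumbel) model to the bulk of the database score distribution — the same idea
the FASTA/SSEARCH programs use: true homologs sit in the top tail, so any
score the fit itself flags as a credible homolog is trimmed and the Gumbel is
refit to the remainder as a right-truncated sample, iterating until stable.

The putative-partial criterion then asks whether an extended query has many
significant homologs (>= 10 at E <= 1e-6) of which a substantial share
(>= 25%) align over less than half the family model — the signature of a
genuinely mobile sub-domain rather than an alignment artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation_core import FamilyModel
from .partial_classifier import ProjectedInterval

__all__ = [
    "AlignmentHit",
    "HomologSummary",
    "ExtendedQuery",
    "EValueCalibration",
    "CalibrationError",
    "MissingSequenceError",
    "extract_extended_query",
    "smith_waterman",
    "calibrate_evalues",
    "search_extended_queries",
    "summarize_homologs",
    "is_putative_partial",
    "shuffled_decoys",
]

DEFAULT_EVALUE_THRESHOLD = 1e-6
MIN_CALIBRATION_SCORES = 50


class CalibrationError(ValueError):
    """Too few database scores to fit the extreme-value model."""


class MissingSequenceError(KeyError):
    """Residues were requested for a seq_id absent from the FASTA input."""


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a database sequence."""

    query_id: str
    subject_id: str
    raw_score: float
    evalue: float
    identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_length: int

    def span_length(self, mode: str = "pairs") -> int:
        """Alignment length under a chosen convention.

        ``pairs``: aligned residue pairs (gap columns excluded, the default);
        ``query_span`` / ``subject_span``: end - start + 1 on that sequence.
        """
        if mode == "pairs":
            return self.aligned_length
        if mode == "query_span":
            return self.q_end - self.q_start + 1
        if mode == "subject_span":
            return self.s_end - self.s_start + 1
        raise ValueError(f"unknown alignment-length mode {mode!r}")


@dataclass(frozen=True)
class HomologSummary:
    """Counts of significant and short-aligning homologs for one query."""

    query_id: str
    n_significant: int
    n_short: int

    @property
    def short_fraction(self) -> float | None:
        if self.n_significant == 0:
            return None
        return self.n_short / self.n_significant


@dataclass(frozen=True)
class ExtendedQuery:
    """Residues of a projected (optionally padded) region, with coordinates."""

    seq_id: str
    start: int  # 1-based inclusive on the source sequence
    end: int
    residues: str


def extract_extended_query(
    sequence_residues: Mapping[str, str],
    projection: ProjectedInterval,
    pad: int = 0,
) -> ExtendedQuery:
    """Cut the projected full-model region (plus ``pad`` residues each side)
    out of the source sequence, clipped to the sequence ends."""
    try:
        seq = sequence_residues[projection.seq_id]
    except KeyError:
        raise MissingSequenceError(
            f"no residues available for {projection.seq_id!r}"
        ) from None
    start = max(1, projection.proj_start - pad)
    end = min(len(seq), projection.proj_end + pad)
    return ExtendedQuery(
        seq_id=projection.seq_id, start=start, end=end, residues=seq[start - 1 : end]
    )


def _make_aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # length-k gap costs gap_open + k*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Best local alignment under affine gap costs, or None if nothing scores > 0."""
    if not query or not subject:
        return None
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    q_blocks, s_blocks = aln.aligned
    pairs = 0
    identical = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        pairs += qe - qs
        for i in range(qe - qs):
            if query[qs + i] == subject[ss + i]:
                identical += 1
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(score),
        evalue=float("nan"),
        identity=identical / pairs if pairs else 0.0,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
        aligned_length=pairs,
    )


@dataclass(frozen=True)
class EValueCalibration:
    """Fitted Gumbel survival model for database search scores.

    The expected score grows linearly in log subject length (slope
    ``length_slope``); the length-adjusted scores follow a Gumbel law with
    location ``loc`` and scale ``scale``.  ``evalue`` scales the per-subject
    tail probability by the database size.
    """

    loc: float
    scale: float
    length_slope: float
    mean_log_length: float
    db_size: int

    def adjusted(self, score: float, subject_length: int) -> float:
        return score - self.length_slope * (np.log(subject_length) - self.mean_log_length)

    def evalue(self, score: float, subject_length: int) -> float:
        s = self.adjusted(score, subject_length)
        return float(self.db_size * stats.gumbel_r.sf(s, loc=self.loc, scale=self.scale))


def _fit_gumbel_truncated(kept: np.ndarray, threshold: float) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit to a right-truncated sample.

    The kept scores are modeled as null draws conditioned on falling below
    ``threshold``; the trimmed-away top scores are simply not part of the
    sample (they are suspected homologs, so no claim is made about how much
    null mass lies above the threshold — right-censoring would wrongly force
    the null to account for them).
    """
    scale_mom = max(float(np.std(kept) * np.sqrt(6) / np.pi), 1e-6)
    loc0 = float(np.mean(kept) - 0.5772 * scale_mom)

    def nll(params: np.ndarray) -> float:
        loc, log_scale = params
        scale = np.exp(log_scale)
        ll = np.sum(stats.gumbel_r.logpdf(kept, loc=loc, scale=scale))
        ll -= kept.size * stats.gumbel_r.logcdf(threshold, loc=loc, scale=scale)
        return -ll

    res = optimize.minimize(nll, x0=[loc0, np.log(scale_mom)], method="Nelder-Mead")
    loc, log_scale = res.x
    return float(loc), float(np.exp(log_scale))


def calibrate_evalues(
    all_scores: Sequence[float],
    subject_lengths: Sequence[int],
    db_size: int,
    outlier_evalue: float = 0.01,
    max_iter: int = 10,
) -> EValueCalibration:
    """Fit the E-value model from one search's database score distribution.

    A linear regression of score on log subject length (lower 75% of scores,
    so homologs do not leverage the slope) removes the length dependence.
    The adjusted scores are then fit to a Gumbel law, excluding suspected
    true homologs: starting from robust quantile estimates, any score the
    current fit deems a credible homolog (E < ``outlier_evalue``) is trimmed
    and the law is refit to the remainder by right-truncated maximum
    likelihood, iterating until the trimmed set is stable.  When nothing is
    trimmed the fit is plain maximum likelihood on the full sample —
    otherwise a database rich in true homologs would corrupt its own null
    model, while needless trimming on a null database degrades the tail fit.
    Requires at least 50 scores; augment a small database with shuffled
    decoys (:func:`shuffled_decoys`) if necessary.
    """
    scores = np.asarray(all_scores, dtype=float)
    lengths = np.asarray(subject_lengths, dtype=float)
    if scores.size < MIN_CALIBRATION_SCORES:
        raise CalibrationError(
            f"need >= {MIN_CALIBRATION_SCORES} database scores to calibrate "
            f"(got {scores.size}); augment the database with shuffled decoys"
        )
    log_len = np.log(lengths)
    mean_log_length = float(np.mean(log_len))
    order = np.argsort(scores)
    bulk = order[: int(np.floor(scores.size * 0.75))]
    if np.ptp(log_len[bulk]) > 1e-9:
        slope = float(np.polyfit(log_len[bulk], scores[bulk], 1)[0])
    else:
        slope = 0.0
    adjusted = np.sort(scores - slope * (log_len - mean_log_length))
    n = adjusted.size

    # robust initial parameters from the 25th/50th percentiles
    q25, q50 = np.percentile(adjusted, [25, 50])
    scale = max((q50 - q25) / 0.69315, 1e-6)  # ln(ln4) - ln(ln2)
    loc = q25 + 0.32663 * scale

    n_excl = -1
    for _ in range(max_iter):
        surv = stats.gumbel_r.sf(adjusted, loc=loc, scale=scale)
        outliers = int(np.sum(db_size * surv < outlier_evalue))
        new_excl = min(max(n_excl, outliers), n - MIN_CALIBRATION_SCORES // 2)
        if new_excl == 0:
            loc, scale = stats.gumbel_r.fit(adjusted)
        else:
            kept = adjusted[: n - new_excl]
            loc, scale = _fit_gumbel_truncated(kept, adjusted[n - new_excl])
        if new_excl == n_excl:
            break
        n_excl = new_excl
    return EValueCalibration(
        loc=loc,
        scale=scale,
        length_slope=slope,
        mean_log_length=mean_log_length,
        db_size=db_size,
    )


def shuffled_decoys(
    residues: Mapping[str, str], n: int, seed: int, prefix: str = "decoy"
) -> dict[str, str]:
    """Shuffled copies of database sequences: same composition, no homology."""
    rng = np.random.default_rng(seed)
    ids = sorted(residues)
    out: dict[str, str] = {}
    for i in range(n):
        src = residues[ids[int(rng.integers(len(ids)))]]
        chars = np.array(list(src))
        rng.shuffle(chars)
        out[f"{prefix}{i:05d}"] = "".join(chars)
    return out


def search_extended_queries(
    queries: Sequence[ExtendedQuery],
    database: Mapping[str, str],
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> dict[str, list[AlignmentHit]]:
    """Search each extended query against the database.

    E-values are calibrated per query from that query's own database score
    distribution.  Self-hits (subject seq_id equal to the query's source
    seq_id) are excluded; significant hits (E <= threshold) are returned
    sorted by E-value.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    subject_ids = sorted(database)
    lengths = [len(database[s]) for s in subject_ids]
    results: dict[str, list[AlignmentHit]] = {}
    for q in queries:
        scores = np.array(
            [aligner.score(q.residues, database[s]) if database[s] else 0.0 for s in subject_ids]
        )
        calib = calibrate_evalues(scores, lengths, db_size=len(subject_ids))
        hits: list[AlignmentHit] = []
        for s_id, score, length in zip(subject_ids, scores, lengths):
            if s_id == q.seq_id or score <= 0:
                continue
            ev = calib.evalue(score, length)
            if ev <= threshold:
                hit = smith_waterman(
                    q.residues,
                    database[s_id],
                    matrix=matrix,
                    gap_open=gap_open,
                    gap_extend=gap_extend,
                    query_id=q.seq_id,
                    subject_id=s_id,
                )
                if hit is not None:
                    hits.append(
                        AlignmentHit(
                            **{**hit.__dict__, "evalue": ev}
                        )
                    )
        hits.sort(key=lambda h: (h.evalue, h.subject_id))
        results[q.seq_id] = hits
    return results


def summarize_homologs(
    hits: Sequence[AlignmentHit],
    family: FamilyModel,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
    length_mode: str = "pairs",
) -> HomologSummary:
    """Count significant homologs and those aligning over less than half the model."""
    significant = [h for h in hits if h.evalue <= threshold]
    half = 0.5 * family.model_length
    n_short = sum(1 for h in significant if h.span_length(length_mode) < half)
    query_id = hits[0].query_id if hits else ""
    return HomologSummary(
        query_id=query_id, n_significant=len(significant), n_short=n_short
    )


def is_putative_partial(
    summary: HomologSummary,
    min_homologs: int = 10,
    min_short_fraction: float = 0.25,
) -> bool:
    """True iff the query has >= min_homologs significant homologs and the
    short-alignment share is >= min_short_fraction (both boundaries inclusive)."""
    if summary.n_significant < min_homologs:
        return False
    return summary.short_fraction >= min_short_fraction
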