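"""Shared fixtures: small hand-built datasets and deterministic RNGs."""

from __future__ import annotations

import numpy as np
import pytest

from partialdom.annotation_core import (
    Dataset,
    DomainAnnotation,
    FamilyModel,
    SequenceMeta,
)


def make_dataset(families, sequences, annotations, residues=None) -> Dataset:
    """Build a Dataset from terse tuples.

    families: (family_id, model_length[, clan_id])
    sequences: (seq_id, length[, is_fragment, is_eukaryote, reviewed, has_gene_model])
    annotations: (seq_id, family_id, seq_start, seq_end, model_start, model_end[, in_full])
    """
    fams = {}
    for f in families:
        fams[f[0]] = FamilyModel(f[0], f[1], f[2] if len(f) > 2 else None)
    seqs = {}
    for s in sequences:
        flags = list(s[2:]) + [False] * (4 - len(s[2:]))
        seqs[s[0]] = SequenceMeta(s[0], s[1], *flags)
    anns = [
        DomainAnnotation(a[0], a[1], a[2], a[3], a[4], a[5], a[6] if len(a) > 6 else True)
        for a in annotations
    ]
    ds = Dataset(families=fams, sequences=seqs, annotations=anns, residues=residues or {})
    ds.validate()
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cora_like_dataset():
    """One 292-state family with the worked single-annotation geometry:
    a 141-residue cation-transporter-like protein carrying match states
    167-292 of a 292-state model."""
    return make_dataset(
        families=[("PF01544", 292)],
        sequences=[("Q7U9V6", 141)],
        annotations=[("Q7U9V6", "PF01544", 10, 135, 167, 292)],
    )
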