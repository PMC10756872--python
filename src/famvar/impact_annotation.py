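"""Per-variant tolerance and conservation evidence.

LOEUF (loss-of-function observed/expected upper bound fraction) is joined
from a gene-keyed table and reported with a qualitative constraint flag at
LOEUF < 1; it never gates retention. SIFT/PolyPhen calls are summarized to
the compact per-transcript strings used in the candidate table. Ortholog
conservation at the mutated residue is scored from an aligned FASTA: the
human residue position is mapped to its alignment column and the fraction
of non-gap ortholog residues identical to the human residue is computed.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .types import (
    CohortError,
    ConservationAssessment,
    POLYPHEN_LABELS,
    SIFT_LABELS,
    VariantRecord,
)

GAP_CHARS = {"-", "."}

#: LOEUF below this marks reportable loss-of-function constraint evidence.
CONSTRAINT_LOEUF = 1.0


def annotate_tolerance(
    variants: Sequence[VariantRecord], loeuf_table: Mapping[str, float]
) -> tuple[list[VariantRecord], dict[str, bool]]:
    """Join LOEUF scores onto variants by gene symbol.

    Returns the annotated records plus a per-gene constraint flag
    (LOEUF < 1). Genes absent from the table keep a missing score and no
    flag; they are never dropped.
    """
    for gene, score in loeuf_table.items():
        if score < 0:
            raise CohortError(f"negative LOEUF score {score} for {gene}")
    annotated = []
    flags: dict[str, bool] = {}
    for v in variants:
        score = loeuf_table.get(v.gene.upper())
        annotated.append(v.with_loeuf(score) if score is not None else v)
        flags[v.gene] = score is not None and score < CONSTRAINT_LOEUF
    return annotated, flags


def summarize_predictions(variant: VariantRecord) -> dict[str, str]:
    """Compact per-tool strings, per-transcript order preserved; "--" when
    a tool made no call. Unknown labels are rejected."""
    for call in variant.sift_calls:
        if call not in SIFT_LABELS:
            raise CohortError(f"unknown SIFT label {call!r}")
    for call in variant.polyphen_calls:
        if call not in POLYPHEN_LABELS:
            raise CohortError(f"unknown PolyPhen label {call!r}")
    return {
        "sift": ", ".join(variant.sift_calls) if variant.sift_calls else "--",
        "polyphen": ", ".join(variant.polyphen_calls) if variant.polyphen_calls else "--",
    }


def _human_column(human_seq: str, residue_position: int) -> int:
    """1-based alignment column of the ``residue_position``-th (1-based)
    non-gap character of the human row."""
    count = 0
    for col, ch in enumerate(human_seq, start=1):
        if ch not in GAP_CHARS:
            count += 1
            if count == residue_position:
                return col
    raise CohortError(
        f"residue position {residue_position} beyond ungapped human length {count}"
    )


def conservation_score(
    alignment: MultipleSeqAlignment | str | os.PathLike,
    human_id: str,
    residue_position: int,
    gene: str = "",
    threshold: float = 0.8,
) -> ConservationAssessment:
    """Fraction of ortholog sequences matching the human residue at an
    alignment column, gaps excluded from the denominator.

    ``alignment`` may be a Biopython alignment or a path to an aligned
    FASTA containing the human sequence under ``human_id``.
    """
    if not isinstance(alignment, MultipleSeqAlignment):
        alignment = AlignIO.read(str(alignment), "fasta")
    human = None
    for rec in alignment:
        if rec.id == human_id:
            human = str(rec.seq)
            break
    if human is None:
        raise CohortError(f"human sequence {human_id!r} absent from alignment")
    column = _human_column(human, residue_position)
    residue = human[column - 1].upper()
    matches = 0
    total = 0
    for rec in alignment:
        if rec.id == human_id:
            continue
        ch = str(rec.seq[column - 1]).upper()
        if ch in GAP_CHARS:
            continue
        total += 1
        matches += ch == residue
    fraction = matches / total if total else 0.0
    return ConservationAssessment(
        gene=gene,
        residue_position=residue_position,
        column=column,
        human_residue=residue,
        fraction_identical=fraction,
        conserved=fraction >= threshold,
        threshold=threshold,
    )
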