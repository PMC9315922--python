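"""Germline alignment and nucleotide mutation calling.

The paper's consortia received IMGT pre-aligned rearrangements, so the
recommended path here is pre-aligned equal-length gapped strings which pass
straight through.  A global pairwise alignment (Biopython) is provided for
raw input.  Mutations are nucleotide substitutions at aligned positions
where both bases are unambiguous; indels and N-masked columns contribute
neither to the mutation count nor to the compared length.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio import Align

from .records import BASES, GAP_CHARS, SequenceRecord

MIN_COMPARED_DEFAULT = 60


class MutationStatus(str, enum.Enum):
    """Classical two-way IGHV mutation status at the 2% germline cutoff."""

    UNMUTATED_LT2 = "UNMUTATED_LT2"  # U-CLL: < cutoff % difference
    MUTATED_GE2 = "MUTATED_GE2"  # M-CLL: >= cutoff % difference


@dataclass
class StatusParams:
    percent_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.percent_cutoff < 100:
            raise ValueError("percent_cutoff must be in (0, 100)")


@dataclass
class GermlinePair:
    """An aligned patient/germline sequence pair.

    ``compared_length`` counts aligned columns where both characters are
    unambiguous bases — the denominator of percent difference.
    """

    patient_id: str
    aligned_patient: str
    aligned_germline: str
    frame_offset: int = 0
    compared_length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_patient) != len(self.aligned_germline):
            raise ValueError(
                f"{self.patient_id}: aligned strings differ in length "
                f"({len(self.aligned_patient)} vs {len(self.aligned_germline)})"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.patient_id}: frame_offset must be 0, 1 or 2")
        self.compared_length = sum(
            1
            for p, g in zip(self.aligned_patient, self.aligned_germline)
            if p in BASES and g in BASES
        )


@dataclass
class NtMutationSite:
    """One nucleotide substitution with its germline codon context.

    Codon coordinates are in the *ungapped germline* frame; sites falling
    before the reading-frame offset or in an incomplete trailing codon have
    ``germline_codon=None`` and are excluded from S/Rc/Rnc typing (but still
    count toward percent difference).
    """

    alignment_pos: int
    germline_base: str
    observed_base: str
    codon_index: int | None = None
    pos_in_codon: int | None = None
    germline_codon: str | None = None
    observed_codon: str | None = None


def align_pair(
    patient: SequenceRecord,
    germline: SequenceRecord,
    min_compared: int = MIN_COMPARED_DEFAULT,
) -> GermlinePair:
    """Pair a patient sequence with its germline.

    Pre-aligned records pass through unchanged.  Otherwise a global
    alignment is computed (match +2, mismatch -1, gap open -6, gap extend
    -1; Biopython's first reported alignment gives a deterministic
    leftmost-gap tie-break).
    """
    if not patient.nt_sequence or not germline.nt_sequence:
        raise ValueError(f"{patient.id}: empty sequence")
    if patient.is_prealigned:
        pair = GermlinePair(
            patient_id=patient.id,
            aligned_patient=patient.nt_sequence,
            aligned_germline=patient.germline_alignment,
            frame_offset=patient.reading_frame_offset,
        )
    else:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -6
        aligner.extend_gap_score = -1
        aln = aligner.align(patient.ungapped, germline.ungapped)[0]
        pair = GermlinePair(
            patient_id=patient.id,
            aligned_patient=str(aln[0]),
            aligned_germline=str(aln[1]),
            frame_offset=patient.reading_frame_offset,
        )
    if pair.compared_length < min_compared:
        raise ValueError(
            f"{patient.id}: insufficient overlap "
            f"({pair.compared_length} < {min_compared} compared positions)"
        )
    return pair


def call_mutations(pair: GermlinePair) -> list[NtMutationSite]:
    """Enumerate nucleotide substitutions in alignment order.

    A site is called where both the germline and patient characters are in
    {A,C,G,T} and differ; gapped or N columns are skipped.  Codon context is
    attached in ungapped-germline coordinates using the frame offset.
    """
    germ_ungapped = "".join(c for c in pair.aligned_germline if c not in GAP_CHARS)
    # patient character aligned over each ungapped germline position
    patient_at_gpos = [
        p for p, g in zip(pair.aligned_patient, pair.aligned_germline) if g not in GAP_CHARS
    ]
    n_codons = (len(germ_ungapped) - pair.frame_offset) // 3

    sites: list[NtMutationSite] = []
    gpos = -1
    for apos, (p, g) in enumerate(zip(pair.aligned_patient, pair.aligned_germline)):
        if g not in GAP_CHARS:
            gpos += 1
        if g not in BASES or p not in BASES or p == g:
            continue
        site = NtMutationSite(
            alignment_pos=apos, germline_base=g, observed_base=p
        )
        rel = gpos - pair.frame_offset
        if rel >= 0 and rel // 3 < n_codons:
            ci, pc = divmod(rel, 3)
            start = pair.frame_offset + 3 * ci
            site.codon_index = ci
            site.pos_in_codon = pc
            site.germline_codon = germ_ungapped[start : start + 3]
            obs = patient_at_gpos[start : start + 3]
            site.observed_codon = (
                "".join(obs) if all(c in BASES for c in obs) else None
            )
        sites.append(site)
    return sites


def percent_difference(pair: GermlinePair) -> float:
    """Percent nucleotide difference from germline over compared positions."""
    if pair.compared_length == 0:
        raise ValueError(f"{pair.patient_id}: no compared positions")
    return 100.0 * len(call_mutations(pair)) / pair.compared_length


def mutation_status(pct: float, params: StatusParams | None = None) -> MutationStatus:
    """Two-way status: < cutoff -> U-CLL-like; >= cutoff -> M-CLL-like.

    The boundary value (exactly 2.0% by default) belongs to the mutated
    (>= 2%) category.
    """
    params = params or StatusParams()
    if pct < 0:
        raise ValueError("percent difference cannot be negative")
    if pct < params.percent_cutoff:
        return MutationStatus.UNMUTATED_LT2
    return MutationStatus.MUTATED_GE2
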