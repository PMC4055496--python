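"""COI barcode species assignment.

A query amplicon is assigned to the reference species (or congener
group) with the highest pairwise sequence identity, mirroring the
BOLD-style workflow: an identification requires >= 99.5% identity; exact
cross-group ties are reported as ambiguous; a sub-threshold best hit
whose runner-up is *not* the best hit's nearest relative indicates DNA
from more than one species (a mixed-composition product).  Replicate
extractions of the same sample are reconciled into a final call.

Identity conventions
--------------------
Queries are fixed-region (~655 bp) COI amplicons.  Equal-length
sequences are compared position by position (the region itself defines
the homology).  Unequal-length pairs are aligned semi-globally (free
end gaps; match +1, mismatch -1, gap -2) and identity is the fraction
of matched columns among aligned columns, excluding terminal-gap
columns; internal gap columns count as mismatches and N matches
nothing.  Queries are checked in both orientations and the better one
is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from . import taxa
from .tree import encode, p_distance

__all__ = [
    "PairwiseAlignment",
    "PanelRecord",
    "ReferencePanel",
    "SpeciesAssignment",
    "ReconciledID",
    "align_pair",
    "pairwise_identity",
    "percent_identity",
    "assign_species",
    "detect_mixed",
    "reconcile_replicates",
    "reverse_complement",
    "derive_sister_map",
]

IDENTITY_THRESHOLD = 0.995

_IUPAC = set("ACGTRYSWKMBDHVN")
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _check_sequence(seq: str, what: str) -> str:
    if not seq:
        raise ValueError(f"{what} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"{what} sequence contains non-IUPAC characters: {sorted(bad)}")
    return seq


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps (semi-global); attribute names changed in Biopython 1.88
    try:
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # pragma: no cover - older Biopython
        aligner.target_end_open_gap_score = 0
        aligner.target_end_extend_gap_score = 0
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A pairwise alignment as two gapped strings plus its score."""

    query_aligned: str
    ref_aligned: str
    score: float


def align_pair(query: str, reference: str) -> PairwiseAlignment:
    """Semi-global alignment (free end gaps; +1/-1/-2 scoring).

    Co-optimal alignments are resolved by the aligner's deterministic
    enumeration order, so repeated calls always return the same path.
    """
    query = _check_sequence(query, "query")
    reference = _check_sequence(reference, "reference")
    result = _ALIGNER.align(query, reference)
    best = result[0]
    return PairwiseAlignment(str(best[0]), str(best[1]), float(result.score))


def pairwise_identity(alignment: PairwiseAlignment) -> float:
    """Matched positions / aligned columns, excluding terminal gaps.

    Internal gap columns count as mismatches; N matches nothing.
    Raises if no non-terminal columns remain.
    """
    a, b = alignment.query_aligned, alignment.ref_aligned
    lo, hi = 0, len(a)
    while lo < hi and (a[lo] == "-" or b[lo] == "-"):
        lo += 1
    while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
        hi -= 1
    n_cols = hi - lo
    if n_cols == 0:
        raise ValueError("alignment has no non-terminal columns")
    matches = sum(
        1
        for x, y in zip(a[lo:hi], b[lo:hi])
        if x == y and x in "ACGT"
    )
    return matches / n_cols


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Pairwise identity between two sequences.

    Equal-length sequences are compared gaplessly (fixed-region
    amplicons are positionally homologous); otherwise they are aligned
    semi-globally first.
    """
    if len(seq_a) == len(seq_b):
        a, b = encode(seq_a), encode(seq_b)
        if len(a) == 0:
            raise ValueError("empty sequence")
        return float(((a == b) & (a < 4)).sum()) / len(a)
    try:
        return pairwise_identity(align_pair(seq_a, seq_b))
    except ValueError as exc:
        if "non-terminal" in str(exc):
            # optimal alignment leaves the sequences disjoint: no
            # detectable homologous overlap, identity 0
            return 0.0
        raise


@dataclass(frozen=True)
class PanelRecord:
    record_id: str
    species: str
    group: str
    sequence: str


class ReferencePanel:
    """Species-labelled COI reference sequences with congener groups.

    ``sister_map`` maps each species to its nearest-relative species
    within the panel (outside its own group); it drives mixed-sample
    detection.
    """

    def __init__(
        self,
        records: Sequence[PanelRecord],
        species_groups: Mapping[str, Iterable[str]] | None = None,
        sister_map: Mapping[str, str] | None = None,
    ):
        if not records:
            raise ValueError("reference panel is empty")
        self.records = list(records)
        for rec in self.records:
            _check_sequence(rec.sequence, f"reference {rec.record_id}")
        if species_groups is None:
            species_groups = {}
            for rec in self.records:
                species_groups.setdefault(rec.group, set()).add(rec.species)
        self.species_groups = {g: frozenset(m) for g, m in species_groups.items()}
        self._species_to_group = {
            sp: g for g, members in self.species_groups.items() for sp in members
        }
        self.sister_map = dict(sister_map) if sister_map is not None else derive_sister_map(self)
        lengths = {len(rec.sequence) for rec in self.records}
        self._uniform_length = lengths.pop() if len(lengths) == 1 else None
        self._matrix = (
            np.stack([encode(rec.sequence) for rec in self.records])
            if self._uniform_length
            else None
        )

    def __len__(self) -> int:
        return len(self.records)

    def group_of(self, species: str) -> str:
        return self._species_to_group[taxa.canonical_species(species)]

    def record_for_species(self, species: str) -> PanelRecord:
        species = taxa.canonical_species(species)
        for rec in self.records:
            if rec.species == species:
                return rec
        raise KeyError(species)

    @property
    def species(self) -> list[str]:
        return [rec.species for rec in self.records]

    # -- FASTA round trip (header convention: >refID|Genus_species|groupID)
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.record_id}|{rec.species.replace(' ', '_')}|{rec.group}\n")
                seq = rec.sequence
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path, sister_map: Mapping[str, str] | None = None) -> "ReferencePanel":
        records = []
        header, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if header is not None:
                        records.append(cls._record_from(header, "".join(chunks)))
                    header, chunks = line[1:], []
                else:
                    chunks.append(line)
        if header is not None:
            records.append(cls._record_from(header, "".join(chunks)))
        return cls(records, sister_map=sister_map)

    @staticmethod
    def _record_from(header: str, seq: str) -> PanelRecord:
        try:
            record_id, species, group = header.split("|")
        except ValueError as exc:
            raise ValueError(
                f"reference header {header!r} is not 'refID|Genus_species|groupID'"
            ) from exc
        return PanelRecord(record_id, species.replace("_", " "), group, seq)


def derive_sister_map(panel: ReferencePanel) -> dict[str, str]:
    """Nearest other-group species for every panel species.

    Distances are p-distances for uniform-length panels, otherwise
    1 - identity.  Ties go to the alphabetically first species.
    """
    out: dict[str, str] = {}
    for rec in panel.records:
        best: tuple[float, str] | None = None
        for other in panel.records:
            if other.group == rec.group:
                continue
            if len(other.sequence) == len(rec.sequence):
                d = p_distance(rec.sequence, other.sequence)
            else:
                d = 1.0 - percent_identity(rec.sequence, other.sequence)
            cand = (d, other.species)
            if best is None or cand < best:
                best = cand
        if best is not None:
            out[rec.species] = best[1]
    return out


@dataclass(frozen=True)
class SpeciesAssignment:
    """Best-identity match of one query against the panel."""

    query_id: str
    best_group: frozenset[str]
    best_species: str
    best_identity: float
    runner_up_species: str | None
    runner_up_identity: float | None
    runner_up_group: str | None
    status: str  # UNAMBIGUOUS | AMBIGUOUS_GROUP | BELOW_THRESHOLD
    orientation: str = "forward"


def _identities(query: str, panel: ReferencePanel) -> np.ndarray:
    if panel._uniform_length is not None and panel._uniform_length == len(query):
        q = encode(query)
        return ((panel._matrix == q) & (q < 4)).sum(axis=1) / len(q)
    return np.array([percent_identity(query, rec.sequence) for rec in panel.records])


def assign_species(
    query: str,
    panel: ReferencePanel,
    threshold: float = IDENTITY_THRESHOLD,
    query_id: str = "query",
    check_orientation: bool = True,
) -> SpeciesAssignment:
    """Assign a query to the reference group with highest identity.

    If two or more references from *different* groups tie exactly at the
    best identity the union of tied groups is reported with status
    AMBIGUOUS_GROUP.  A best identity below ``threshold`` yields status
    BELOW_THRESHOLD.  The runner-up is the best hit outside the winning
    group(s).
    """
    query = _check_sequence(query, "query")
    idents = _identities(query, panel)
    orientation = "forward"
    if check_orientation:
        rc = reverse_complement(query)
        rc_idents = _identities(rc, panel)
        if rc_idents.max() > idents.max():
            idents, orientation = rc_idents, "reverse"
    best_identity = float(idents.max())
    tied = [panel.records[i] for i in np.flatnonzero(idents == idents.max())]
    winning_groups = frozenset(rec.group for rec in tied)
    best_species = tied[0].species

    runner_species = runner_identity = runner_group = None
    mask = np.array([rec.group not in winning_groups for rec in panel.records])
    if mask.any():
        sub = np.where(mask, idents, -1.0)
        j = int(sub.argmax())
        runner_species = panel.records[j].species
        runner_identity = float(idents[j])
        runner_group = panel.records[j].group

    if best_identity < threshold:
        status = "BELOW_THRESHOLD"
    elif len(winning_groups) > 1:
        status = "AMBIGUOUS_GROUP"
    else:
        status = "UNAMBIGUOUS"
    return SpeciesAssignment(
        query_id=query_id,
        best_group=winning_groups,
        best_species=best_species,
        best_identity=best_identity,
        runner_up_species=runner_species,
        runner_up_identity=runner_identity,
        runner_up_group=runner_group,
        status=status,
        orientation=orientation,
    )


def detect_mixed(assignment: SpeciesAssignment, panel: ReferencePanel) -> bool:
    """Mixed-template signature: sub-threshold best hit whose runner-up
    is not the best hit's nearest relative.

    Only meaningful for BELOW_THRESHOLD assignments; anything at or
    above the identity threshold returns False.
    """
    if assignment.status != "BELOW_THRESHOLD":
        return False
    if assignment.runner_up_species is None:
        return False
    try:
        sister = panel.sister_map[assignment.best_species]
    except KeyError:
        raise KeyError(
            f"species {assignment.best_species!r} missing from sister map"
        ) from None
    return taxa.canonical_species(assignment.runner_up_species) != taxa.canonical_species(sister)


@dataclass(frozen=True)
class ReconciledID:
    """Final per-sample identification from replicate extractions.

    ``kind`` is GROUP (single group), MIXED (>= 2 groups), AMBIGUOUS
    (exact cross-group tie) or UNRESOLVED.
    """

    sample_id: str
    kind: str
    groups: frozenset[str]
    notes: tuple[str, ...] = ()

    @property
    def group(self) -> str:
        if self.kind != "GROUP":
            raise ValueError(f"no single group for kind={self.kind}")
        (g,) = self.groups
        return g


def reconcile_replicates(
    sample_id: str,
    rep1: SpeciesAssignment | None,
    rep2: SpeciesAssignment | None,
    mixed_flags: tuple[bool, bool] = (False, False),
) -> ReconciledID:
    """Combine two replicate assignments into a final identification.

    Rules: agreeing replicates with no mixed flag keep their group;
    disagreeing groups -> MIXED over both; any mixed flag -> MIXED over
    the flagged replicate's best and runner-up groups; a single
    available replicate stands alone (tagged); none -> UNRESOLVED.
    """
    reps = [(rep1, mixed_flags[0]), (rep2, mixed_flags[1])]
    present = [(a, f) for a, f in reps if a is not None]
    if not present:
        return ReconciledID(sample_id, "UNRESOLVED", frozenset(), ("no replicates",))

    notes: list[str] = []
    if len(present) == 1:
        notes.append("single-replicate")

    for assignment, flagged in present:
        if flagged:
            groups = set(assignment.best_group)
            if assignment.runner_up_group is not None:
                groups.add(assignment.runner_up_group)
            notes.append("mixed-signature")
            return ReconciledID(sample_id, "MIXED", frozenset(groups), tuple(notes))

    group_sets = [assignment.best_group for assignment, _ in present]
    common = frozenset.intersection(*group_sets)
    if not common:
        union = frozenset().union(*group_sets)
        notes.append("replicate-disagreement")
        return ReconciledID(sample_id, "MIXED", union, tuple(notes))
    if len(common) == 1:
        return ReconciledID(sample_id, "GROUP", common, tuple(notes))
    notes.append("congeneric-tie")
    return ReconciledID(sample_id, "AMBIGUOUS", common, tuple(notes))
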