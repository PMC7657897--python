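"""Residue-diagnostic classification of carbamoyl-phosphate synthetase sequences.

Teleost CPS III channels the amide nitrogen of glutamine through a
Cys-His-Glu catalytic triad in its glutamine amidotransferase (GAT)
domain, and binds glutamine with two further conserved residues.
Terrestrial-vertebrate CPS I has lost glutamine use (the catalytic Cys,
or both glutamine-binding residues) and runs on free ammonia; an
intermediate configuration — intact triad, one glutamine-binding residue
lost — weakens glutamine affinity and shifts the enzyme toward ammonia
while retaining some glutamine capacity, the state found in Alcolapia
CPS III.

This module maps reference-anchored diagnostic positions through a
protein alignment, reads off each sequence's residue states and applies
the deterministic decision table:

======================  =================  ==============================
catalytic triad         gln-binding pair   functional class
======================  =================  ==============================
all match               both match         GLN_UTILIZING
all match               one divergent      INTERMEDIATE_AMMONIA_PREFERRING
any divergent           (any)              AMMONIA_OBLIGATE
all match               both divergent     AMMONIA_OBLIGATE
any gap at any diagnostic position         INDETERMINATE
======================  =================  ==============================

A gap cannot distinguish loss from missing data, so it short-circuits to
INDETERMINATE. ``X`` counts as divergent (an unknown residue cannot
confirm a match) and is flagged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from cpscan.io_formats import Msa, SeqRecord


class FunctionalClass(str, enum.Enum):
    GLN_UTILIZING = "GLN_UTILIZING"
    INTERMEDIATE_AMMONIA_PREFERRING = "INTERMEDIATE_AMMONIA_PREFERRING"
    AMMONIA_OBLIGATE = "AMMONIA_OBLIGATE"
    INDETERMINATE = "INDETERMINATE"


class State(str, enum.Enum):
    MATCH = "match"
    DIVERGENT = "divergent"
    GAP = "gap"


@dataclass(frozen=True)
class DiagnosticResidue:
    """One diagnostic position: name, 1-based ungapped position on the
    reference, and the expected residue letter."""

    name: str
    position: int
    expected: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if len(self.expected) != 1:
            raise ValueError("expected residue must be a single letter")


@dataclass
class DiagnosticSpec:
    """Reference-anchored diagnostic positions for CPS classification.

    ``triad`` holds the Cys/His/Glu catalytic triad, ``gln_binding`` the
    two glutamine-binding residues; ``window`` optionally bounds the
    region of interest in reference numbering.
    """

    ref_id: str
    triad: list[DiagnosticResidue]
    gln_binding: list[DiagnosticResidue]
    window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.triad) != 3:
            raise ValueError("triad must have exactly 3 entries")
        if len(self.gln_binding) != 2:
            raise ValueError("gln_binding must have exactly 2 entries")
        if sorted(r.expected for r in self.triad) != ["C", "E", "H"]:
            raise ValueError("triad expected residues must be C, H and E")
        positions = [r.position for r in self.triad + self.gln_binding]
        if len(set(positions)) != len(positions):
            raise ValueError("diagnostic positions must be distinct")

    @property
    def residues(self) -> list[DiagnosticResidue]:
        return list(self.triad) + list(self.gln_binding)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "DiagnosticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            ref_id=raw["ref_id"],
            triad=[DiagnosticResidue(**d) for d in raw["triad"]],
            gln_binding=[DiagnosticResidue(**d) for d in raw["gln_binding"]],
            window=tuple(raw["window"]) if raw.get("window") else None,
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {
            "ref_id": self.ref_id,
            "triad": [{"name": r.name, "position": r.position, "expected": r.expected}
                      for r in self.triad],
            "gln_binding": [{"name": r.name, "position": r.position, "expected": r.expected}
                            for r in self.gln_binding],
            "window": list(self.window) if self.window else None,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class ResidueStates:
    """Per-sequence states at the mapped diagnostic columns."""

    seq_id: str
    triad_state: list[State]
    gln_state: list[State]
    observed: dict[int, str]  # ref position -> residue seen (or "-")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.triad_state) != 3 or len(self.gln_state) != 2:
            raise ValueError("expected 3 triad and 2 gln states")


@dataclass
class CPSCall:
    seq_id: str
    states: ResidueStates
    functional_class: FunctionalClass
    rationale: str


def map_ref_positions(msa: Msa, spec: DiagnosticSpec) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 1-based alignment columns.

    Column ``c`` maps from position ``p`` when the reference row carries
    exactly ``p`` non-gap characters in columns 1..c and column ``c``
    itself is non-gap.
    """
    try:
        ref = msa.row(spec.ref_id)
    except KeyError:
        raise ValueError(f"reference {spec.ref_id!r} is not a row of the alignment") from None
    wanted = sorted({r.position for r in spec.residues})
    ungapped_len = sum(1 for ch in ref.residues if ch != "-")
    beyond = [p for p in wanted if p > ungapped_len]
    if beyond:
        raise ValueError(
            f"position(s) {beyond} beyond ungapped reference length {ungapped_len}"
        )
    mapping: dict[int, int] = {}
    p = 0
    for c, ch in enumerate(ref.residues, start=1):
        if ch != "-":
            p += 1
            if p in spec_positions(spec):
                mapping[p] = c
    return mapping


def spec_positions(spec: DiagnosticSpec) -> frozenset[int]:
    return frozenset(r.position for r in spec.residues)


def _state_of(observed: str, expected: str) -> tuple[State, Optional[str]]:
    if observed == "-":
        return State.GAP, None
    if observed == expected:
        return State.MATCH, None
    if observed == "X":
        return State.DIVERGENT, "ambiguous residue"
    return State.DIVERGENT, None


def extract_states(msa: Msa, spec: DiagnosticSpec) -> list[ResidueStates]:
    """Residue states at the diagnostic columns for every alignment row."""
    mapping = map_ref_positions(msa, spec)
    out = []
    for row in msa.rows:
        triad_state, gln_state, flags = [], [], []
        observed: dict[int, str] = {}
        for group, sink in ((spec.triad, triad_state), (spec.gln_binding, gln_state)):
            for res in group:
                ch = row.residues[mapping[res.position] - 1]
                observed[res.position] = ch
                state, flag = _state_of(ch, res.expected)
                sink.append(state)
                if flag:
                    flags.append(f"{res.name}@{res.position}: {flag}")
        out.append(ResidueStates(seq_id=row.id, triad_state=triad_state,
                                 gln_state=gln_state, observed=observed, flags=flags))
    return out


def classify_cps(states: ResidueStates) -> CPSCall:
    """Apply the decision table; total and deterministic over all state combinations."""
    all_states = states.triad_state + states.gln_state
    if any(s is State.GAP for s in all_states):
        cls = FunctionalClass.INDETERMINATE
        why = "gap at one or more diagnostic positions"
    elif any(s is State.DIVERGENT for s in states.triad_state):
        cls = FunctionalClass.AMMONIA_OBLIGATE
        why = "catalytic triad incomplete"
    elif all(s is State.MATCH for s in states.gln_state):
        cls = FunctionalClass.GLN_UTILIZING
        why = "intact triad and both glutamine-binding residues"
    elif sum(s is State.DIVERGENT for s in states.gln_state) == 1:
        cls = FunctionalClass.INTERMEDIATE_AMMONIA_PREFERRING
        why = "intact triad, one glutamine-binding residue divergent"
    else:
        cls = FunctionalClass.AMMONIA_OBLIGATE
        why = "intact triad but both glutamine-binding residues divergent"
    return CPSCall(seq_id=states.seq_id, states=states, functional_class=cls, rationale=why)


def global_align(query: SeqRecord, ref: SeqRecord,
                 substitution_matrix: str = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0
                 ) -> tuple[Msa, float]:
    """Optimal global pairwise protein alignment under affine gap penalties.

    A gap of length L costs ``gap_open + L * gap_extend``. Returns the
    2-row alignment (query first) and its score. Deterministic: the first
    alignment in the aligner's canonical enumeration order is taken.
    """
    if not query.residues or not ref.residues:
        raise ValueError("cannot align an empty sequence")
    if query.alphabet != "protein" or ref.alphabet != "protein":
        raise ValueError("global_align expects protein records")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(query.residues, ref.residues)[0]
    q_row, r_row = str(aln[0]), str(aln[1])
    msa = Msa(rows=[
        SeqRecord(id=query.id, residues=q_row, alphabet="protein"),
        SeqRecord(id=ref.id, residues=r_row, alphabet="protein"),
    ])
    return msa, float(aln.score)


def column_conservation(msa: Msa) -> np.ndarray:
    """Per-column fraction of rows sharing the modal residue, gaps excluded.

    All-gap columns are NaN. Requires at least two rows.
    """
    if len(msa.rows) < 2:
        raise ValueError("conservation needs at least 2 rows")
    out = np.empty(msa.ncol)
    for c in range(msa.ncol):
        col = [r.residues[c] for r in msa.rows if r.residues[c] != "-"]
        if not col:
            out[c] = np.nan
            continue
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        out[c] = max(counts.values()) / len(col)
    return out


def conserved_columns(msa: Msa, threshold: float = 1.0) -> np.ndarray:
    """Boolean mask of columns whose conservation meets the threshold."""
    frac = column_conservation(msa)
    with np.errstate(invalid="ignore"):
        return np.asarray(frac >= threshold) & ~np.isnan(frac)


def classify_alignment(msa: Msa, spec: DiagnosticSpec) -> list[CPSCall]:
    """Extract states and classify every row of an alignment."""
    return [classify_cps(s) for s in extract_states(msa, spec)]


def classify_query(query: SeqRecord, ref: SeqRecord, spec: DiagnosticSpec,
                   **align_kwargs) -> CPSCall:
    """Align an unaligned query to the reference, then classify the query.

    The reference must be the spec's anchor sequence (ungapped).
    """
    if ref.id != spec.ref_id:
        raise ValueError(f"reference id {ref.id!r} does not match spec anchor {spec.ref_id!r}")
    msa, _ = global_align(query, ref, **align_kwargs)
    calls = classify_alignment(msa, spec)
    return next(c for c in calls if c.seq_id == query.id)
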