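"""Synthetic promoters and CPS protein families with known ground truth.

Every pipeline stage is testable without downloads: promoters are i.i.d.
background sequence of configurable length and GC content with motif
concretizations implanted at known positions (truth emitted alongside),
and protein families are a reference sequence perturbed by background
substitutions everywhere *except* the diagnostic columns, which are
clamped to states consistent with an assigned functional class — so the
generating class is recoverable exactly whatever the background noise.

Both generators are deterministic under a fixed seed; the seed is
recorded in the output record description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from cpscan.cps_classify import DiagnosticSpec, FunctionalClass
from cpscan.io_formats import Msa, SeqRecord
from cpscan.motif_scan import MotifHit, revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PromoterSimConfig:
    """Background + implant model for one synthetic upstream region.

    ``implants`` are (concrete sequence, 1-based position, strand); a
    reverse-strand implant is written as its reverse complement. The
    default length matches the 3.5 kb upstream windows the pipeline is
    aimed at.
    """

    length: int = 3500
    gc_fraction: float = 0.41  # typical teleost genomic GC
    implants: list[tuple[str, int, str]] = field(default_factory=list)
    seed: int = 0
    seq_id: str = "synthetic_promoter"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")
        spans = []
        for seq, pos, strand in self.implants:
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if pos < 1 or pos + len(seq) - 1 > self.length:
                raise ValueError(f"implant {seq!r} at {pos} does not fit in length {self.length}")
            spans.append((pos, pos + len(seq) - 1))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping implants")


def gen_promoter(config: PromoterSimConfig) -> tuple[SeqRecord, list[MotifHit]]:
    """Generate one promoter region plus its implant truth list.

    Background bases are drawn independently with P(G)=P(C)=gc/2 and
    P(A)=P(T)=(1-gc)/2; implants overwrite the background. The truth list
    carries one exact :class:`MotifHit` per implant (pattern label
    "implant"), directly writable as BED.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=config.length, p=probs)
    for seq, pos, strand in config.implants:
        written = seq.upper() if strand == "+" else revcomp(seq.upper())
        bases[pos - 1 : pos - 1 + len(seq)] = list(written)
    residues = "".join(bases)
    record = SeqRecord(
        id=config.seq_id,
        residues=residues,
        alphabet="dna",
        description=f"synthetic promoter len={config.length} gc={gc} seed={config.seed}",
    )
    truth = [
        MotifHit(
            seq_id=config.seq_id,
            start=pos,
            end=pos + len(seq) - 1,
            strand=strand,
            pattern="implant",
            mismatches=0,
            matched=residues[pos - 1 : pos - 1 + len(seq)],
            upstream_span=(config.length - pos + 1, config.length - (pos + len(seq) - 1) + 1),
        )
        for seq, pos, strand in config.implants
    ]
    truth.sort(key=lambda h: h.start)
    return record, truth


@dataclass
class ProteinSimConfig:
    """Clamped-diagnostic protein family model.

    Each simulated sequence is the reference with i.i.d. substitutions at
    non-diagnostic sites (``per_site_sub_prob``) and diagnostic sites set
    per its assigned class: GLN_UTILIZING keeps all expected residues;
    INTERMEDIATE_AMMONIA_PREFERRING replaces the first glutamine-binding
    residue with ``alt_residue``; AMMONIA_OBLIGATE replaces the catalytic
    Cys (``knockout="triad"``, default) or both glutamine-binding
    residues (``knockout="gln"``).
    """

    ref: SeqRecord
    spec: DiagnosticSpec
    class_assignments: list[FunctionalClass]
    per_site_sub_prob: float = 0.05
    alt_residue: str = "A"
    knockout: str = "triad"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref.alphabet != "protein" or "-" in self.ref.residues:
            raise ValueError("reference must be an ungapped protein record")
        if not 0.0 <= self.per_site_sub_prob <= 1.0:
            raise ValueError("per_site_sub_prob must be in [0,1]")
        if self.knockout not in ("triad", "gln"):
            raise ValueError("knockout must be 'triad' or 'gln'")
        for res in self.spec.residues:
            if res.position > len(self.ref.residues):
                raise ValueError(f"diagnostic position {res.position} beyond reference length")
            if self.alt_residue == res.expected:
                raise ValueError(
                    f"alt_residue {self.alt_residue!r} equals expected residue at {res.position}"
                )

    @property
    def n_seqs(self) -> int:
        return len(self.class_assignments)


def _clamp(residues: list[str], config: ProteinSimConfig, cls: FunctionalClass) -> None:
    spec = config.spec
    for res in spec.residues:
        residues[res.position - 1] = res.expected
    if cls is FunctionalClass.GLN_UTILIZING:
        return
    if cls is FunctionalClass.INTERMEDIATE_AMMONIA_PREFERRING:
        residues[spec.gln_binding[0].position - 1] = config.alt_residue
    elif cls is FunctionalClass.AMMONIA_OBLIGATE:
        if config.knockout == "triad":
            cys = next(r for r in spec.triad if r.expected == "C")
            residues[cys.position - 1] = config.alt_residue
        else:
            for r in spec.gln_binding:
                residues[r.position - 1] = config.alt_residue
    elif cls is FunctionalClass.INDETERMINATE:
        # represented as missing data at the first triad position
        residues[spec.triad[0].position - 1] = "-"
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"cannot simulate class {cls}")


def gen_protein_family(config: ProteinSimConfig
                       ) -> tuple[Msa, dict[str, FunctionalClass]]:
    """Simulate a CPS-like protein family with known functional classes.

    Returns an ungapped equal-length alignment (substitution-only model)
    and the truth labels keyed by sequence id.
    """
    rng = np.random.default_rng(config.seed)
    ref_res = config.ref.residues
    diag = {r.position - 1 for r in config.spec.residues}
    rows = [SeqRecord(id=config.ref.id, residues=ref_res, alphabet="protein",
                      description=f"reference seed={config.seed}")]
    truth: dict[str, FunctionalClass] = {}
    for i, cls in enumerate(config.class_assignments, start=1):
        residues = list(ref_res)
        for j in range(len(residues)):
            if j in diag:
                continue
            if rng.random() < config.per_site_sub_prob:
                choices = AMINO_ACIDS.replace(residues[j], "")
                residues[j] = choices[rng.integers(len(choices))]
        _clamp(residues, config, cls)
        seq_id = f"sim_{i:03d}_{cls.value}"
        rows.append(SeqRecord(id=seq_id, residues="".join(residues), alphabet="protein",
                              description=f"simulated class={cls.value} seed={config.seed}"))
        truth[seq_id] = cls
    return Msa(rows=rows), truth


def random_reference(length: int = 120, seed: int = 0, seq_id: str = "synthetic_ref"
                     ) -> SeqRecord:
    """A uniform-random protein reference for family simulation."""
    rng = np.random.default_rng(seed)
    res = "".join(AMINO_ACIDS[rng.integers(20)] for _ in range(length))
    return SeqRecord(id=seq_id, residues=res, alphabet="protein",
                     description=f"synthetic reference seed={seed}")
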