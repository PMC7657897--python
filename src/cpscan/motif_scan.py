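"""Degenerate, paired and near-miss E-box motif scanning in promoter regions.

The scanner finds every window of a promoter whose minimal Hamming
distance to an IUPAC-degenerate pattern (minimum over all concretizations,
computed symbol-wise) is within a mismatch budget. E-boxes are hexamers
with consensus CANNTG; the muscle transcription factor MyoD prefers the
narrower CAG(G/C)TG consensus (IUPAC ``CAGSTG``) and acts cooperatively at
*pairs* of E-boxes in close proximity, so exact hits are additionally
assembled into paired-motif units, optionally admitting one near-miss
partner ("presumptive" pairs — a single point mutation away from a
functional pair).

Coordinates are 1-based inclusive on the scanned record; upstream
distances count 5' from the transcription start site, which sits
immediately 3' of the last base of the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from cpscan.io_formats import SeqRecord

# IUPAC nucleotide degeneracy codes -> allowed concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

EBOX_GENERIC = None  # populated below; forward declaration for readers
EBOX_MYOD = None


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A labelled IUPAC-degenerate nucleotide pattern."""

    label: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty pattern")
        bad = [s for s in self.iupac.upper() if s not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {bad} in pattern {self.label!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def length(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(label=self.label, iupac=revcomp(self.iupac))


EBOX_GENERIC = MotifPattern("Ebox_generic", "CANNTG")
EBOX_MYOD = MotifPattern("Ebox_MyoD", "CAGSTG")


@dataclass
class PromoterRegion:
    """A promoter/upstream region whose last base abuts the TSS.

    The base at 1-based position ``p`` lies ``L - p + 1`` bases upstream of
    the transcription start site, where ``L`` is the region length.
    """

    record: SeqRecord
    species: str = ""
    declared_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.record.alphabet != "dna":
            raise ValueError("promoter region must be a dna record")
        if not self.species:
            self.species = self.record.id
        if self.declared_length is not None and len(self.record) != self.declared_length:
            raise ValueError(
                f"region {self.record.id!r}: length {len(self.record)} != declared {self.declared_length}"
            )

    @property
    def length(self) -> int:
        return len(self.record)

    @property
    def sequence(self) -> str:
        return self.record.residues


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a degenerate pattern on a scanned record.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates;
    matching is substitution-only, so ``end - start + 1`` equals the
    pattern length. ``replacements`` lists, for each mismatching offset
    (0-based within the window), the offending base and one allowed
    substitute; it is empty for exact hits.
    """

    seq_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    pattern: str
    mismatches: int
    matched: str
    upstream_span: Optional[tuple[int, int]] = None
    replacements: tuple[tuple[int, str, str], ...] = ()

    @property
    def is_exact(self) -> bool:
        return self.mismatches == 0


@dataclass(frozen=True)
class PairedMotif:
    """Two non-overlapping hits on the same record and strand — the
    cooperative MyoD binding unit.

    ``gap`` counts bases strictly between the two hits; ``category`` is
    "exact" when both members are exact and "presumptive" when exactly one
    member is a near-miss.
    """

    first: MotifHit
    second: MotifHit
    gap: int
    composite: str
    category: Literal["exact", "presumptive"] = "exact"


def iupac_matches(pattern_symbol: str, base: str) -> bool:
    """True iff ``base`` is in the IUPAC symbol's allowed set.

    Subject base ``N`` matches nothing: an undetermined assembly base
    cannot confirm a motif.
    """
    try:
        allowed = IUPAC[pattern_symbol.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol {pattern_symbol!r}") from None
    if base not in "ACGTN":
        raise ValueError(f"invalid subject base {base!r}")
    return base != "N" and base in allowed


def _window_mismatches(window: str, pattern: str) -> int:
    return sum(1 for s, b in zip(pattern, window) if not (b != "N" and b in IUPAC[s]))


def _scan_one_strand(seq: str, seq_id: str, pattern: MotifPattern, strand: str,
                     max_mismatches: int, region_length: int) -> list[MotifHit]:
    pat = pattern.iupac if strand == "+" else revcomp(pattern.iupac)
    m = len(pat)
    hits = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        mm = _window_mismatches(window, pat)
        if mm <= max_mismatches:
            repl = tuple(
                (j, window[j], IUPAC[pat[j]][0])
                for j in range(m)
                if not (window[j] != "N" and window[j] in IUPAC[pat[j]])
            )
            start, end = i + 1, i + m
            hits.append(
                MotifHit(
                    seq_id=seq_id, start=start, end=end, strand=strand,  # forward coords
                    pattern=pattern.label, mismatches=mm, matched=window,
                    upstream_span=(region_length - start + 1, region_length - end + 1),
                    replacements=repl,
                )
            )
    return hits


def scan(region: PromoterRegion, pattern: MotifPattern,
         strands: Literal["forward", "both"] = "forward",
         max_mismatches: int = 0) -> list[MotifHit]:
    """Find every window within ``max_mismatches`` of the degenerate pattern.

    Overlapping hits are all reported, sorted by (start, strand, pattern
    label). Reverse-strand hits (``strands="both"``) are reported in
    forward coordinates with strand "-". A pattern longer than the region
    yields an empty list; an empty region is an error.
    """
    seq = region.sequence
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if len(pattern) > len(seq):
        return []
    hits = _scan_one_strand(seq, region.record.id, pattern, "+", max_mismatches, len(seq))
    if strands == "both":
        hits += _scan_one_strand(seq, region.record.id, pattern, "-", max_mismatches, len(seq))
    elif strands != "forward":
        raise ValueError(f"unknown strand policy {strands!r}")
    hits.sort(key=lambda h: (h.start, h.strand, h.pattern))
    return hits


def find_near_misses(region: PromoterRegion, pattern: MotifPattern, k: int = 1,
                     strands: Literal["forward", "both"] = "forward") -> list[MotifHit]:
    """Windows at Hamming distance 1..k from the pattern (exact matches excluded).

    Each hit's ``replacements`` field records, per mismatching position,
    the offending base and one substitution that would restore a match —
    the "single point mutation" diagnostic.
    """
    if k == 0:
        raise ValueError("use scan for exact matches")
    if k < 0:
        raise ValueError("k must be >= 1")
    return [h for h in scan(region, pattern, strands=strands, max_mismatches=k)
            if h.mismatches >= 1]


def pair_hits(hits: Sequence[MotifHit], max_gap: int = 19,
              allow_near_miss_partner: bool = False) -> list[PairedMotif]:
    """Assemble ordered pairs of non-overlapping hits with gap <= max_gap.

    Exact pairs require both members exact. With ``allow_near_miss_partner``
    pairs where exactly one member has mismatches >= 1 are additionally
    reported with category "presumptive". Hits must come from one region
    and strand. The gap counts bases strictly between the two footprints.
    """
    seq_ids = {h.seq_id for h in hits}
    strands = {h.strand for h in hits}
    if len(seq_ids) > 1 or len(strands) > 1:
        raise ValueError("pair_hits expects hits from a single region and strand")
    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    pairs: list[PairedMotif] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            gap = b.start - a.end - 1
            if gap < 0:
                continue
            if gap > max_gap:
                break  # ordered by start; later partners only get farther
            n_miss = (a.mismatches >= 1) + (b.mismatches >= 1)
            if n_miss == 0:
                category = "exact"
            elif n_miss == 1 and allow_near_miss_partner:
                category = "presumptive"
            else:
                continue
            pairs.append(PairedMotif(first=a, second=b, gap=gap, composite="", category=category))
    return pairs


def composite_sequence(pair: PairedMotif, region: PromoterRegion) -> PairedMotif:
    """Fill in the literal substring spanned by a pair on its region."""
    sub = region.sequence[pair.first.start - 1 : pair.second.end]
    return replace(pair, composite=sub)


def to_upstream_coords(hit: MotifHit, region: PromoterRegion) -> tuple[int, int]:
    """(distal, proximal) upstream distances of a hit from the TSS.

    distal = L - start + 1, proximal = L - end + 1; distal >= proximal.
    """
    L = region.length
    if not (1 <= hit.start <= hit.end <= L):
        raise ValueError(f"hit [{hit.start},{hit.end}] outside region of length {L}")
    return (L - hit.start + 1, L - hit.end + 1)


def from_upstream_coords(span: tuple[int, int], region: PromoterRegion) -> tuple[int, int]:
    """Inverse of :func:`to_upstream_coords`: recover (start, end)."""
    distal, proximal = span
    L = region.length
    return (L - distal + 1, L - proximal + 1)


@dataclass
class ScanConfig:
    """Knobs for the cross-species comparison.

    ``max_gap`` defaults to 19, the one quantified pairing distance in the
    study system; ``near_miss_k`` is the Hamming budget for presumptive
    partners; ``pairing_pattern`` names which pattern's hits are paired.
    """

    max_gap: int = 19
    near_miss_k: int = 1
    strands: Literal["forward", "both"] = "forward"
    pairing_pattern: str = EBOX_MYOD.label


def compare_regions(regions: Sequence[PromoterRegion],
                    patterns: Sequence[MotifPattern] = (EBOX_GENERIC, EBOX_MYOD),
                    config: Optional[ScanConfig] = None
                    ) -> tuple[pd.DataFrame, dict[str, list[MotifHit]]]:
    """Cross-species motif survey.

    Returns a per-species table (exact hit count per pattern, exact and
    presumptive pair counts for the pairing pattern) and, per species, the
    hit list suitable for BED output. Deterministic: identical regions
    under two ids yield identical rows.
    """
    if not regions:
        raise ValueError("at least one region required")
    cfg = config or ScanConfig()
    if not patterns:
        return pd.DataFrame(), {r.species: [] for r in regions}
    rows = []
    hits_by_species: dict[str, list[MotifHit]] = {}
    for region in regions:
        row: dict[str, object] = {"species": region.species, "region_id": region.record.id,
                                  "length": region.length}
        all_hits: list[MotifHit] = []
        for pat in patterns:
            exact = scan(region, pat, strands=cfg.strands, max_mismatches=0)
            row[f"n_{pat.label}"] = len(exact)
            all_hits.extend(exact)
            if pat.label == cfg.pairing_pattern:
                near = find_near_misses(region, pat, k=cfg.near_miss_k, strands=cfg.strands)
                candidates = exact + near
                by_strand = {}
                for h in candidates:
                    by_strand.setdefault(h.strand, []).append(h)
                pairs: list[PairedMotif] = []
                for shits in by_strand.values():
                    pairs += pair_hits(shits, max_gap=cfg.max_gap, allow_near_miss_partner=True)
                row["exact_pairs"] = sum(p.category == "exact" for p in pairs)
                row["presumptive_pairs"] = sum(p.category == "presumptive" for p in pairs)
        row.setdefault("exact_pairs", 0)
        row.setdefault("presumptive_pairs", 0)
        rows.append(row)
        hits_by_species[region.species] = all_hits
    return pd.DataFrame(rows), hits_by_species
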